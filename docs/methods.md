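# Methods

## Knowledge-base model

The knowledge base is a set of subject–predicate–object triples over
compact `prefix:localname` identifiers. Entities (signs, disorders,
echographic views, anatomical structures, ultrasound routes and modes) are
declared with `epo:kind` and a `skos:prefLabel`, optionally a definition and
opaque reference-image identifiers. Domain relations are `epo:has_sign`
(disorder → sign), `epo:suggests` (sign → disorder), `epo:requires_view`
(sign → view) and `epo:located_in` (→ anatomical structure).

`epo:has_sign` is the authoritative direction; `epo:suggests` is
materialized automatically whenever either direction is asserted, and this
inverse closure is the only inference rule the store applies. Full
description-logic classification is deliberately out of scope: the protocol
derivation exercises exactly the closure-plus-pattern-matching fragment, and
keeping the inference surface this small is what makes every reasoning step
auditable.

Serialization uses a restricted Turtle dialect — prefix declarations, plain
statements, string literals; no blank nodes, collections or datatype tags,
none of which the schema needs. Parsing goes through rdflib; writing is done
in-package with prefixes and triples sorted so output is byte-deterministic
and `load(save(kb))` is the identity on the triple set. All query output
(`match`, entity listings, reasoner results) is sorted by IRI text for the
same reason: identical inputs must produce bit-identical outputs.

Integrity validation reports data, not exceptions: undeclared or unlabeled
entities in relation positions, kind mismatches, broken inverse closure,
signs with no required view, disorders with no sign.

## Protocol derivation and differential ranking

From identified signs *S* and explicitly-absent signs *A*:
disorders *D* = ⋃ suggests(S); relevant signs *R* = ⋃ has_sign(D); pending
*P* = *R* − *S* − *A*; the protocol has one item per view required by some
pending sign and not yet acquired, carrying the pending signs demonstrable
in it.

Two orderings are artifact conventions, since a knowledge graph does not
rank:

* **Protocol items**: descending number of sought signs (most informative
  acquisition first), ties by ascending view label then IRI. This maximizes
  signs assessable per acquisition and is reproducible.
* **Differential**: descending support (identified signs of the disorder),
  then descending completeness (identified fraction of the disorder's sign
  inventory), then label. Support-first is the simplest defensible evidence
  ordering; completeness breaks ties in favor of disorders whose picture is
  more fully established.

Callers may mark signs assessed-absent; without that channel the guidance
loop could never terminate on truly negative findings. With it, each
guidance step retires its sought signs, so the loop reaches an empty
protocol in at most |signs| iterations.

## Session workflow and reporting

A session accumulates per-image keyword annotations validated against the
knowledge base (unknown IRIs and kind mismatches are rejected, image ids
must be unique). Derived state is recomputed from the annotations: a sign
present in any image is identified; a sign is absent only if it was marked
absent somewhere and never seen (presence is an observation, absence a
failed search). Timestamps are caller-supplied; no wall-clock reads occur in
logic, so tests are deterministic. Finalizing emits an immutable report
whose conclusion is a structured diagnosis statement — location class
(intrauterine / ectopic / pregnancy of unknown location) with the precise
ectopic site when stated. The published free-text criterion ("tubal
pregnancy" explicitly stated) maps to `ectopic_site = tubal`.

## Scoring instruments

The image-set quality score sums 15 boolean criteria (5 on the sagittal
uterus view, 5 per ovary view), one point each. The criteria are expert
judgments supplied as data; views never acquired leave their items unticked
and score 0 (partial image sets are scored, not excluded). The trust scale
is the canonical 5-level ordinal; levels 1–3 require a supervisor
examination. Kappa agreement bands: below 0.6 poor, 0.6–0.8 moderate, above
0.8 good; the boundary wording being inclusive-ambiguous, "moderate" is the
closed interval [0.6, 0.8].

## Outcome classification

The gold standard is always a definite location. A location call is correct
when the report states the gold location class; a
pregnancy-of-unknown-location conclusion is never a correct call on these
cases. This is stricter than treating "not ectopic" as correct for
intrauterine cases, and it is the reading under which the published
outcome table is internally consistent: the incorrect-location counts
(12 assisted / 25 nonassisted of 64) exceed the false-negative plus
false-positive counts (4 / 11) exactly by the unknown-location calls on
intrauterine cases. False negative of EP = gold ectopic, conclusion not
ectopic (including unknown location — the ectopic was missed either way);
false positive = gold nonectopic, conclusion ectopic. Exact diagnosis
additionally requires the gold ectopic site to be stated; for intrauterine
cases correct location is already exact.

Percentages are rounded half away from zero to integer percent, which
reproduces the printed values (81, 61, 77, 47, 20, 30, 23, −27).

## Statistical battery

* **Paired t**: classical paired t on within-(case, operator) differences,
  two-sided p; zero-variance differences are signaled as errors, not NaN.
* **Exact McNemar**: p = min(1, 2·P(X ≤ min(b,c))), X ~ Binomial(b+c, ½),
  on the discordant-pair counts.
* **Weighted kappa**: 1 − Σw·observed / Σw·expected with linear
  (|i−j|/(k−1)) or quadratic disagreement weights over category positions;
  quadratic is the default (the published analysis does not state the
  scheme). Degenerate single-category margins return 1.
* **Proportion-difference CI**: unpaired Wald, (p₁−p₂) ± 1.96·√(p₁q₁/n +
  p₂q₂/n), in percentage points. This deliberately documented choice does
  **not** reproduce the published intervals (7–33, 15–44), which require
  pair-level data that was not printed; the same holds for the published
  McNemar p-values. The test suite therefore validates this machinery
  against independent oracles (binomial enumeration, quadrature of the t
  density, hand-built contingency tables, an independent kappa
  implementation) rather than against the unprintable values.

## The simulator

`run_study` replicates the crossover design: 2 operators × 32 cases
(18 intrauterine, 14 tubal EP, the published case mix) × 2 modes = 128
scans. Each case fixes which signs are truly demonstrable in which views:
intrauterine cases always show the intrauterine gestational sac, with yolk
sac (p=0.8), embryonic cardiac activity (p=0.6) and the double decidual sac
sign (p=0.5) sampled per case; tubal-EP cases always show an empty uterus,
with adnexal mass (p=0.7), tubal ring (p=0.6) on a randomly-sided adnexal
view, free pelvic fluid (p=0.7) and a pseudogestational sac (p=0.3). These
frequencies were chosen once as plausible early-pregnancy values; no
acceptance property depends on them beyond graph consistency.

Operators always acquire the three mandatory views (sagittal uterus, both
adnexa) and detect each demonstrable sign there with
`p_detect_spontaneous` (default 0.6). In assisted mode the protocol loop
then acquires the top-ranked pending view each round, detecting sought
demonstrable signs with `p_detect_prompted` (default 0.95) and marking the
rest absent. Completed views are never re-prompted, so every sign gets at
most one detection opportunity per arm; consequently, when the base views
cover all views and the two probabilities are equal, the two arms are
identically distributed — the null configuration the null-recovery test
exercises. The assisted advantage flows through the extra views the
protocol requests (pouch of Douglas, transverse uterus, endometrial zoom)
and is monotone in `p_detect_prompted`.

The simulated conclusion is the top differential disorder when it has
support ≥ 1 and is not tied with the runner-up on both support and
completeness; otherwise pregnancy of unknown location — deterministic and
conservative, mirroring how uncertainty is reported clinically. Each scan
draws from its own pseudo-random stream keyed by (seed, case index,
operator index, mode index), so records are byte-identical across runs and
independent of insertion order. Scan duration is base + per-image +
per-step minutes (3 / 0.5 / 2.5), which reproduces the qualitative pattern
that assistance costs time; quality and trust scores emulate the expert
review as binomial draws with per-mode success probabilities (0.83 / 0.68
per quality item, 0.78 / 0.60 per trust step). No headline property depends
on the duration or review emulation.

What the simulator does *not* model: real image interpretation, operator
learning or fatigue, inter-case difficulty correlation, the color-Doppler
semiology, and the behavioral parameters of any real trainee — the
detection probabilities are free knobs for property tests, not estimates.
Passing tests therefore demonstrate the mechanics of the workflow and
statistics, not clinical performance.

## Problem sizes and numerical choices

Property suites run on randomly generated valid KBs (≤ ~100 triples, 100
replicates for the reasoner-vs-brute-force equivalence), 200 seeded
replicates of the full 128-scan study for null recovery, and an 80-replicate
common-seed grid over `p_detect_prompted` ∈ {0.6, 0.8, 1.0} for monotone
effect recovery — sizes at which the whole suite completes in well under a
minute while the sign tests retain ample power. Exact McNemar is verified by
full enumeration for all discordant totals ≤ 20. Percent rounding uses exact
rational arithmetic (`fractions.Fraction`) to keep half-way cases honest.

## Known limitations

* The demonstration semiology is illustrative, not clinically validated.
* The Wald CI ignores the pairing of the design (documented above).
* Ranking schemes (protocol order, differential order) are conventions; a
  production system might order by diagnostic discriminability or
  acquisition convenience instead.
* Absence marking retires a sign globally, so a sign demonstrable only on
  the side opposite to the first-searched adnexal view can be lost; in the
  bundled simulation the adnexal views are part of the mandatory set, so
  the path does not arise.
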