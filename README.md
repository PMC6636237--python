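# scanassist

Ontology-backed scan assistance for early-pregnancy transvaginal ultrasound
(TVS), with the full statistical apparatus of a paired crossover evaluation.

Ectopic pregnancy (EP) is diagnosed by TVS through a precise reading of
ultrasound signs, and trainees in emergency units miss it far more often
than experts do. A clinical decision support system (CDSS) can close part of
that gap by reasoning over a knowledge base of early-pregnancy semiology:
when the operator identifies a sign, the system derives — dynamically, not
from a precalculated checklist — which echographic views still need to be
acquired and which signs to look for in them. `scanassist` implements that
reasoning core, the guided scan-session workflow around it, the scoring
instruments used to review such scans, and the statistics used to evaluate
the system in a 2-operator × 32-case × 2-mode crossover design, together
with a seeded in-silico replication of that design.

This package is aimed at researchers in medical knowledge engineering and
clinical decision support who want a reproducible, fully inspectable
implementation of the reasoning pattern and the evaluation machinery. The
bundled early-pregnancy knowledge base is illustrative (the clinical content
of production ontologies is not published); everything downstream depends
only on its graph structure.

## The reasoning core

The knowledge base is a set of RDF triples over a small vocabulary:
`epo:has_sign` (disorder → sign, with `epo:suggests` as its materialized
inverse), `epo:requires_view` (sign → echographic view), plus SKOS labels
and definitions so every inference step stays human-readable. Given the set
*S* of identified signs, the reasoner computes

1. *D* = ⋃<sub>s∈S</sub> suggests(s) — the disorders suggested by the signs;
2. *R* = ⋃<sub>d∈D</sub> has_sign(d) — all signs of those disorders;
3. *P* = *R* \ *S* \ *A* — the pending signs (*A* = signs searched and not
   found);
4. a protocol: one item per view required by a pending sign and not yet
   acquired, each carrying the pending signs demonstrable there, ordered
   most-informative-first.

Alongside, each disorder d ∈ D is ranked by its support |signs(d) ∩ S| and
completeness |signs(d) ∩ S| / |signs(d)|.

## Worked example

On the bundled toy ontology (`fig5.ttl`: four signs, two disorders, three
views), identifying `epo:sign_A` yields:

```
$ scanassist protocol --kb src/scanassist/data/fig5.ttl --sign epo:sign_A
{
  "protocol": [
    {"rank": 1, "view": "epo:echographic_view_j", "view_label": "Echographic view j",
     "sought_signs": ["epo:sign_B", "epo:sign_C"]},
    {"rank": 2, "view": "epo:echographic_view_k", "view_label": "Echographic view k",
     "sought_signs": ["epo:sign_D"]}
  ],
  "differential": [
    {"disorder": "epo:disorder_2", "label": "Disorder 2", "support": 1,
     "total_signs": 2, "completeness": 0.5},
    {"disorder": "epo:disorder_1", "label": "Disorder 1", "support": 1,
     "total_signs": 3, "completeness": 0.3333}
  ]
}
```

Reading: sign_A suggests both disorders (support 1 each; disorder_2 ranks
first because one identified sign covers half of its two-sign inventory).
Three signs are still pending, reachable through two views; view j comes
first because it can demonstrate two of them.

The crossover simulation and its evaluation, from Python:

```python
from scanassist import StudyDesign, run_study, summarize_study

records = run_study(StudyDesign(seed=7))   # 128 scans: 2 x 32 x 2
summary = summarize_study(records).to_dict()
print(summary["outcomes"]["correct_location"])
```

With seed 7 this prints (abridged) `count_assisted: 52, count_nonassisted:
45` for correct pregnancy location, with 1 vs 8 false negatives of EP —
the assisted arm finds more ectopics because the personalized protocol
directs attention (at higher detection probability) to views the standard
acquisition skips. The same records are available from the command line via
`scanassist simulate-study --seed 7 --out records.csv` followed by
`scanassist evaluate --records records.csv`.

The transcription of the published outcome tables ships as a fixture:
`scanassist evaluate --records src/scanassist/data/table2_records.csv`
reports 52/64 vs 39/64 correct location calls, 49 vs 30 exact diagnoses,
1 vs 8 EP false negatives, and 3 vs 3 false positives.

## Layout

| Module | Contents |
| --- | --- |
| `scanassist.ontology_store` | triple store, Turtle load/save, pattern matching, integrity validation |
| `scanassist.protocol_reasoner` | the four-step reasoning, protocol assembly, differential ranking |
| `scanassist.scan_session` | session workflow, controlled-keyword annotations, structured reports |
| `scanassist.scoring` | 15-item quality score, 5-level trust scale, kappa agreement bands |
| `scanassist.study_stats` | outcome classification, paired t, exact McNemar, weighted kappa, study summaries |
| `scanassist.fixtures_sim` | bundled KBs, outcome-table transcriptions, the seeded study simulator |
| `scanassist.cli` | `scanassist` command-line front end |

See `docs/methods.md` for the model assumptions, parameter choices, and
known limitations.
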