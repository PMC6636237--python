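"""Outcome classification and the crossover-study statistical battery.

The evaluation design is a paired crossover: each operator scans each case
twice, once assisted by the decision-support system and once not, giving
4 scans per case and paired comparisons within (case, operator). Continuous
outcomes (scan duration, image count, quality score, trust score) are
compared with paired t tests; the binary diagnostic outcomes (correct
pregnancy location, exact diagnosis) with exact McNemar tests on the
discordant pairs; scoring reproducibility with Cohen's weighted kappa.

Outcome definitions
-------------------
The gold standard is always a definite location (intrauterine or ectopic).
A scan's location call is *correct* when the report states the gold
location class — a conclusion of pregnancy of unknown location is never a
correct location call, since every study case has a known location. The
*exact* diagnosis additionally requires the precise ectopic site to be
stated (e.g. "tubal") for ectopic cases; for intrauterine cases correct
location is already exact. A *false negative of EP* is a gold-ectopic case
reported as anything but ectopic (including unknown location); a *false
positive of EP* is a gold-nonectopic case reported as ectopic. Percentages
are rounded half away from zero to integer percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .scan_session import DiagnosisStatement, EctopicSite, LocationClass

__all__ = [
    "ScanRecord",
    "OutcomeFlags",
    "PairedComparison",
    "ContinuousSummary",
    "CategoricalSummary",
    "StudySummary",
    "StatsError",
    "classify",
    "proportion_pct",
    "pct_change",
    "paired_t",
    "mcnemar_exact",
    "weighted_kappa",
    "wald_ci_diff",
    "summarize_study",
    "records_to_csv",
    "records_from_csv",
]


class StatsError(ValueError):
    """Invalid statistical input (zero variance, empty margins, ...)."""


@dataclass(frozen=True)
class ScanRecord:
    """One scan of the 2 operators x 32 cases x 2 modes design."""

    case_id: str
    operator_id: str
    mode: str  # "assisted" | "nonassisted"
    gold: DiagnosisStatement
    conclusion: DiagnosisStatement
    image_count: int
    duration_min: float
    quality_score: int
    trust_level: int

    def __post_init__(self) -> None:
        if self.mode not in ("assisted", "nonassisted"):
            raise ValueError(f"bad mode: {self.mode!r}")
        if self.gold.location_class is LocationClass.PREGNANCY_OF_UNKNOWN_LOCATION:
            raise ValueError("gold standard must be a definite location")
        if self.image_count < 0 or self.duration_min < 0:
            raise ValueError("image_count and duration_min must be nonnegative")
        if not 0 <= self.quality_score <= 15:
            raise ValueError("quality_score must lie in 0..15")
        if not 1 <= self.trust_level <= 5:
            raise ValueError("trust_level must lie in 1..5")


@dataclass(frozen=True)
class OutcomeFlags:
    correct_location: bool
    exact_diagnosis: bool
    fp_ep: bool
    fn_ep: bool


def classify(record: ScanRecord) -> OutcomeFlags:
    """Derive the four diagnostic outcome flags for one scan."""
    gold, concl = record.gold, record.conclusion
    correct = concl.location_class is gold.location_class
    gold_ectopic = gold.location_class is LocationClass.ECTOPIC
    concl_ectopic = concl.location_class is LocationClass.ECTOPIC
    if gold_ectopic:
        exact = (
            correct
            and concl.ectopic_site is not None
            and concl.ectopic_site is not EctopicSite.UNSPECIFIED
            and concl.ectopic_site is gold.ectopic_site
        )
    else:
        exact = correct
    return OutcomeFlags(
        correct_location=correct,
        exact_diagnosis=exact,
        fp_ep=(not gold_ectopic) and concl_ectopic,
        fn_ep=gold_ectopic and not concl_ectopic,
    )


# --------------------------------------------------------------------------
# Elementary statistics
# --------------------------------------------------------------------------


def _round_half_away(value: float) -> int:
    return int(math.copysign(math.floor(abs(value) + 0.5), value))


def proportion_pct(count: int, n: int) -> int:
    """100*count/n as an integer percent, rounded half away from zero."""
    if n <= 0:
        raise StatsError("n must be positive")
    if not 0 <= count <= n:
        raise StatsError("count must lie in 0..n")
    frac = Fraction(100 * count, n)
    return int(math.floor(frac + Fraction(1, 2)))


def pct_change(new: float, old: float) -> int:
    """Percent change from ``old`` to ``new``, rounded half away from zero."""
    if old == 0:
        raise StatsError("reference value must be nonzero")
    return _round_half_away(100.0 * (new - old) / old)


@dataclass(frozen=True)
class PairedComparison:
    """Result of a paired t test between the assisted and nonassisted arms."""

    mean_assisted: float
    mean_nonassisted: float
    difference: float
    pct_difference: float
    t_statistic: float
    degrees_freedom: int
    p_value: float


def paired_t(xs: Sequence[float], ys: Sequence[float]) -> PairedComparison:
    """Classical paired t test of xs (assisted) against ys (nonassisted).

    Two-sided p from the t distribution with n-1 degrees of freedom.
    Raises :class:`StatsError` when the pairwise differences have zero
    variance (the t statistic is undefined, not infinite).
    """
    if len(xs) != len(ys):
        raise StatsError("paired samples must have equal length")
    if len(xs) < 2:
        raise StatsError("need at least 2 pairs")
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise StatsError("pairwise differences have zero variance")
    n = len(d)
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    mean_x, mean_y = x.mean(), y.mean()
    return PairedComparison(
        mean_assisted=float(mean_x),
        mean_nonassisted=float(mean_y),
        difference=float(mean_x - mean_y),
        pct_difference=float(100.0 * (mean_x - mean_y) / mean_y) if mean_y else math.nan,
        t_statistic=float(t),
        degrees_freedom=n - 1,
        p_value=float(p),
    )


def mcnemar_exact(b: int, c: int) -> float:
    """Exact two-sided McNemar p-value from the discordant-pair counts.

    Under the null the smaller discordant count is Binomial(b+c, 1/2);
    p = min(1, 2 * P(X <= min(b, c))).
    """
    if b < 0 or c < 0:
        raise StatsError("discordant counts must be nonnegative")
    if b + c == 0:
        raise StatsError("no discordant pairs: McNemar test undefined")
    p = 2.0 * sps.binom.cdf(min(b, c), b + c, 0.5)
    return float(min(1.0, p))


def weighted_kappa(
    r1: Sequence,
    r2: Sequence,
    categories: Sequence,
    weights: str = "quadratic",
) -> float:
    """Cohen's weighted kappa for two raters over ordered categories.

    kappa = 1 - sum(w * observed) / sum(w * expected), with disagreement
    weights w_ij = |i-j|/(k-1) (linear) or ((i-j)/(k-1))^2 (quadratic) over
    category positions. Returns 1.0 on perfect agreement (including the
    degenerate single-category margin, where chance disagreement is zero).
    """
    if len(r1) != len(r2):
        raise StatsError("rating lists must have equal length")
    if not r1:
        raise StatsError("rating lists must be nonempty")
    if weights not in ("linear", "quadratic"):
        raise StatsError(f"weights must be 'linear' or 'quadratic', got {weights!r}")
    index = {c: i for i, c in enumerate(categories)}
    for r in (r1, r2):
        for value in r:
            if value not in index:
                raise StatsError(f"rating {value!r} outside categories")
    k = len(categories)
    observed = np.zeros((k, k))
    for a, b in zip(r1, r2):
        observed[index[a], index[b]] += 1
    n = observed.sum()
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / n
    ii, jj = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    if k == 1:
        return 1.0
    w = np.abs(ii - jj) / (k - 1)
    if weights == "quadratic":
        w = w**2
    expected_disagreement = (w * expected).sum()
    if expected_disagreement == 0:
        return 1.0
    return float(1.0 - (w * observed).sum() / expected_disagreement)


def wald_ci_diff(p1: float, p2: float, n: int) -> tuple[float, float]:
    """Unpaired Wald 95% CI for p1 - p2, in percentage points.

    Treats the two arms as independent samples of size ``n`` each; this is
    a simple, documented convention and ignores the pairing of the design.
    """
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise StatsError(f"proportion out of [0, 1]: {p}")
    if n <= 0:
        raise StatsError("n must be positive")
    se = math.sqrt(p1 * (1 - p1) / n + p2 * (1 - p2) / n)
    diff = p1 - p2
    return (100.0 * (diff - 1.96 * se), 100.0 * (diff + 1.96 * se))


# --------------------------------------------------------------------------
# Study summaries
# --------------------------------------------------------------------------

CONTINUOUS_METRICS = ("image_count", "duration_min", "quality_score", "trust_level")
BINARY_OUTCOMES = ("correct_location", "exact_diagnosis")
COUNT_OUTCOMES = ("fn_ep", "fp_ep")


@dataclass(frozen=True)
class ContinuousSummary:
    """One continuous row: per-mode mean (SD) and the paired t result."""

    metric: str
    sd_assisted: float
    sd_nonassisted: float
    comparison: PairedComparison


@dataclass(frozen=True)
class CategoricalSummary:
    """One diagnostic-outcome row: per-mode counts, percentages, and tests."""

    outcome: str
    n_per_mode: int
    count_assisted: int
    count_nonassisted: int
    pct_assisted: int
    pct_nonassisted: int
    difference: int
    difference_pct: int
    wald_ci_pct: Optional[tuple[float, float]] = None
    discordant_b: Optional[int] = None
    discordant_c: Optional[int] = None
    mcnemar_p: Optional[float] = None


@dataclass(frozen=True)
class StudySummary:
    n_scans: int
    n_pairs: int
    continuous: dict[str, ContinuousSummary]
    outcomes: dict[str, CategoricalSummary]

    def to_dict(self) -> dict:
        return {
            "n_scans": self.n_scans,
            "n_pairs": self.n_pairs,
            "continuous": {
                m: {
                    "mean_assisted": c.comparison.mean_assisted,
                    "sd_assisted": c.sd_assisted,
                    "mean_nonassisted": c.comparison.mean_nonassisted,
                    "sd_nonassisted": c.sd_nonassisted,
                    "difference": c.comparison.difference,
                    "pct_difference": c.comparison.pct_difference,
                    "t": c.comparison.t_statistic,
                    "df": c.comparison.degrees_freedom,
                    "p": c.comparison.p_value,
                }
                for m, c in self.continuous.items()
            },
            "outcomes": {
                o: {
                    "n_per_mode": s.n_per_mode,
                    "count_assisted": s.count_assisted,
                    "count_nonassisted": s.count_nonassisted,
                    "pct_assisted": s.pct_assisted,
                    "pct_nonassisted": s.pct_nonassisted,
                    "difference": s.difference,
                    "difference_pct": s.difference_pct,
                    "wald_ci_pct": s.wald_ci_pct,
                    "discordant_b": s.discordant_b,
                    "discordant_c": s.discordant_c,
                    "mcnemar_p": s.mcnemar_p,
                }
                for o, s in self.outcomes.items()
            },
        }


def _pair_records(
    records: Sequence[ScanRecord],
) -> list[tuple[ScanRecord, ScanRecord]]:
    by_key: dict[tuple[str, str], dict[str, ScanRecord]] = {}
    for rec in records:
        slot = by_key.setdefault((rec.case_id, rec.operator_id), {})
        if rec.mode in slot:
            raise StatsError(
                f"duplicate {rec.mode} scan for case {rec.case_id}, "
                f"operator {rec.operator_id}"
            )
        slot[rec.mode] = rec
    pairs = []
    for key in sorted(by_key):
        slot = by_key[key]
        if set(slot) != {"assisted", "nonassisted"}:
            raise StatsError(f"unpaired records for case/operator {key}")
        pairs.append((slot["assisted"], slot["nonassisted"]))
    return pairs


def summarize_study(records: Sequence[ScanRecord]) -> StudySummary:
    """Per-mode means/tests for continuous outcomes and counts/tests for
    the diagnostic outcomes, paired within (case, operator)."""
    pairs = _pair_records(records)
    n_pairs = len(pairs)

    continuous: dict[str, ContinuousSummary] = {}
    for metric in CONTINUOUS_METRICS:
        xs = [float(getattr(a, metric)) for a, _ in pairs]
        ys = [float(getattr(b, metric)) for _, b in pairs]
        comparison = paired_t(xs, ys)
        continuous[metric] = ContinuousSummary(
            metric=metric,
            sd_assisted=float(np.std(xs, ddof=1)),
            sd_nonassisted=float(np.std(ys, ddof=1)),
            comparison=comparison,
        )

    flags = [(classify(a), classify(b)) for a, b in pairs]
    outcomes: dict[str, CategoricalSummary] = {}
    for outcome in BINARY_OUTCOMES + COUNT_OUTCOMES:
        ca = sum(getattr(fa, outcome) for fa, _ in flags)
        cb = sum(getattr(fb, outcome) for _, fb in flags)
        entry = dict(
            outcome=outcome,
            n_per_mode=n_pairs,
            count_assisted=ca,
            count_nonassisted=cb,
            pct_assisted=proportion_pct(ca, n_pairs),
            pct_nonassisted=proportion_pct(cb, n_pairs),
            difference=ca - cb,
            difference_pct=_round_half_away(100.0 * (ca - cb) / n_pairs),
        )
        if outcome in BINARY_OUTCOMES:
            b = sum(
                1 for fa, fb in flags if getattr(fa, outcome) and not getattr(fb, outcome)
            )
            c = sum(
                1 for fa, fb in flags if not getattr(fa, outcome) and getattr(fb, outcome)
            )
            entry.update(
                wald_ci_pct=wald_ci_diff(ca / n_pairs, cb / n_pairs, n_pairs),
                discordant_b=b,
                discordant_c=c,
                mcnemar_p=mcnemar_exact(b, c) if b + c else None,
            )
        outcomes[outcome] = CategoricalSummary(**entry)

    return StudySummary(
        n_scans=len(records),
        n_pairs=n_pairs,
        continuous=continuous,
        outcomes=outcomes,
    )


# --------------------------------------------------------------------------
# CSV interchange
# --------------------------------------------------------------------------

_CSV_COLUMNS = [
    "case_id",
    "operator_id",
    "mode",
    "gold_location",
    "gold_ectopic_site",
    "conclusion_location",
    "conclusion_ectopic_site",
    "image_count",
    "duration_min",
    "quality_score",
    "trust_level",
]


def _statement_to_cols(st: DiagnosisStatement) -> tuple[str, str]:
    return st.location_class.value, st.ectopic_site.value if st.ectopic_site else ""


def _statement_from_cols(location: str, site: str) -> DiagnosisStatement:
    return DiagnosisStatement(
        location_class=LocationClass(location),
        ectopic_site=EctopicSite(site) if site else None,
    )


def records_to_csv(records: Sequence[ScanRecord], path) -> None:
    """Write one row per scan with a documented, stable header."""
    rows = []
    for r in records:
        gl, gs = _statement_to_cols(r.gold)
        cl, cs = _statement_to_cols(r.conclusion)
        rows.append(
            {
                "case_id": r.case_id,
                "operator_id": r.operator_id,
                "mode": r.mode,
                "gold_location": gl,
                "gold_ectopic_site": gs,
                "conclusion_location": cl,
                "conclusion_ectopic_site": cs,
                "image_count": r.image_count,
                "duration_min": r.duration_min,
                "quality_score": r.quality_score,
                "trust_level": r.trust_level,
            }
        )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def records_from_csv(path) -> list[ScanRecord]:
    df = pd.read_csv(path, dtype={"case_id": str, "operator_id": str}, keep_default_na=False)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise StatsError(f"missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ScanRecord(
                case_id=str(row.case_id),
                operator_id=str(row.operator_id),
                mode=str(row.mode),
                gold=_statement_from_cols(row.gold_location, row.gold_ectopic_site),
                conclusion=_statement_from_cols(
                    row.conclusion_location, row.conclusion_ectopic_site
                ),
                image_count=int(row.image_count),
                duration_min=float(row.duration_min),
                quality_score=int(row.quality_score),
                trust_level=int(row.trust_level),
            )
        )
    return records
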