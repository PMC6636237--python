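"""Outcome classification and the paired statistical battery."""

import itertools
import math

import numpy as np
import pytest
from scipy import integrate

from scanassist import (
    DiagnosisStatement,
    EctopicSite,
    LocationClass,
    ScanRecord,
    StatsError,
    classify,
    mcnemar_exact,
    paired_t,
    pct_change,
    proportion_pct,
    records_from_csv,
    records_to_csv,
    summarize_study,
    table2_records,
    wald_ci_diff,
    weighted_kappa,
)

IUP = DiagnosisStatement(LocationClass.INTRAUTERINE)
TUBAL = DiagnosisStatement(LocationClass.ECTOPIC, EctopicSite.TUBAL)
EP_UNSPEC = DiagnosisStatement(LocationClass.ECTOPIC, EctopicSite.UNSPECIFIED)
PUL = DiagnosisStatement(LocationClass.PREGNANCY_OF_UNKNOWN_LOCATION)


def record(gold, conclusion, mode="assisted", case="c1", op="t1"):
    return ScanRecord(
        case_id=case,
        operator_id=op,
        mode=mode,
        gold=gold,
        conclusion=conclusion,
        image_count=5,
        duration_min=10.0,
        quality_score=12,
        trust_level=4,
    )


class TestClassify:
    def test_missed_tubal_ep_is_false_negative(self):
        flags = classify(record(gold=TUBAL, conclusion=IUP))
        assert flags.fn_ep and not flags.correct_location
        assert not flags.exact_diagnosis and not flags.fp_ep

    def test_identical_conclusion_is_exact(self):
        for gold in (TUBAL, IUP):
            flags = classify(record(gold=gold, conclusion=gold))
            assert flags.correct_location and flags.exact_diagnosis
            assert not flags.fn_ep and not flags.fp_ep

    def test_ectopic_without_site_is_correct_but_not_exact(self):
        flags = classify(record(gold=TUBAL, conclusion=EP_UNSPEC))
        assert flags.correct_location and not flags.exact_diagnosis

    def test_unknown_location_call_is_never_correct(self):
        """A PUL conclusion neither matches a definite gold location nor
        counts as a false positive; on an ectopic case it is a miss."""
        on_iup = classify(record(gold=IUP, conclusion=PUL))
        assert not on_iup.correct_location and not on_iup.fp_ep
        on_ep = classify(record(gold=TUBAL, conclusion=PUL))
        assert not on_ep.correct_location and on_ep.fn_ep

    def test_flag_implications_hold_exhaustively(self):
        """Exhaust the gold x conclusion cross-product of statements."""
        golds = [IUP, TUBAL]
        sites = [None] + list(EctopicSite)
        conclusions = [IUP, PUL] + [
            DiagnosisStatement(LocationClass.ECTOPIC, s) for s in sites
        ]
        for gold, concl in itertools.product(golds, conclusions):
            flags = classify(record(gold=gold, conclusion=concl))
            if flags.exact_diagnosis:
                assert flags.correct_location
            if flags.fp_ep:
                assert gold.location_class is not LocationClass.ECTOPIC
                assert not flags.correct_location
            if flags.fn_ep:
                assert gold.location_class is LocationClass.ECTOPIC
                assert not flags.correct_location

    def test_gold_must_be_definite(self):
        with pytest.raises(ValueError):
            record(gold=PUL, conclusion=IUP)


class TestProportions:
    @pytest.mark.parametrize(
        "count,n,expected",
        [
            (52, 64, 81),
            (39, 64, 61),
            (49, 64, 77),
            (30, 64, 47),
            (13, 64, 20),
            (19, 64, 30),
            (0, 64, 0),
            (19, 64, 30),
            (1, 64, 2),
            (3, 64, 5),
        ],
    )
    def test_published_percentages_reproduce(self, count, n, expected):
        assert proportion_pct(count, n) == expected

    def test_half_rounds_away_from_zero(self):
        assert proportion_pct(1, 8) == 13  # 12.5
        assert proportion_pct(1, 200) == 1  # 0.5

    def test_invalid_inputs_rejected(self):
        with pytest.raises(StatsError):
            proportion_pct(1, 0)
        with pytest.raises(StatsError):
            proportion_pct(5, 4)

    def test_percent_change_on_printed_means(self):
        assert pct_change(12.5, 10.2) == 23
        assert pct_change(4.64, 6.33) == -27
        assert pct_change(4.12, 3.42) == 20


class TestPairedT:
    def test_hand_computed_example(self):
        cmp = paired_t([1, 2, 3], [2, 4, 6])
        assert cmp.t_statistic == pytest.approx(-3.4641, abs=1e-4)
        assert cmp.degrees_freedom == 2
        assert cmp.difference == pytest.approx(-2.0)

    def test_zero_variance_signaled(self):
        with pytest.raises(StatsError):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        with pytest.raises(StatsError):
            paired_t([1.0, 2.0], [0.0, 1.0])  # constant nonzero difference

    def test_length_mismatch_rejected(self):
        with pytest.raises(StatsError):
            paired_t([1, 2, 3], [1, 2])

    @pytest.mark.parametrize("seed", range(5))
    def test_p_value_matches_quadrature_of_t_density(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 15))
        xs = rng.normal(0.5, 1.0, size=n)
        ys = rng.normal(0.0, 1.0, size=n)
        cmp = paired_t(list(xs), list(ys))
        nu = n - 1

        def density(t):
            return (
                math.gamma((nu + 1) / 2)
                / (math.sqrt(nu * math.pi) * math.gamma(nu / 2))
                * (1 + t * t / nu) ** (-(nu + 1) / 2)
            )

        tail, _ = integrate.quad(density, abs(cmp.t_statistic), np.inf)
        assert cmp.p_value == pytest.approx(2 * tail, rel=1e-6)


class TestMcNemar:
    def test_symmetric_discordance_gives_one(self):
        assert mcnemar_exact(4, 4) == 1.0

    def test_one_sided_discordance_closed_form(self):
        assert mcnemar_exact(13, 0) == pytest.approx(2 * 0.5**13, rel=1e-12)

    def test_fifteen_vs_two(self):
        # lower tail of Binomial(17, 1/2) at 2: (1 + 17 + 136) / 2^17, doubled
        assert mcnemar_exact(15, 2) == pytest.approx(2 * 154 / 2**17, rel=1e-12)
        assert mcnemar_exact(15, 2) == pytest.approx(0.00235, abs=5e-6)

    def test_symmetry_and_range(self):
        for b in range(0, 12):
            for c in range(0, 12):
                if b + c == 0:
                    continue
                p = mcnemar_exact(b, c)
                assert p == mcnemar_exact(c, b)
                assert 0 < p <= 1

    def test_enumeration_oracle_all_small_tables(self):
        for n in range(1, 21):
            for b in range(n + 1):
                c = n - b
                expected = min(
                    1.0,
                    2.0 * sum(math.comb(n, k) for k in range(min(b, c) + 1)) / 2**n,
                )
                assert mcnemar_exact(b, c) == pytest.approx(expected, rel=1e-12)

    def test_no_discordance_signaled(self):
        with pytest.raises(StatsError):
            mcnemar_exact(0, 0)


class TestWeightedKappa:
    def test_perfect_agreement_is_one(self):
        assert weighted_kappa([1, 2, 3, 3], [1, 2, 3, 3], [1, 2, 3]) == 1.0
        assert weighted_kappa([2, 2], [2, 2], [1, 2, 3]) == 1.0

    def test_hand_built_three_category_contingency(self):
        # reversal [1,2,3] vs [3,2,1]: observed disagreement 2 in both
        # schemes; expected 4/3 (linear), 1 (quadratic) from uniform margins
        assert weighted_kappa([1, 2, 3], [3, 2, 1], [1, 2, 3], "linear") == pytest.approx(-0.5)
        assert weighted_kappa([1, 2, 3], [3, 2, 1], [1, 2, 3], "quadratic") == pytest.approx(-1.0)

    def test_matches_independent_implementation(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(7)
        for weights in ("linear", "quadratic"):
            for _ in range(10):
                n = int(rng.integers(5, 40))
                r1 = rng.integers(1, 6, size=n)
                r2 = rng.integers(1, 6, size=n)
                mine = weighted_kappa(list(r1), list(r2), [1, 2, 3, 4, 5], weights)
                ref = sklearn_metrics.cohen_kappa_score(r1, r2, weights=weights)
                assert mine == pytest.approx(ref, abs=1e-12)

    def test_invariant_under_order_preserving_relabeling(self):
        r1, r2 = [1, 3, 5, 3, 1], [1, 5, 5, 1, 3]
        base = weighted_kappa(r1, r2, [1, 3, 5], "linear")
        relabeled = weighted_kappa(
            [{1: "a", 3: "b", 5: "c"}[x] for x in r1],
            [{1: "a", 3: "b", 5: "c"}[x] for x in r2],
            ["a", "b", "c"],
            "linear",
        )
        assert relabeled == pytest.approx(base)

    def test_kappa_never_exceeds_one(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(2, 30))
            r1 = list(rng.integers(1, 4, size=n))
            r2 = list(rng.integers(1, 4, size=n))
            k = weighted_kappa(r1, r2, [1, 2, 3])
            assert k <= 1.0
            if r1 == r2:
                assert k == 1.0

    def test_rating_outside_categories_rejected(self):
        with pytest.raises(StatsError):
            weighted_kappa([1, 9], [1, 2], [1, 2, 3])


class TestWaldCI:
    def test_equal_proportions_centered_at_zero(self):
        low, high = wald_ci_diff(0.5, 0.5, 10_000)
        assert low == pytest.approx(-high)
        assert abs(low) < 2.0

    def test_published_table_marginals_formula(self):
        low, high = wald_ci_diff(52 / 64, 39 / 64, 64)
        assert low == pytest.approx(5.0, abs=0.05)
        assert high == pytest.approx(35.6, abs=0.05)

    def test_width_shrinks_with_n(self):
        widths = [
            wald_ci_diff(0.7, 0.5, n)[1] - wald_ci_diff(0.7, 0.5, n)[0]
            for n in (10, 50, 200, 1000)
        ]
        assert widths == sorted(widths, reverse=True)

    def test_invalid_proportions_rejected(self):
        with pytest.raises(StatsError):
            wald_ci_diff(1.2, 0.5, 10)


class TestSummarizeStudy:
    def test_table2_expansion_reproduces_printed_counts(self):
        summary = summarize_study(table2_records())
        out = summary.outcomes
        assert (out["correct_location"].count_assisted,
                out["correct_location"].count_nonassisted) == (52, 39)
        assert (out["exact_diagnosis"].count_assisted,
                out["exact_diagnosis"].count_nonassisted) == (49, 30)
        assert (out["fn_ep"].count_assisted, out["fn_ep"].count_nonassisted) == (1, 8)
        assert (out["fp_ep"].count_assisted, out["fp_ep"].count_nonassisted) == (3, 3)
        assert out["correct_location"].pct_assisted == 81
        assert out["correct_location"].pct_nonassisted == 61
        assert out["exact_diagnosis"].pct_assisted == 77
        assert out["exact_diagnosis"].pct_nonassisted == 47
        assert out["correct_location"].difference_pct == 20
        assert out["exact_diagnosis"].difference_pct == 30

    def test_unpaired_records_rejected(self):
        records = [record(TUBAL, TUBAL, mode="assisted", case="c1")]
        with pytest.raises(StatsError, match="unpaired"):
            summarize_study(records)

    @pytest.mark.parametrize("seed", range(3))
    def test_summary_means_equal_brute_force_arithmetic(self, seed):
        rng = np.random.default_rng(seed)
        records = []
        for i in range(12):
            for mode in ("assisted", "nonassisted"):
                records.append(
                    ScanRecord(
                        case_id=f"c{i}",
                        operator_id="t1",
                        mode=mode,
                        gold=TUBAL if i % 2 else IUP,
                        conclusion=TUBAL if rng.random() < 0.5 else IUP,
                        image_count=int(rng.integers(1, 10)),
                        duration_min=float(rng.uniform(3, 20)),
                        quality_score=int(rng.integers(0, 16)),
                        trust_level=int(rng.integers(1, 6)),
                    )
                )
        summary = summarize_study(records)
        for metric in ("image_count", "duration_min", "quality_score", "trust_level"):
            expected_a = np.mean(
                [getattr(r, metric) for r in records if r.mode == "assisted"]
            )
            expected_n = np.mean(
                [getattr(r, metric) for r in records if r.mode == "nonassisted"]
            )
            cmp = summary.continuous[metric].comparison
            assert cmp.mean_assisted == pytest.approx(expected_a)
            assert cmp.mean_nonassisted == pytest.approx(expected_n)
            assert cmp.difference == pytest.approx(expected_a - expected_n)

    def test_single_identical_pair_has_zero_count_differences(self):
        records = [
            record(TUBAL, TUBAL, mode="assisted"),
            record(TUBAL, TUBAL, mode="nonassisted"),
        ]
        # continuous t tests are undefined on one pair; check counts directly
        with pytest.raises(StatsError):
            summarize_study(records)
        flags = [classify(r) for r in records]
        assert flags[0] == flags[1]


class TestCsvRoundTrip:
    def test_records_survive_csv_round_trip(self, tmp_path):
        records = table2_records()
        path = tmp_path / "records.csv"
        records_to_csv(records, path)
        assert records_from_csv(path) == records

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("case_id,mode\nc1,assisted\n")
        with pytest.raises(StatsError, match="missing columns"):
            records_from_csv(path)
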