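"""Enrichment statistics: co-occurrence, overlap null model, metrics."""

import math

import numpy as np
import pytest
from scipy import stats

from repeatcc.enrichment import (
    OverlapRecord,
    PhyloPoint,
    a4_q4_ratio,
    cc_association_test,
    cooccurrence_test,
    expected_overlap,
    normalized_overlap_metric,
    overlap_class_test,
    permutation_oracle,
    phylo_correlation,
    summarize_proteome,
)
from repeatcc.repeats import RepeatFlags


def make_flags(spec):
    """Flags from a list of (hasQ, hasA, hasQA) triples."""
    return [
        RepeatFlags(f"p{i}", q, a, qa) for i, (q, a, qa) in enumerate(spec)
    ]


def yates_chi2(table):
    """Textbook Yates-corrected chi-squared on a 2x2 table."""
    table = np.asarray(table, dtype=float)
    rows, cols, n = table.sum(1), table.sum(0), table.sum()
    expected = np.outer(rows, cols) / n
    return float(
        ((np.maximum(np.abs(table - expected) - 0.5, 0)) ** 2 / expected).sum()
    )


class TestSummarize:
    def test_four_protein_example(self):
        flags = make_flags(
            [(True, False, False), (False, True, False),
             (True, True, False), (False, False, False)]
        )
        s = summarize_proteome(flags)
        assert s.percent("Q4") == 50.0
        assert s.percent("A4") == 50.0
        assert s.percent("Q4", "A4") == 25.0

    def test_empty_proteome_is_error(self):
        with pytest.raises(ValueError):
            summarize_proteome([])

    def test_key_mismatch_lists_ids(self):
        flags = make_flags([(True, False, False)])
        with pytest.raises(ValueError, match="p0"):
            summarize_proteome(flags, cc_flags={"other": True})

    def test_marginals_reconstituted_from_venn(self):
        rng = np.random.default_rng(5)
        flags = [
            RepeatFlags(f"p{i}", *(rng.random(3) < 0.4)) for i in range(500)
        ]
        s = summarize_proteome(flags)
        only_q = sum(f.has_Q4 and not f.has_A4 for f in flags)
        assert only_q + s.count("Q4", "A4") == s.count("Q4")

    def test_planted_prevalence_recovered(self):
        from repeatcc.simulate import ProteomeSpec, draw_repeat_flags

        spec = ProteomeSpec(n_proteins=20_000, p_Q4=0.05, cooccurrence_factor=1.0)
        df = draw_repeat_flags(spec, np.random.default_rng(3))
        flags = [
            RepeatFlags(r.protein_id, r.has_Q4, r.has_A4, r.has_QA4)
            for r in df.itertuples()
        ]
        s = summarize_proteome(flags)
        se = 100 * math.sqrt(0.05 * 0.95 / 20_000)
        assert abs(s.percent("Q4") - 5.0) <= 3 * se


class TestCooccurrence:
    def test_exact_independence(self):
        res = cooccurrence_test(100, 200, 20, 1000)
        assert res.expected == 20.0
        assert res.ratio == 1.0
        assert res.chi2 <= 1e-9
        assert res.p_value > 0.99

    def test_complete_nesting(self):
        res = cooccurrence_test(10, 10, 10, 100)
        assert res.ratio == 10.0
        assert res.p_value < 0.001

    def test_zero_margin_flagged(self):
        res = cooccurrence_test(0, 10, 0, 100)
        assert res.undefined and math.isnan(res.ratio)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            cooccurrence_test(10, 10, 11, 100)

    def test_matches_textbook_yates_formula(self, rng):
        for _ in range(200):
            N = int(rng.integers(50, 2000))
            n_a = int(rng.integers(1, N // 2))
            n_b = int(rng.integers(1, N // 2))
            n_ab = int(rng.integers(0, min(n_a, n_b) + 1))
            res = cooccurrence_test(n_a, n_b, n_ab, N)
            table = [[n_ab, n_a - n_ab], [n_b - n_ab, N - n_a - n_b + n_ab]]
            assert res.chi2 == pytest.approx(yates_chi2(table), abs=1e-9)

    def test_yates_not_larger_than_uncorrected(self):
        res = cooccurrence_test(100, 200, 25, 1000)
        table = np.array([[25, 75], [175, 725]])
        uncorrected, _, _, _ = stats.chi2_contingency(table, correction=False)
        assert res.chi2 <= uncorrected

    def test_fisher_alternative(self):
        res = cooccurrence_test(10, 10, 10, 100, method="fisher")
        assert res.p_value < 0.001 and math.isnan(res.chi2)

    def test_cc_association_wraps_cooccurrence(self):
        flags = make_flags(
            [(True, False, False)] * 10 + [(False, False, False)] * 90
        )
        cc = {f.protein_id: i < 20 for i, f in enumerate(flags)}
        s = summarize_proteome(flags, cc)
        res = cc_association_test(s, "Q4")
        direct = cooccurrence_test(10, 20, 10, 100)
        assert res.observed == direct.observed
        assert res.expected == direct.expected


class TestOverlapNull:
    def test_formula(self):
        assert expected_overlap(100, 50, 10) == 5.0
        assert expected_overlap(100, 0, 10) == 0.0

    def test_zero_length_protein_rejected(self):
        with pytest.raises(ValueError):
            expected_overlap(0, 0, 0)

    def test_single_residue_collision_probability(self):
        mean, se = permutation_oracle(10, [1], [1], n_iter=100_000, seed=2)
        assert mean == pytest.approx(0.1, abs=3 * max(se, 1e-4))

    def test_full_coverage_is_deterministic(self):
        mean, se = permutation_oracle(50, [50], [7], n_iter=500, seed=2)
        assert mean == 7.0 and se == 0.0

    def test_formula_within_monte_carlo_error_short_segments(self, rng):
        for _ in range(10):
            L = 2000
            cc_lens = list(rng.integers(3, 9, size=int(rng.integers(1, 4))))
            rep_lens = list(rng.integers(3, 9, size=int(rng.integers(1, 4))))
            mean, se = permutation_oracle(L, cc_lens, rep_lens, n_iter=30_000,
                                          seed=int(rng.integers(2**31)))
            formula = expected_overlap(L, int(np.sum(cc_lens)), int(np.sum(rep_lens)))
            assert abs(mean - formula) <= 3 * se + 1e-12

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError):
            permutation_oracle(10, [6, 6], [1], n_iter=10, seed=0)


class TestOverlapClassTest:
    def test_cc_covers_whole_protein_gives_unit_ratio(self):
        records = [
            OverlapRecord(f"p{i}", 100, 100, rep, rep, expected_overlap(100, 100, rep))
            for i, rep in enumerate([2, 3, 4, 5, 8, 10])
        ]
        res = overlap_class_test(records, overlap_threshold=4)
        assert res.observed == 4 and res.expected == 4 and res.ratio == 1.0

    def test_disjoint_planted_features_give_zero_observed(self):
        records = [
            OverlapRecord(f"p{i}", 1000, 10, 10, 0, expected_overlap(1000, 10, 10))
            for i in range(20)
        ] + [OverlapRecord("anchor", 10, 8, 8, 8, 6.4)]
        res = overlap_class_test(records, overlap_threshold=4)
        assert res.observed == 1  # only the anchor protein reaches 4 residues

    def test_excludes_proteins_missing_either_feature(self):
        records = [
            OverlapRecord("both", 100, 20, 20, 20, 4.0),
            OverlapRecord("no_cc", 100, 0, 20, 0, 0.0),
            OverlapRecord("no_rep", 100, 20, 0, 0, 0.0),
        ]
        with pytest.raises(ValueError):
            overlap_class_test([records[1], records[2]])
        res = overlap_class_test(records)
        assert res.observed == 1

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            overlap_class_test([])


class TestScalarMetrics:
    def test_a4_q4_ratio(self):
        flags = make_flags(
            [(True, True, False)] * 10 + [(False, False, False)] * 10
        )
        s = summarize_proteome(flags)
        assert a4_q4_ratio(s) == 1.0

    def test_printed_percentages_consistency(self):
        """%A4 = 7.73, %Q4 = 2.29 imply a ratio of ~3.375."""
        flags = make_flags(
            [(True, True, False)] * 229
            + [(False, True, False)] * (773 - 229)
            + [(False, False, False)] * (10_000 - 773)
        )
        s = summarize_proteome(flags)
        assert s.percent("Q4") == pytest.approx(2.29)
        assert s.percent("A4") == pytest.approx(7.73)
        assert a4_q4_ratio(s) == pytest.approx(7.73 / 2.29)
        assert a4_q4_ratio(s) == pytest.approx(3.375, abs=0.005)

    def test_zero_q4_flagged(self):
        s = summarize_proteome(make_flags([(False, True, False)] * 4))
        assert math.isnan(a4_q4_ratio(s))

    def test_normalized_overlap_metric(self):
        # %(Q4&A4) = 2, %A4 = 4 -> 0.125
        flags = make_flags(
            [(True, True, False)] * 2 + [(False, True, False)] * 2
            + [(False, False, False)] * 96
        )
        s = summarize_proteome(flags)
        assert normalized_overlap_metric(s) == pytest.approx(2 / 16)

    def test_normalized_metric_algebraic_identity(self):
        # when every A4 protein is also Q4, the metric is 1/%A4
        flags = make_flags([(True, True, False)] * 5 + [(False, False, False)] * 45)
        s = summarize_proteome(flags)
        assert normalized_overlap_metric(s) == pytest.approx(1 / s.percent("A4"))

    def test_metric_monotone_in_conditional_cooccurrence(self):
        values = []
        for n_joint in (40, 30, 20, 10):
            flags = make_flags(
                [(True, True, False)] * n_joint
                + [(False, True, False)] * (50 - n_joint)
                + [(False, False, False)] * 950
            )
            values.append(normalized_overlap_metric(summarize_proteome(flags)))
        assert values == sorted(values, reverse=True)


class TestPhyloCorrelation:
    def test_exact_negative_line(self):
        pts = [PhyloPoint(f"s{i}", float(m), 5 - 0.01 * m) for i, m in
               enumerate([0, 100, 300, 700, 900, 1100])]
        res = phylo_correlation(pts)
        assert res.r == pytest.approx(-1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_values_flagged(self):
        pts = [PhyloPoint(f"s{i}", float(i * 100), 2.0) for i in range(5)]
        res = phylo_correlation(pts)
        assert res.note and math.isnan(res.r)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            phylo_correlation([PhyloPoint("a", 0, 1), PhyloPoint("b", 1, 2)])

    def test_matches_manual_covariance_formula(self, rng):
        x = rng.uniform(0, 1000, 30)
        y = rng.normal(0, 1, 30) + 0.001 * x
        pts = [PhyloPoint(f"s{i}", float(a), float(b)) for i, (a, b) in
               enumerate(zip(x, y))]
        res = phylo_correlation(pts)
        manual = (
            np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
        )
        assert res.r == pytest.approx(float(manual), abs=1e-12)
        assert res.r_squared == pytest.approx(res.r**2)
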