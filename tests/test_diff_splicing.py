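import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snisplice.benchmarks import by_stepup_formula, hypergeom_fisher_p
from snisplice.diff_splicing import (
    age_matched_check,
    by_adjust,
    coverage_filter,
    delta_psi,
    fisher_exact_2x2,
    psi,
    sample_ordering_filter,
    sample_support_filter,
)
from snisplice.diff_splicing import test_exons as run_exon_tests


class TestPsi:
    def test_printed_excitatory_example(self):
        # 90% inclusion in controls vs 83% in cases: -7 percentage points
        d = delta_psi(psi(83, 17), psi(90, 10))
        assert d == pytest.approx(-0.07)

    def test_printed_inhibitory_example(self):
        # 90% vs 37%: -53 percentage points
        d = delta_psi(psi(37, 63), psi(90, 10))
        assert d == pytest.approx(-0.53)

    def test_all_exclusion_reads_give_zero_psi(self):
        assert psi(0, 10) == 0.0

    def test_no_informative_reads_is_undefined(self):
        assert math.isnan(psi(0, 0))


class TestFisherExact:
    def test_balanced_table_p_one(self):
        p, gate = fisher_exact_2x2([[5, 5], [5, 5]])
        assert p == pytest.approx(1.0)
        assert gate

    def test_small_diagonal_table_p_and_failed_gate(self):
        # enumeration over a=0..3 gives p = 2/C(6,3) = 0.1; expected counts 1.5
        p, gate = fisher_exact_2x2([[3, 0], [0, 3]])
        assert p == pytest.approx(0.1)
        assert not gate

    def test_strong_diagonal_table_passes_gate(self):
        p, gate = fisher_exact_2x2([[10, 0], [0, 10]])
        assert p == pytest.approx(2 / math.comb(20, 10))
        assert gate

    def test_zero_margin_fails_gate_with_undefined_p(self):
        p, gate = fisher_exact_2x2([[0, 0], [5, 5]])
        assert math.isnan(p)
        assert not gate

    def test_negative_or_fractional_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [2, 2]])
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1.5, 1], [2, 2]])

    @given(
        st.tuples(*[st.integers(min_value=0, max_value=20)] * 4)
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_hypergeometric_enumeration(self, cells):
        a, b, c, d = cells
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        p, _ = fisher_exact_2x2([[a, b], [c, d]])
        assert p == pytest.approx(hypergeom_fisher_p([[a, b], [c, d]]), abs=1e-10)

    def test_scaling_counts_never_increases_p(self):
        for table in ([[12, 8], [7, 13]], [[20, 10], [10, 20]], [[9, 1], [5, 5]]):
            p1, _ = fisher_exact_2x2(table)
            p2, _ = fisher_exact_2x2([[4 * x for x in row] for row in table])
            assert p2 <= p1 + 1e-12


class TestByAdjust:
    def test_hand_worked_three_values(self):
        # m=3, c(3)=11/6: 0.01*3*(11/6)/1 = 0.055, step-up ties the first two
        q = by_adjust([0.01, 0.02, 0.9])
        assert q == pytest.approx([0.055, 0.055, 1.0])

    def test_single_value_unchanged(self):
        assert by_adjust([0.2]) == pytest.approx([0.2])

    def test_rejects_values_outside_unit_interval(self):
        with pytest.raises(ValueError):
            by_adjust([0.5, 1.2])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_matches_stepup_formula_dominates_p_and_permutation_invariant(self, ps):
        q = by_adjust(ps)
        assert np.allclose(q, by_stepup_formula(ps), atol=1e-12)
        assert (q >= np.asarray(ps) - 1e-12).all()
        perm = np.random.default_rng(0).permutation(len(ps))
        q_perm = by_adjust([ps[i] for i in perm])
        assert np.allclose(q_perm, q[perm])

    def test_dominates_benjamini_hochberg(self):
        from statsmodels.stats.multitest import multipletests

        ps = [0.001, 0.01, 0.02, 0.2, 0.5, 0.9]
        q_by = by_adjust(ps)
        q_bh = multipletests(ps, method="fdr_bh")[1]
        assert (q_by >= q_bh - 1e-12).all()


class TestSampleFilters:
    def test_support_boundary_four_of_six(self):
        four = [1, 2, 3, 1, 0, 0]
        three = [1, 2, 3, 0, 0, 0]
        assert sample_support_filter(four, four)
        assert not sample_support_filter(three, four)
        assert sample_support_filter([1] * 6, [1] * 6)

    def test_ordering_complete_separation_passes(self):
        assert sample_ordering_filter(
            [0.3, 0.2, 0.1], [0.9, 0.8, 0.7], pooled_direction=1.0
        )

    def test_ordering_swapped_roles_when_cases_higher(self):
        # cases {0.8,0.7,0.6} vs controls {0.9,0.2,0.1}: each of the 3 cases
        # beats 2 controls, so >= 2 cases beat >= 2 controls -> pass
        assert sample_ordering_filter(
            [0.8, 0.7, 0.6], [0.9, 0.2, 0.1], pooled_direction=-1.0
        )

    def test_ordering_all_ties_fail(self):
        assert not sample_ordering_filter(
            [0.5] * 3, [0.5] * 3, pooled_direction=1.0
        )
        assert not sample_ordering_filter([0.5] * 3, [0.5] * 3, pooled_direction=0.0)

    def test_ordering_requires_informative_samples(self):
        assert not sample_ordering_filter([], [0.5, 0.6], pooled_direction=1.0)

    def test_coverage_boundary(self):
        assert coverage_filter(4, 4, 10)  # exactly 0.8
        assert not coverage_filter(4, 3, 10)
        assert coverage_filter(6, 4, 10, threshold=0.8)
        assert not coverage_filter(0, 0, 0)


def _counts_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "exon_start", "exon_end", "strand",
                 "source", "cell_type", "condition", "sample_id",
                 "inclusion", "exclusion", "total"],
    )


def _exon_rows(gene, incl_case, excl_case, incl_ctrl, excl_ctrl, n_samples=6,
               cell_type="ExN", extra_total=0):
    """Spread condition totals evenly over samples."""
    rows = []
    for cond, inc, exc in (("case", incl_case, excl_case),
                           ("control", incl_ctrl, excl_ctrl)):
        for i in range(n_samples):
            inc_i = inc // n_samples + (1 if i < inc % n_samples else 0)
            exc_i = exc // n_samples + (1 if i < exc % n_samples else 0)
            tot_i = inc_i + exc_i + (extra_total if i == 0 else 0)
            rows.append((gene, "chr1", 1800, 1899, "+", "annotated",
                         cell_type, cond, f"{cond}{i + 1}", inc_i, exc_i, tot_i))
    return rows


class TestTestExons:
    def test_strong_effect_called_significant(self):
        counts = _counts_frame(_exon_rows("g1", 90, 30, 30, 90))
        res = run_exon_tests(counts)
        row = res.iloc[0]
        assert row.significant
        assert row.delta_psi == pytest.approx(0.5)
        assert row.q_by <= 0.05

    def test_small_delta_psi_blocks_significance(self):
        # large counts make q tiny, but |delta psi| = 0.15 < 0.20
        counts = _counts_frame(_exon_rows("g1", 3000, 2000, 2250, 2750))
        res = run_exon_tests(counts)
        row = res.iloc[0]
        assert row.q_by <= 0.05
        assert abs(row.delta_psi) == pytest.approx(0.15, abs=0.001)
        assert not row.significant
        assert "delta_psi_min" in row.reason

    def test_psi_out_of_bounds_not_assessed(self):
        counts = _counts_frame(_exon_rows("g1", 118, 2, 116, 4))
        res = run_exon_tests(counts)
        row = res.iloc[0]
        assert not row.flag_psi_range
        assert math.isnan(row.q_by)

    def test_min_reads_per_condition_enforced(self):
        counts = _counts_frame(_exon_rows("g1", 5, 4, 60, 60))
        res = run_exon_tests(counts)
        assert not res.iloc[0].flag_min_reads
        assert not res.iloc[0].significant

    def test_coverage_failure_blocks(self):
        counts = _counts_frame(
            _exon_rows("g1", 90, 30, 30, 90, extra_total=40)
        )
        res = run_exon_tests(counts)
        assert not res.iloc[0].flag_coverage
        assert not res.iloc[0].significant

    def test_by_family_is_per_cell_type(self):
        rows = []
        for i in range(4):
            rows += _exon_rows(f"g{i}", 90, 30, 30, 90, cell_type="ExN")
        rows += _exon_rows("h1", 90, 30, 30, 90, cell_type="Astro")
        res = run_exon_tests(_counts_frame(rows))
        exn = res[res.cell_type == "ExN"]
        astro = res[res.cell_type == "Astro"]
        # same raw p, but the ExN family is larger, so its q is at least as big
        assert astro.iloc[0].q_by <= exn.q_by.max() + 1e-12
        assert len(exn) == 4 and len(astro) == 1


class TestAgeMatchedCheck:
    # full-group means 67.5 vs 75.5 years; the best age-matched 4-sample
    # subsets uniquely drop case1/case6 (youngest cases) and
    # control3/control4 (oldest controls)
    ages = {
        "case1": 60, "case2": 65, "case3": 70, "case4": 72, "case5": 74,
        "case6": 64, "control1": 75, "control2": 78, "control3": 80,
        "control4": 82, "control5": 70, "control6": 68,
    }

    @staticmethod
    def _planted_counts(subset_case, extreme_case, subset_ctrl, extreme_ctrl):
        """Per-sample counts with distinct planted effects in the samples
        inside vs outside the age-matched subsets."""
        rows = []
        for i in range(1, 7):
            inc, exc = extreme_case if i in (1, 6) else subset_case
            rows.append(("g1", "chr1", 1800, 1899, "+", "annotated",
                         "ExN", "case", f"case{i}", inc, exc, inc + exc))
        for i in range(1, 7):
            inc, exc = extreme_ctrl if i in (3, 4) else subset_ctrl
            rows.append(("g1", "chr1", 1800, 1899, "+", "annotated",
                         "ExN", "control", f"control{i}", inc, exc, inc + exc))
        return _counts_frame(rows)

    def test_subset_keeping_exactly_half_the_effect_passes(self):
        # full delta psi 0.30, age-matched subset delta psi 0.15
        counts = self._planted_counts((15, 85), (60, 40), (0, 100), (0, 100))
        res = run_exon_tests(counts)
        checked = age_matched_check(res, counts, self.ages)
        row = checked.iloc[0]
        assert row.delta_psi == pytest.approx(0.30)
        assert row.age_match_status == "evaluated"
        assert row.flag_age_match

    def test_subset_below_half_retention_fails(self):
        # full delta psi 0.30, subset only 0.10
        counts = self._planted_counts((10, 90), (70, 30), (0, 100), (0, 100))
        res = run_exon_tests(counts)
        checked = age_matched_check(res, counts, self.ages)
        row = checked.iloc[0]
        assert row.delta_psi == pytest.approx(0.30)
        assert not row.flag_age_match

    def test_sign_flip_in_matched_subset_fails(self):
        # subset samples carry a negative effect; extreme-age samples push
        # the full pooled delta psi positive
        counts = self._planted_counts((10, 30), (200, 0), (15, 25), (0, 200))
        res = run_exon_tests(counts)
        checked = age_matched_check(res, counts, self.ages)
        row = checked.iloc[0]
        assert row.delta_psi > 0
        assert not row.flag_age_match

    def test_too_few_samples_leaves_flag_undefined(self):
        counts = _counts_frame(_exon_rows("g1", 40, 20, 20, 40, n_samples=3))
        res = run_exon_tests(counts)
        ages = {f"case{i}": 70 for i in range(1, 4)}
        ages.update({f"control{i}": 70 for i in range(1, 4)})
        checked = age_matched_check(res, counts, ages)
        assert (checked["age_match_status"] == "undefined").all()
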