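import numpy as np
import pandas as pd
import pytest
from scipy import stats

from snisplice.comparative import (
    de_gene_set,
    delta_psi_correlation,
    expression_overlap,
    pseudobulk_masking,
)


def results_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "exon_start", "exon_end", "strand",
                 "cell_type", "delta_psi", "q_by", "significant"],
    )


def exon_row(gene, cell_type="ExN", dpsi=0.3, q=0.01, sig=True, start=100):
    return (gene, "chr1", start, start + 99, "+", cell_type, dpsi, q, sig)


class TestPseudobulkMasking:
    def test_masked_fraction_with_wilson_interval(self):
        ct = results_frame(
            [exon_row(f"g{i}", sig=True, start=100 * i) for i in range(10)]
        )
        pb = results_frame(
            [exon_row(f"g{i}", cell_type="pseudobulk", sig=i >= 2,
                      start=100 * i) for i in range(10)]
        )
        (s,) = pseudobulk_masking(ct, pb)
        assert (s.n_significant, s.n_masked) == (10, 2)
        assert s.fraction_masked == pytest.approx(0.2)
        lo, hi = stats.binomtest(2, 10).proportion_ci(0.95, method="wilson")
        assert (s.ci_low, s.ci_high) == (pytest.approx(lo), pytest.approx(hi))
        assert s.ci_low <= s.fraction_masked <= s.ci_high

    def test_all_significant_in_both_gives_zero_fraction(self):
        ct = results_frame([exon_row("g1"), exon_row("g2", start=300)])
        pb = ct.assign(cell_type="pseudobulk")
        (s,) = pseudobulk_masking(ct, pb)
        assert s.n_masked == 0 and s.fraction_masked == 0.0

    def test_exon_absent_from_pseudobulk_counts_as_masked_and_logged(self):
        ct = results_frame([exon_row("g1"), exon_row("g2", start=300)])
        pb = results_frame([exon_row("g1", cell_type="pseudobulk")])
        (s,) = pseudobulk_masking(ct, pb)
        assert s.n_masked == 1
        assert s.n_untested_in_pseudobulk == 1

    def test_single_cell_type_dataset_masks_nothing(self):
        """With one cell type, pseudobulk pooling is the identity, so the
        pseudobulk run reproduces the cell type's calls exactly."""
        from snisplice.benchmarks import run_exon_pipeline
        from snisplice.simulate import planted_effect_config

        cfg = planted_effect_config(
            4, psi_case=0.8, psi_control=0.3, cell_types={"ExN": 20},
            reads_per_cell_mean=2.0, seed=6,
        )
        ct_res = run_exon_pipeline(cfg)
        pb_res = run_exon_pipeline(cfg, pseudobulk=True)
        assert int(ct_res["significant"].sum()) > 0
        (s,) = pseudobulk_masking(ct_res, pb_res)
        assert s.n_masked == 0

    def test_row_order_invariance(self):
        rows = [exon_row(f"g{i}", sig=i % 2 == 0, start=100 * i) for i in range(8)]
        ct = results_frame(rows)
        pb = results_frame(
            [exon_row(f"g{i}", cell_type="pseudobulk", sig=i < 2,
                      start=100 * i) for i in range(8)]
        )
        (a,) = pseudobulk_masking(ct, pb)
        (b,) = pseudobulk_masking(ct.iloc[::-1], pb.iloc[::-1])
        assert (a.n_masked, a.fraction_masked) == (b.n_masked, b.fraction_masked)


class TestDeltaPsiCorrelation:
    def test_identical_vectors_give_r_one(self):
        a = results_frame(
            [exon_row(f"g{i}", dpsi=0.1 * i - 0.3, start=100 * i) for i in range(6)]
        )
        b = a.assign(cell_type="Astro")
        out = delta_psi_correlation(a, b)
        assert out["defined"] and out["r"] == pytest.approx(1.0)

    def test_constant_stratum_is_undefined(self):
        a = results_frame(
            [exon_row(f"g{i}", dpsi=0.25, start=100 * i) for i in range(5)]
        )
        b = results_frame(
            [exon_row(f"g{i}", dpsi=0.1 * i, cell_type="B", start=100 * i)
             for i in range(5)]
        )
        assert not delta_psi_correlation(a, b)["defined"]

    def test_fewer_than_three_pairs_undefined(self):
        a = results_frame([exon_row("g1"), exon_row("g2", start=300)])
        b = a.assign(cell_type="B")
        assert not delta_psi_correlation(a.iloc[:1], b.iloc[:1])["defined"]

    def test_bivariate_normal_recovery_covers_truth(self):
        """The Fisher-z 95% CI on r covers rho=0.75 in >= 93% of sampling
        replicates (n=200 exon pairs per replicate)."""
        rng = np.random.default_rng(12)
        rho = 0.75
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            cov = [[1, rho], [rho, 1]]
            xy = rng.multivariate_normal([0, 0], cov, size=200) * 0.2
            a = results_frame(
                [exon_row(f"g{i}", dpsi=xy[i, 0], start=100 * i)
                 for i in range(200)]
            )
            b = results_frame(
                [exon_row(f"g{i}", dpsi=xy[i, 1], cell_type="B", start=100 * i)
                 for i in range(200)]
            )
            out = delta_psi_correlation(a, b)
            hits += out["ci95_low"] <= rho <= out["ci95_high"]
        assert hits / n_rep >= 0.93

    def test_selection_restricts_to_significant_in_either(self):
        a = results_frame(
            [exon_row(f"g{i}", dpsi=0.1 * i, sig=i < 3, start=100 * i)
             for i in range(6)]
        )
        b = a.assign(cell_type="B", significant=False)
        out = delta_psi_correlation(a, b)
        assert out["n_pairs"] == 3
        assert delta_psi_correlation(a, b, selection="all")["n_pairs"] == 6


class TestExpressionOverlap:
    def test_worked_odds_ratio_of_eight(self):
        # table [[5,5],[10,80]] -> OR = (5*80)/(5*10) = 8
        universe = {f"g{i}" for i in range(100)}
        spliced = {f"g{i}" for i in range(10)}
        de = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(10, 20)}
        r = expression_overlap(spliced, de, universe)
        assert r.table == [[5, 5], [10, 80]]
        assert r.odds_ratio == pytest.approx(8.0)
        assert r.odds_ratio_corrected is None

    def test_zero_cell_gets_corrected_odds_ratio(self):
        universe = {f"g{i}" for i in range(50)}
        spliced = {"g1", "g2"}
        de = {"g10", "g11"}
        r = expression_overlap(spliced, de, universe)
        assert r.both == 0 and r.odds_ratio == 0.0
        expected = (0.5 * 46.5) / (2.5 * 2.5)
        assert r.odds_ratio_corrected == pytest.approx(expected)

    def test_genes_outside_universe_excluded(self):
        universe = {"g1", "g2", "g3", "g4"}
        r = expression_overlap({"g1", "x1"}, {"g1", "x2"}, universe)
        assert r.both == 1
        assert r.both + r.spliced_only + r.de_only + r.neither == 4

    def test_empty_universe_is_error(self):
        with pytest.raises(ValueError):
            expression_overlap({"g1"}, {"g1"}, set())

    def test_independent_sets_give_odds_ratio_near_one(self):
        """Null calibration: with independently drawn gene sets the median
        OR over replicates sits near 1."""
        rng = np.random.default_rng(99)
        universe = [f"g{i}" for i in range(500)]
        ors = []
        for _ in range(200):
            spliced = set(rng.choice(universe, size=60, replace=False))
            de = set(rng.choice(universe, size=60, replace=False))
            r = expression_overlap(spliced, de, set(universe))
            if np.isfinite(r.odds_ratio) and r.odds_ratio > 0:
                ors.append(r.odds_ratio)
        assert 0.8 <= float(np.median(ors)) <= 1.25

    def test_de_gene_set_thresholds(self):
        de = pd.DataFrame({
            "gene_id": ["a", "b", "c", "d"],
            "log2FC": [0.5, 0.05, -0.2, 0.3],
            "fdr": [0.01, 0.01, 0.2, 0.04],
            "cell_type": ["ExN"] * 4,
        })
        sig, universe = de_gene_set(de, cell_type="ExN")
        assert sig == {"a", "d"}  # |log2FC| >= 0.1 and FDR <= 0.05
        assert universe == {"a", "b", "c", "d"}
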