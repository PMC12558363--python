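"""Cross-stratum analyses.

* pseudobulk masking — which cell-type-significant exons disappear when all
  cell types are pooled per condition,
* delta-psi correlation between two strata,
* overlap between differentially spliced and differentially expressed genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .diff_splicing import EXON_KEY


@dataclass
class MaskingSummary:
    """Fraction of a cell type's significant exons invisible in pseudobulk."""

    cell_type: str
    n_significant: int
    n_masked: int
    n_untested_in_pseudobulk: int  # subset of n_masked, logged distinctly
    fraction_masked: float
    ci_low: float
    ci_high: float


def pseudobulk_masking(
    celltype_results: pd.DataFrame, pseudobulk_results: pd.DataFrame
) -> list[MaskingSummary]:
    """Per cell type: exons significant there but not in pseudobulk.

    The pseudobulk table must come from :func:`test_exons` on the same reads
    with cell-type labels merged (sample identity kept) under identical
    criteria.  Exons absent from the pseudobulk table count as masked and
    are reported separately.  The 95% CI on the masked fraction is a Wilson
    score interval.
    """
    pb_sig = {
        tuple(row[k] for k in EXON_KEY)
        for _, row in pseudobulk_results[pseudobulk_results["significant"]].iterrows()
    }
    pb_all = {
        tuple(row[k] for k in EXON_KEY)
        for _, row in pseudobulk_results.iterrows()
    }
    out = []
    for cell_type, sub in celltype_results.groupby("cell_type"):
        sig = sub[sub["significant"]]
        n_sig = len(sig)
        n_masked = 0
        n_untested = 0
        for _, row in sig.iterrows():
            key = tuple(row[k] for k in EXON_KEY)
            if key not in pb_sig:
                n_masked += 1
                if key not in pb_all:
                    n_untested += 1
        if n_sig:
            frac = n_masked / n_sig
            lo, hi = proportion_confint(n_masked, n_sig, alpha=0.05, method="wilson")
        else:
            frac, lo, hi = float("nan"), float("nan"), float("nan")
        out.append(
            MaskingSummary(cell_type, n_sig, n_masked, n_untested, frac, lo, hi)
        )
    return out


def masking_to_frame(summaries: list[MaskingSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.cell_type, s.n_significant, s.n_masked,
             s.n_untested_in_pseudobulk, s.fraction_masked, s.ci_low, s.ci_high)
            for s in summaries
        ],
        columns=["cell_type", "n_significant", "n_masked",
                 "n_untested_in_pseudobulk", "fraction_masked",
                 "ci95_low", "ci95_high"],
    )


def delta_psi_correlation(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    selection: str = "either_significant",
) -> dict:
    """Pearson correlation of delta psi between two strata.

    Exons must be quantifiable (tested, delta psi defined) in both strata;
    ``selection`` restricts pairs to exons significant in at least one
    stratum (``"either_significant"``) or keeps all shared exons
    (``"all"``).  The 95% CI comes from the Fisher z-transform.  With fewer
    than 3 pairs or zero variance the correlation is reported undefined.
    """
    cols = EXON_KEY + ["delta_psi", "significant"]
    a = results_a[cols].dropna(subset=["delta_psi"]).set_index(EXON_KEY)
    b = results_b[cols].dropna(subset=["delta_psi"]).set_index(EXON_KEY)
    joined = a.join(b, how="inner", lsuffix="_a", rsuffix="_b")
    if selection == "either_significant":
        joined = joined[joined["significant_a"] | joined["significant_b"]]
    elif selection != "all":
        raise ValueError(f"unknown selection {selection!r}")

    n = len(joined)
    base = {"n_pairs": n, "r": float("nan"), "ci95_low": float("nan"),
            "ci95_high": float("nan"), "defined": False}
    if n < 3:
        return base
    x = joined["delta_psi_a"].to_numpy()
    y = joined["delta_psi_b"].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        return base
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval(confidence_level=0.95)
    return {"n_pairs": n, "r": float(res.statistic),
            "ci95_low": float(ci.low), "ci95_high": float(ci.high),
            "defined": True}


@dataclass
class OverlapResult:
    """Splicing-vs-expression gene overlap in the doubly-tested universe."""

    cell_type: str
    both: int
    spliced_only: int
    de_only: int
    neither: int
    odds_ratio: float
    odds_ratio_corrected: float | None  # Haldane-Anscombe, set iff a zero cell
    p_value: float

    @property
    def table(self) -> list[list[int]]:
        return [[self.both, self.spliced_only], [self.de_only, self.neither]]


def expression_overlap(
    spliced_genes: set[str],
    de_genes: set[str],
    tested_universe: set[str],
    cell_type: str = "all",
) -> OverlapResult:
    """2x2 overlap of spliced vs differentially expressed genes.

    Both gene sets are restricted to ``tested_universe`` (genes tested for
    both splicing and expression).  Reports the sample odds ratio
    (a*d)/(b*c), a two-sided Fisher p, and — whenever a cell is zero — the
    Haldane-Anscombe corrected OR (+0.5 per cell).
    """
    if not tested_universe:
        raise ValueError("tested_universe is empty")
    s = spliced_genes & tested_universe
    d = de_genes & tested_universe
    a = len(s & d)
    b = len(s - d)
    c = len(d - s)
    n = len(tested_universe) - a - b - c
    if b * c > 0:
        odds = (a * n) / (b * c)
    elif a * n > 0:
        odds = float("inf")
    else:
        odds = float("nan")  # 0/0: table too degenerate for a raw OR
    corrected = None
    if 0 in (a, b, c, n):
        corrected = ((a + 0.5) * (n + 0.5)) / ((b + 0.5) * (c + 0.5))
    p = stats.fisher_exact([[a, b], [c, n]], alternative="two-sided")[1]
    return OverlapResult(cell_type, a, b, c, n, odds, corrected, float(p))


def de_gene_set(
    de_table: pd.DataFrame,
    log2fc_min: float = 0.1,
    fdr_max: float = 0.05,
    cell_type: str | None = None,
) -> tuple[set[str], set[str]]:
    """(significant DE genes, tested universe) from a per-gene DE table
    with columns gene_id, log2FC, fdr[, cell_type]."""
    df = de_table
    if cell_type is not None and "cell_type" in df.columns:
        df = df[df["cell_type"] == cell_type]
    sig = df[(df["log2FC"].abs() >= log2fc_min) & (df["fdr"] <= fdr_max)]
    return set(sig["gene_id"]), set(df["gene_id"])
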