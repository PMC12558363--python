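"""Case-control differential exon inclusion testing.

For each alternative exon and cell type, reads from all case samples are
pooled against reads from all control samples into a 2x2 inclusion/exclusion
table tested with Fisher's exact test (gated by Cochran's chi-squared
validity rule) and corrected with Benjamini-Yekutieli.  Percent spliced in::

    psi = inclusion / (inclusion + exclusion)
    delta_psi = psi_case - psi_control

so a negative delta means more skipping in cases.  An exon is called
significantly dysregulated only if, additionally, it survives a cascade of
robustness filters: pooled-psi range, per-condition read minimum, coverage
ratio, per-sample support, per-sample ordering, and (optionally) an
age-matched subset check.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

EXON_KEY = ["gene_id", "chrom", "exon_start", "exon_end", "strand"]


@dataclass
class TestConfig:
    """Thresholds of the exon-test filter cascade (fractions in [0, 1])."""

    delta_psi_min: float = 0.20
    fdr: float = 0.05
    psi_bounds: tuple[float, float] = (0.05, 0.95)
    min_reads_per_condition: int = 10
    coverage_min: float = 0.8
    support_fraction: float = 2 / 3
    ordering_fraction: float = 2 / 3
    age_match_retention: float = 0.5
    age_match_subset_size: int = 4
    flank: int = 50

    def validate(self) -> None:
        lo, hi = self.psi_bounds
        checks = [
            0 <= self.delta_psi_min <= 1, 0 < self.fdr <= 1,
            0 <= lo < hi <= 1, self.min_reads_per_condition >= 0,
            0 <= self.coverage_min <= 1, 0 < self.support_fraction <= 1,
            0 < self.ordering_fraction <= 1, 0 <= self.age_match_retention <= 1,
            self.flank >= 0,
        ]
        if not all(checks):
            raise ValueError("TestConfig threshold outside its natural range")


def psi(inclusion: int, exclusion: int) -> float:
    """Percent spliced in; NaN when there are no informative reads."""
    informative = inclusion + exclusion
    if informative == 0:
        return float("nan")
    return inclusion / informative


def delta_psi(psi_case: float, psi_control: float) -> float:
    return psi_case - psi_control


def fisher_exact_2x2(table) -> tuple[float, bool]:
    """Two-sided Fisher exact p plus the chi-squared validity gate.

    The gate (Cochran's rule) passes iff all four expected counts — row
    total x column total / grand total — are >= 5.  With a zero margin the
    p-value is undefined (NaN) and the gate fails.  Gate-failing tables are
    excluded from the multiple-testing family by the caller.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError(f"need a non-negative integer 2x2 table, got {table!r}")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    grand = t.sum()
    if (rows == 0).any() or (cols == 0).any():
        return float("nan"), False
    expected = np.outer(rows, cols) / grand
    gate = bool((expected >= 5).all())
    p = stats.fisher_exact(t.astype(int), alternative="two-sided")[1]
    return float(p), gate


def by_adjust(p_values) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted q-values, in input order.

    q_(i) = min over j >= i of min(1, p_(j) * m * c(m) / j) with
    c(m) = sum_{k=1..m} 1/k; valid under arbitrary dependence.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def _ceil_frac(fraction: float, n: int) -> int:
    return math.ceil(fraction * n - 1e-12)


def sample_support_filter(
    case_informative: list[int] | np.ndarray,
    control_informative: list[int] | np.ndarray,
    fraction: float = 2 / 3,
) -> bool:
    """True iff in each group >= ceil(fraction * group size) samples
    contribute at least one informative read."""
    case_informative = np.asarray(case_informative)
    control_informative = np.asarray(control_informative)
    ok_case = (case_informative > 0).sum() >= _ceil_frac(fraction, case_informative.size)
    ok_ctrl = (control_informative > 0).sum() >= _ceil_frac(fraction, control_informative.size)
    return bool(ok_case and ok_ctrl)


def sample_ordering_filter(
    per_sample_psis_case,
    per_sample_psis_control,
    pooled_direction: float,
    fraction: float = 2 / 3,
) -> bool:
    """Per-sample ordering consistency with the pooled effect direction.

    ``pooled_direction`` is sign(pooled control psi - pooled case psi).
    When pooled control psi is the larger one, the filter passes iff at
    least ceil(fraction * n_informative_controls) control samples each
    strictly exceed the psi of at least ceil(fraction * n_informative_cases)
    case samples; roles swap for the opposite direction.  Ties count
    against; a pooled tie fails.  Only samples with >= 1 informative read
    participate.
    """
    case = [x for x in per_sample_psis_case if not math.isnan(x)]
    ctrl = [x for x in per_sample_psis_control if not math.isnan(x)]
    if not case or not ctrl or pooled_direction == 0:
        return False
    if pooled_direction > 0:  # control higher
        high, low = ctrl, case
    else:
        high, low = case, ctrl
    need_high = _ceil_frac(fraction, len(high))
    need_low = _ceil_frac(fraction, len(low))
    n_winners = sum(
        1 for h in high if sum(1 for l in low if h > l) >= need_low
    )
    return n_winners >= need_high


def coverage_filter(
    inclusion: int, exclusion: int, total: int, threshold: float = 0.8
) -> bool:
    """True iff informative reads make up >= threshold of all reads
    overlapping the exon (both conditions pooled)."""
    if total == 0:
        return False
    return (inclusion + exclusion) / total >= threshold


RESULT_COLUMNS = EXON_KEY + [
    "source", "cell_type",
    "inclusion_case", "exclusion_case", "total_case",
    "inclusion_control", "exclusion_control", "total_control",
    "psi_case", "psi_control", "delta_psi", "p_raw", "q_by",
    "flag_psi_range", "flag_min_reads", "flag_coverage", "flag_chi2_gate",
    "flag_sample_support", "flag_sample_ordering", "flag_age_match",
    "significant", "reason",
]


def _per_sample_psis(sub: pd.DataFrame, condition: str) -> list[float]:
    rows = sub[sub["condition"] == condition]
    agg = rows.groupby("sample_id")[["inclusion", "exclusion"]].sum()
    return [
        psi(int(r.inclusion), int(r.exclusion))
        for r in agg.itertuples()
        if (r.inclusion + r.exclusion) > 0
    ]


def test_exons(counts: pd.DataFrame, config: TestConfig | None = None) -> pd.DataFrame:
    """Run the full exon test per cell type on a per-sample counts table.

    ``counts`` must be the per-sample output of
    :func:`snisplice.events.count_events`.  Within each cell type: exons
    passing the pooled-psi range, per-condition read minimum and coverage
    filters form the candidate set; Fisher p is computed on the pooled 2x2
    table and the chi-squared gate applied; BY correction runs across the
    cell type's gated candidates only.  The returned table contains every
    exon x cell type with all counts, psi values, per-filter flags, the
    significance call, and a human-readable reason for non-significance.
    """
    config = config or TestConfig()
    config.validate()

    rows = []
    for (cell_type,), ct_counts in counts.groupby(["cell_type"]):
        ct_rows = []
        for key, sub in ct_counts.groupby(EXON_KEY + ["source"]):
            case = sub[sub["condition"] == "case"]
            ctrl = sub[sub["condition"] == "control"]
            inc_a, exc_a, tot_a = (int(case[c].sum()) for c in ("inclusion", "exclusion", "total"))
            inc_b, exc_b, tot_b = (int(ctrl[c].sum()) for c in ("inclusion", "exclusion", "total"))
            psi_a = psi(inc_a, exc_a)
            psi_b = psi(inc_b, exc_b)
            dpsi = delta_psi(psi_a, psi_b)
            informative = inc_a + exc_a + inc_b + exc_b
            pooled_psi = psi(inc_a + inc_b, exc_a + exc_b)

            lo, hi = config.psi_bounds
            f_range = informative > 0 and lo <= pooled_psi <= hi
            f_min = (
                inc_a + exc_a >= config.min_reads_per_condition
                and inc_b + exc_b >= config.min_reads_per_condition
            )
            f_cov = coverage_filter(
                inc_a + inc_b, exc_a + exc_b, tot_a + tot_b, config.coverage_min
            )

            p_raw, gate = fisher_exact_2x2([[inc_a, exc_a], [inc_b, exc_b]])

            case_inf = case.groupby("sample_id")[["inclusion", "exclusion"]].sum().sum(axis=1)
            ctrl_inf = ctrl.groupby("sample_id")[["inclusion", "exclusion"]].sum().sum(axis=1)
            f_support = sample_support_filter(
                case_inf.to_numpy(), ctrl_inf.to_numpy(), config.support_fraction
            )
            direction = 0.0 if math.isnan(dpsi) or dpsi == 0 else -math.copysign(1, dpsi)
            f_order = sample_ordering_filter(
                _per_sample_psis(sub, "case"),
                _per_sample_psis(sub, "control"),
                direction,
                config.ordering_fraction,
            )
            ct_rows.append(
                list(key[:5]) + [key[5], cell_type,
                 inc_a, exc_a, tot_a, inc_b, exc_b, tot_b,
                 psi_a, psi_b, dpsi, p_raw, float("nan"),
                 f_range, f_min, f_cov, gate, f_support, f_order, True]
            )
        # flag_age_match defaults True here; age_matched_check re-evaluates it
        ct_df = pd.DataFrame(ct_rows, columns=RESULT_COLUMNS[:-2])

        in_family = (
            ct_df["flag_psi_range"] & ct_df["flag_min_reads"]
            & ct_df["flag_coverage"] & ct_df["flag_chi2_gate"]
        )
        if in_family.any():
            ct_df.loc[in_family, "q_by"] = by_adjust(
                ct_df.loc[in_family, "p_raw"].to_numpy()
            )
        rows.append(ct_df)

    res = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=RESULT_COLUMNS[:-2]
    )
    res["significant"] = (
        res["q_by"].le(config.fdr).fillna(False)
        & res["delta_psi"].abs().ge(config.delta_psi_min).fillna(False)
        & res["flag_psi_range"] & res["flag_min_reads"] & res["flag_coverage"]
        & res["flag_chi2_gate"] & res["flag_sample_support"]
        & res["flag_sample_ordering"] & res["flag_age_match"]
    )
    res["reason"] = res.apply(_reason, axis=1, args=(config,))
    return res[RESULT_COLUMNS]


def _reason(row: pd.Series, config: TestConfig) -> str:
    if row["significant"]:
        return "significant"
    reasons = []
    for flag, label in [
        ("flag_psi_range", "psi_range"), ("flag_min_reads", "min_reads"),
        ("flag_coverage", "coverage"), ("flag_chi2_gate", "chi2_gate"),
        ("flag_sample_support", "sample_support"),
        ("flag_sample_ordering", "sample_ordering"),
        ("flag_age_match", "age_match"),
    ]:
        if not row[flag]:
            reasons.append(label)
    if not pd.isna(row["q_by"]) and row["q_by"] > config.fdr:
        reasons.append("fdr")
    if not pd.isna(row["delta_psi"]) and abs(row["delta_psi"]) < config.delta_psi_min:
        reasons.append("delta_psi_min")
    return ",".join(reasons) or "not_assessed"


def _best_age_matched_subsets(
    sample_ages: dict[str, float],
    case_samples: list[str],
    control_samples: list[str],
    subset_size: int,
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Subsets of ``subset_size`` samples per group minimizing the absolute
    difference in group mean age (ties broken by sample-id order)."""
    best = None
    for cs in combinations(sorted(case_samples), subset_size):
        mean_c = np.mean([sample_ages[s] for s in cs])
        for ks in combinations(sorted(control_samples), subset_size):
            mean_k = np.mean([sample_ages[s] for s in ks])
            diff = abs(mean_c - mean_k)
            if best is None or diff < best[0] - 1e-12:
                best = (diff, cs, ks)
    assert best is not None
    return best[1], best[2]


def age_matched_check(
    results: pd.DataFrame,
    counts: pd.DataFrame,
    sample_ages: dict[str, float],
    config: TestConfig | None = None,
) -> pd.DataFrame:
    """Robustness check against the groups' age imbalance.

    Re-pools the exon tables over the ``subset_size`` samples per group
    whose mean ages match best, recomputes delta psi, and sets
    ``flag_age_match`` to pass iff the subset delta psi keeps the sign of
    the full delta psi and retains at least ``age_match_retention`` of its
    magnitude.  Groups with fewer than ``subset_size`` aged samples leave
    the flag undefined (recorded as pass, noted in ``age_match_status``).
    Significance is re-derived with the updated flag.
    """
    config = config or TestConfig()
    res = results.copy()
    case_samples = sorted(
        counts.loc[counts["condition"] == "case", "sample_id"].unique()
    )
    control_samples = sorted(
        counts.loc[counts["condition"] == "control", "sample_id"].unique()
    )
    k = config.age_match_subset_size
    aged_case = [s for s in case_samples if s in sample_ages]
    aged_ctrl = [s for s in control_samples if s in sample_ages]
    if len(aged_case) < k or len(aged_ctrl) < k:
        res["age_match_status"] = "undefined"
        return res

    cs, ks = _best_age_matched_subsets(sample_ages, aged_case, aged_ctrl, k)
    keep = counts["sample_id"].isin(set(cs) | set(ks))
    sub = counts[keep]

    pooled = sub.groupby(EXON_KEY + ["cell_type", "condition"])[
        ["inclusion", "exclusion"]
    ].sum().reset_index()
    piv = pooled.pivot_table(
        index=EXON_KEY + ["cell_type"], columns="condition",
        values=["inclusion", "exclusion"], fill_value=0,
    )
    subset_dpsi = {}
    for idx, row in piv.iterrows():
        pa = psi(int(row.get(("inclusion", "case"), 0)), int(row.get(("exclusion", "case"), 0)))
        pb = psi(int(row.get(("inclusion", "control"), 0)), int(row.get(("exclusion", "control"), 0)))
        subset_dpsi[idx] = delta_psi(pa, pb)

    flags, status = [], []
    for row in res.itertuples():
        idx = (row.gene_id, row.chrom, row.exon_start, row.exon_end, row.strand, row.cell_type)
        d_sub = subset_dpsi.get(idx, float("nan"))
        d_full = row.delta_psi
        if math.isnan(d_sub) or math.isnan(d_full) or d_full == 0:
            flags.append(False)
            status.append("no_subset_signal")
            continue
        same_sign = (d_sub > 0) == (d_full > 0) and d_sub != 0
        retained = abs(d_sub) >= config.age_match_retention * abs(d_full) - 1e-12
        flags.append(bool(same_sign and retained))
        status.append("evaluated")
    res["flag_age_match"] = flags
    res["age_match_status"] = status
    res["significant"] = (
        res["q_by"].le(config.fdr).fillna(False)
        & res["delta_psi"].abs().ge(config.delta_psi_min).fillna(False)
        & res["flag_psi_range"] & res["flag_min_reads"] & res["flag_coverage"]
        & res["flag_chi2_gate"] & res["flag_sample_support"]
        & res["flag_sample_ordering"] & res["flag_age_match"]
    )
    res["reason"] = res.apply(_reason, axis=1, args=(config,))
    return res


def write_results(
    df: pd.DataFrame, path: str | os.PathLike, header_comment: str = ""
) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def significant_exons_bed(df: pd.DataFrame, path: str | os.PathLike) -> int:
    """BED6 of significant exons (0-based half-open); returns row count."""
    sig = df[df["significant"]]
    n = 0
    with open(path, "w") as fh:
        for row in sig.itertuples():
            fh.write(
                "\t".join(
                    [row.chrom, str(row.exon_start - 1), str(row.exon_end),
                     f"{row.gene_id}|{row.cell_type}",
                     str(int(round(1000 * abs(row.delta_psi)))), row.strand]
                ) + "\n"
            )
            n += 1
    return n
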