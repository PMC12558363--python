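"""Case-control testing of alternative splice-donor and -acceptor usage.

Introns sharing one fixed end within a gene form a site group: donor groups
share the acceptor coordinate and differ in donor position, acceptor groups
the reverse.  Each group is reduced to its two most used sites over all
samples; Psi is the fraction of top-two reads using the top site, tested
case vs control with Fisher's exact test and BY correction per
(cell type, kind) family.
"""

from __future__ import annotations

import os
from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .diff_splicing import by_adjust, fisher_exact_2x2
from .reads import ReadRecord

INTRON_COUNT_COLUMNS = [
    "gene_id", "chrom", "intron_start", "intron_end", "strand",
    "cell_type", "sample_id", "condition", "count",
]


@dataclass
class SiteTestConfig:
    fdr: float = 0.05
    delta_psi_min: float = 0.10
    group_total_fraction: float = 0.8


@dataclass
class SpliceSiteGroup:
    """Alternative donor (or acceptor) sites sharing the other intron end."""

    gene_id: str
    chrom: str
    strand: str
    cell_type: str
    kind: str  # "donor" | "acceptor"
    fixed_end: int
    # variable site coordinate -> condition -> count (summed over samples)
    site_counts: dict[int, dict[str, int]] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.site_counts)

    def site_total(self, site: int) -> int:
        return sum(self.site_counts[site].values())

    @property
    def grand_total(self) -> int:
        return sum(self.site_total(s) for s in self.site_counts)

    def top_two(self) -> tuple[int, int]:
        """Two sites with the highest totals over all samples; ties broken
        by ascending genomic coordinate (deterministic)."""
        ranked = sorted(self.site_counts, key=lambda s: (-self.site_total(s), s))
        return ranked[0], ranked[1]


def intron_counts_from_reads(reads: list[ReadRecord]) -> pd.DataFrame:
    """Per-(gene, intron, cell type, sample) junction counts from read
    chains; mirrors the intron-count tables of transcript quantifiers."""
    counts: dict[tuple, int] = defaultdict(int)
    for r in reads:
        for s, e in r.introns:
            key = (r.gene_id, r.span.chrom, s, e, r.span.strand,
                   r.cell_type, r.sample_id, r.condition)
            counts[key] += 1
    rows = [k + (v,) for k, v in sorted(counts.items())]
    return pd.DataFrame(rows, columns=INTRON_COUNT_COLUMNS)


def read_intron_counts(path: str | os.PathLike) -> pd.DataFrame:
    """Import an external per-intron count TSV (same columns; ``cell_type``
    optional, defaulting to a single stratum)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "cell_type" not in df.columns:
        df["cell_type"] = "all"
    missing = [c for c in INTRON_COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing intron-count columns {missing}")
    return df[INTRON_COUNT_COLUMNS]


def group_splice_sites(intron_counts: pd.DataFrame) -> list[SpliceSiteGroup]:
    """Sort introns into alternative donor/acceptor groups per cell type.

    Donor and acceptor coordinates are strand-aware: the donor is the
    intron end adjacent to the upstream exon in transcription order.
    Groups with fewer than two observed variable sites are omitted.
    """
    groups: dict[tuple, SpliceSiteGroup] = {}
    for row in intron_counts.itertuples():
        if row.strand == "+":
            donor, acceptor = row.intron_start, row.intron_end
        else:
            donor, acceptor = row.intron_end, row.intron_start
        for kind, fixed, variable in (
            ("donor", acceptor, donor),
            ("acceptor", donor, acceptor),
        ):
            key = (row.gene_id, row.cell_type, kind, fixed)
            g = groups.get(key)
            if g is None:
                g = groups[key] = SpliceSiteGroup(
                    row.gene_id, row.chrom, row.strand, row.cell_type,
                    kind, fixed,
                )
            per_cond = g.site_counts.setdefault(variable, defaultdict(int))
            per_cond[row.condition] += int(row.count)
    return [g for g in groups.values() if g.n_sites >= 2]


SITE_RESULT_COLUMNS = [
    "gene_id", "chrom", "strand", "cell_type", "kind", "fixed_end",
    "top_site", "second_site", "n_sites",
    "top_case", "second_case", "top_control", "second_control",
    "psi_case", "psi_control", "delta_psi", "p_raw", "q_by",
    "retained", "significant", "reason",
]


def test_site_groups(
    groups: list[SpliceSiteGroup], config: SiteTestConfig | None = None
) -> pd.DataFrame:
    """Test all site groups; BY correction runs separately within each
    (cell type, kind) family over retained groups.

    A group is discarded (``retained=False``) if either condition has zero
    reads across the top two sites, or if the top-two table's grand total is
    below ``group_total_fraction`` of the whole group's total.
    Significance requires q <= fdr and |delta psi| >= delta_psi_min.
    """
    config = config or SiteTestConfig()
    rows = []
    for g in sorted(groups, key=lambda g: (g.cell_type, g.kind, g.gene_id, g.fixed_end)):
        top, second = g.top_two()
        tc = g.site_counts[top].get("case", 0)
        sc = g.site_counts[second].get("case", 0)
        tk = g.site_counts[top].get("control", 0)
        sk = g.site_counts[second].get("control", 0)
        table_total = tc + sc + tk + sk
        retained = (
            (tc + sc) > 0 and (tk + sk) > 0
            and table_total >= config.group_total_fraction * g.grand_total
        )
        psi_case = tc / (tc + sc) if (tc + sc) else float("nan")
        psi_ctrl = tk / (tk + sk) if (tk + sk) else float("nan")
        dpsi = psi_case - psi_ctrl
        p = float("nan")
        if retained:
            p, _ = fisher_exact_2x2([[tc, sc], [tk, sk]])
        rows.append(
            [g.gene_id, g.chrom, g.strand, g.cell_type, g.kind, g.fixed_end,
             top, second, g.n_sites, tc, sc, tk, sk,
             psi_case, psi_ctrl, dpsi, p, float("nan"), retained, False, ""]
        )
    res = pd.DataFrame(rows, columns=SITE_RESULT_COLUMNS)
    for (_, _), idx in res.groupby(["cell_type", "kind"]).groups.items():
        fam = res.loc[idx]
        mask = fam["retained"] & fam["p_raw"].notna()
        if mask.any():
            res.loc[fam.index[mask], "q_by"] = by_adjust(
                fam.loc[mask, "p_raw"].to_numpy()
            )
    res["significant"] = (
        res["retained"]
        & res["q_by"].le(config.fdr).fillna(False)
        & res["delta_psi"].abs().ge(config.delta_psi_min).fillna(False)
    )
    res["reason"] = [
        "significant" if s
        else ("discarded" if not r else "below_threshold")
        for s, r in zip(res["significant"], res["retained"])
    ]
    return res


def test_site_usage(
    reads: list[ReadRecord], config: SiteTestConfig | None = None
) -> pd.DataFrame:
    """Convenience wrapper: derive intron counts from read chains, group,
    and test, per cell type."""
    counts = intron_counts_from_reads(reads)
    return test_site_groups(group_splice_sites(counts), config)


def write_site_results(
    df: pd.DataFrame, path: str | os.PathLike, header_comment: str = ""
) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
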