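"""Alternative-exon discovery and per-read event classification.

An alternative exon is an internal exon that is entirely included in some
reads and entirely skipped (spanned by a single intron) in others.  Each
read overlapping such an exon is classified as an inclusion event, an
exclusion event, or neither; counts are tallied per (cell type, condition
[, sample]) group.
"""

from __future__ import annotations

import os
from collections import defaultdict
from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .annotation import GeneModel, internal_exons
from .intervals import GenomicInterval
from .reads import ReadRecord

DEFAULT_FLANK = 50


class ReadClass(str, Enum):
    INCLUSION = "inclusion"
    EXCLUSION = "exclusion"
    UNINFORMATIVE = "uninformative"
    NON_OVERLAPPING = "non_overlapping"


@dataclass(frozen=True, slots=True)
class AltExon:
    """An internal exon with both-behavior evidence in the read set."""

    gene_id: str
    interval: GenomicInterval
    source: str  # "annotated" | "observed"

    def __post_init__(self) -> None:
        if self.source not in ("annotated", "observed"):
            raise ValueError(f"bad AltExon source {self.source!r}")

    @property
    def key(self) -> tuple:
        iv = self.interval
        return (self.gene_id, iv.chrom, iv.start, iv.end, iv.strand)

    @property
    def upstream_boundary_intron_end(self) -> int:
        """A junction matches the exon's genomic-left boundary iff its intron
        ends here."""
        return self.interval.start - 1

    @property
    def downstream_boundary_intron_start(self) -> int:
        """A junction matches the exon's genomic-right boundary iff its
        intron starts here."""
        return self.interval.end + 1


def read_internal_segments(read: ReadRecord) -> list[tuple[int, int]]:
    """Maximal aligned segments between two consecutive junctions of a read:
    exons bounded by splice junctions on both sides."""
    segs = []
    for (s1, e1), (s2, e2) in zip(read.introns, read.introns[1:]):
        segs.append((e1 + 1, s2 - 1))
    return segs


def discover_alternative_exons(
    reads: list[ReadRecord],
    gene_models: dict[str, GeneModel],
    min_observed_support: int = 2,
) -> list[AltExon]:
    """Find exons with both inclusion and exclusion evidence.

    Candidates are (a) annotated internal exons of each gene and (b)
    observed exons — junction-bounded aligned segments seen in at least
    ``min_observed_support`` distinct reads (this suppresses alignment
    artifacts for unannotated, e.g. cryptic, exons).  A candidate is
    returned iff at least one read of the gene includes it (bounded by
    junctions on both sides) and at least one other read spans it with a
    single intron.
    """
    by_gene: dict[str, list[ReadRecord]] = defaultdict(list)
    for r in reads:
        by_gene[r.gene_id].append(r)

    out: list[AltExon] = []
    for gene_id, gene_reads in by_gene.items():
        seg_support: dict[tuple[int, int], int] = defaultdict(int)
        introns: set[tuple[int, int]] = set()
        for r in gene_reads:
            for seg in read_internal_segments(r):
                seg_support[seg] += 1
            introns.update(r.introns)

        model = gene_models.get(gene_id)
        annotated: dict[tuple[int, int], GenomicInterval] = {}
        if model is not None:
            for ex in internal_exons(model):
                annotated[(ex.start, ex.end)] = ex
        chrom = model.chrom if model is not None else gene_reads[0].span.chrom
        strand = model.strand if model is not None else gene_reads[0].span.strand

        candidates: dict[tuple[int, int], str] = {
            coords: "annotated" for coords in annotated
        }
        for seg, support in seg_support.items():
            if seg not in candidates and support >= min_observed_support:
                candidates[seg] = "observed"

        for (s, e), source in sorted(candidates.items()):
            included = seg_support.get((s, e), 0) >= 1
            excluded = any(a <= s and e <= b for a, b in introns)
            if included and excluded:
                out.append(
                    AltExon(gene_id, GenomicInterval(chrom, s, e, strand), source)
                )
    return out


def classify_read(
    read: ReadRecord,
    exon: AltExon,
    flank: int = DEFAULT_FLANK,
    junction_tolerance: int = 0,
) -> ReadClass:
    """Classify one read against one alternative exon.

    inclusion
        (i) aligned bases cover the entire exon and the chain carries
        junctions matching both exon boundaries, or (ii) the alignment
        starts/ends strictly inside the exon and the chain carries a
        junction matching the one boundary internal to the read.
    exclusion
        a single junction's intron covers the exon plus ``flank`` bases on
        each side (the read, by construction, aligns on both sides of it).
    non_overlapping
        the read span does not intersect the exon.
    uninformative
        everything else (e.g. reads ending inside the exon with no adjacent
        junction, or skipping with insufficient flank).

    Junction matching is coordinate-exact by default
    (``junction_tolerance=0``); splice-site accuracy is delegated to the
    upstream mapping stack.  A small tolerance admits boundary matches
    within that many bases.
    """
    if read.gene_id != exon.gene_id:
        raise ValueError(
            f"read {read.read_id} (gene {read.gene_id}) classified against "
            f"exon of gene {exon.gene_id}"
        )
    iv = exon.interval
    span = read.span
    if span.chrom != iv.chrom or span.end < iv.start or span.start > iv.end:
        return ReadClass.NON_OVERLAPPING

    tol = junction_tolerance
    up_end = exon.upstream_boundary_intron_end
    down_start = exon.downstream_boundary_intron_start
    has_upstream_jn = any(abs(e - up_end) <= tol for _, e in read.introns)
    has_downstream_jn = any(abs(s - down_start) <= tol for s, _ in read.introns)

    # exclusion: one intron covering exon +/- flank
    for s, e in read.introns:
        if s <= iv.start - flank and e >= iv.end + flank:
            return ReadClass.EXCLUSION

    covers = span.start <= iv.start and span.end >= iv.end and not any(
        s <= iv.end and e >= iv.start for s, e in read.introns
    )
    if covers and has_upstream_jn and has_downstream_jn:
        return ReadClass.INCLUSION

    starts_inside = iv.start < span.start <= iv.end
    ends_inside = iv.start <= span.end < iv.end
    if (
        starts_inside and read.introns
        and abs(read.introns[0][0] - down_start) <= tol
    ):
        return ReadClass.INCLUSION
    if (
        ends_inside and read.introns
        and abs(read.introns[-1][1] - up_end) <= tol
    ):
        return ReadClass.INCLUSION
    return ReadClass.UNINFORMATIVE


COUNT_COLUMNS = [
    "gene_id", "chrom", "exon_start", "exon_end", "strand", "source",
    "cell_type", "condition", "sample_id", "inclusion", "exclusion", "total",
]


def count_events(
    reads: list[ReadRecord],
    exons: list[AltExon],
    flank: int = DEFAULT_FLANK,
    per_sample: bool = True,
    junction_tolerance: int = 0,
) -> pd.DataFrame:
    """Tally inclusion/exclusion/total counts per exon and group.

    ``total`` counts all reads overlapping the exon location (inclusion,
    exclusion, or uninformative); non-overlapping reads are excluded.  All
    groups observed anywhere in ``reads`` are present for every exon, with
    zero counts where no read overlaps.  Grouping is (cell type, condition)
    and, with ``per_sample=True``, additionally sample.
    """
    group_universe = sorted(
        {(r.cell_type, r.condition, r.sample_id if per_sample else "") for r in reads}
    )
    by_gene: dict[str, list[ReadRecord]] = defaultdict(list)
    for r in reads:
        by_gene[r.gene_id].append(r)

    rows = []
    for exon in exons:
        counts: dict[tuple, list[int]] = {g: [0, 0, 0] for g in group_universe}
        for r in by_gene.get(exon.gene_id, ()):
            cls = classify_read(
                r, exon, flank=flank, junction_tolerance=junction_tolerance
            )
            if cls is ReadClass.NON_OVERLAPPING:
                continue
            key = (r.cell_type, r.condition, r.sample_id if per_sample else "")
            c = counts[key]
            c[2] += 1
            if cls is ReadClass.INCLUSION:
                c[0] += 1
            elif cls is ReadClass.EXCLUSION:
                c[1] += 1
        iv = exon.interval
        for (ct, cond, sample), (inc, exc, tot) in counts.items():
            rows.append(
                (exon.gene_id, iv.chrom, iv.start, iv.end, iv.strand,
                 exon.source, ct, cond, sample, inc, exc, tot)
            )
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def write_counts(df: pd.DataFrame, path: str | os.PathLike, header_comment: str = "") -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
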