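"""Per-read table I/O, UMI deduplication, and rare-intron-chain filtering.

The read table is the contract with upstream long-read mappers: one row per
barcoded, gene-assigned molecule carrying its ordered intron chain.  Columns
(tab-separated, header required)::

    read_id  sample_id  condition  cell_type  subtype  barcode  umi  gene_id
    chrom  read_start  read_end  strand  intron_chain

``intron_chain`` encodes introns as ``start-end`` pairs joined by ``";"``
(1-based inclusive intronic coordinates); the empty string denotes a
mono-exonic read.
"""

from __future__ import annotations

import os
from collections import Counter, defaultdict
from dataclasses import dataclass, replace

import edlib
import pandas as pd

from .intervals import GenomicInterval, Junction

READ_TABLE_COLUMNS = [
    "read_id", "sample_id", "condition", "cell_type", "subtype", "barcode",
    "umi", "gene_id", "chrom", "read_start", "read_end", "strand",
    "intron_chain",
]

CONDITIONS = ("case", "control")


class ReadTableError(ValueError):
    """Raised for malformed read tables or records."""


@dataclass(frozen=True, slots=True)
class ReadRecord:
    """One deduplicated long read with its labels and intron chain.

    ``introns`` holds genomic (start, end) intron coordinates sorted by
    start; strand-aware :class:`~snisplice.intervals.Junction` views are
    available via :attr:`junctions`.
    """

    read_id: str
    sample_id: str
    condition: str
    cell_type: str
    subtype: str
    barcode: str
    umi: str
    gene_id: str
    span: GenomicInterval
    introns: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ReadTableError(
                f"read {self.read_id}: condition must be one of {CONDITIONS}, "
                f"got {self.condition!r}"
            )
        if not self.cell_type:
            raise ReadTableError(f"read {self.read_id}: empty cell_type")
        prev_end = self.span.start - 1
        for start, end in self.introns:
            if start > end:
                raise ReadTableError(
                    f"read {self.read_id}: intron {start}-{end} is inverted"
                )
            if start <= prev_end:
                raise ReadTableError(
                    f"read {self.read_id}: intron chain overlapping or unsorted "
                    f"at {start}-{end}"
                )
            prev_end = end
        if self.introns and (
            self.introns[0][0] <= self.span.start
            or self.introns[-1][1] >= self.span.end
        ):
            raise ReadTableError(
                f"read {self.read_id}: introns extend outside aligned span"
            )

    @property
    def junctions(self) -> list[Junction]:
        return [
            Junction.from_intron(self.span.chrom, s, e, self.span.strand)
            for s, e in self.introns
        ]

    @property
    def chain_key(self) -> tuple:
        """Gene-scoped exact intron-chain identity (empty chain is a class)."""
        return (self.gene_id, self.introns)


def encode_chain(introns: tuple[tuple[int, int], ...]) -> str:
    return ";".join(f"{s}-{e}" for s, e in introns)


def decode_chain(text: str) -> tuple[tuple[int, int], ...]:
    if not text or text != text:  # '' or NaN
        return ()
    out = []
    for part in str(text).split(";"):
        s, _, e = part.partition("-")
        out.append((int(s), int(e)))
    return tuple(out)


def parse_read_table(
    path: str | os.PathLike, lenient: bool = False
) -> list[ReadRecord]:
    """Parse a read-table TSV into :class:`ReadRecord` objects.

    With ``lenient=True``, rows violating record invariants are skipped and
    reported to stderr with their line numbers; otherwise the first bad row
    raises :class:`ReadTableError` naming the line.
    """
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, comment="#"
    )
    missing = [c for c in READ_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ReadTableError(f"{path}: missing required columns {missing}")
    return frame_to_reads(df, lenient=lenient, source=str(path))


def frame_to_reads(
    df: pd.DataFrame, lenient: bool = False, source: str = "<frame>"
) -> list[ReadRecord]:
    records: list[ReadRecord] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False)):
        lineno = i + 2  # header is line 1
        try:
            span = GenomicInterval(
                row.chrom, int(row.read_start), int(row.read_end), row.strand
            )
            rec = ReadRecord(
                read_id=row.read_id, sample_id=row.sample_id,
                condition=row.condition, cell_type=row.cell_type,
                subtype=row.subtype, barcode=row.barcode, umi=row.umi,
                gene_id=row.gene_id, span=span,
                introns=decode_chain(row.intron_chain),
            )
        except (ValueError, ReadTableError) as exc:
            msg = f"{source}: line {lineno}: {exc}"
            if lenient:
                errors.append(msg)
                continue
            raise ReadTableError(msg) from exc
        records.append(rec)
    if errors:
        import sys

        print(f"skipped {len(errors)} invalid rows:", file=sys.stderr)
        for msg in errors[:20]:
            print(f"  {msg}", file=sys.stderr)
    return records


def reads_to_frame(reads: list[ReadRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": [r.read_id for r in reads],
            "sample_id": [r.sample_id for r in reads],
            "condition": [r.condition for r in reads],
            "cell_type": [r.cell_type for r in reads],
            "subtype": [r.subtype for r in reads],
            "barcode": [r.barcode for r in reads],
            "umi": [r.umi for r in reads],
            "gene_id": [r.gene_id for r in reads],
            "chrom": [r.span.chrom for r in reads],
            "read_start": [r.span.start for r in reads],
            "read_end": [r.span.end for r in reads],
            "strand": [r.span.strand for r in reads],
            "intron_chain": [encode_chain(r.introns) for r in reads],
        },
        columns=READ_TABLE_COLUMNS,
    )


def write_read_table(
    reads: list[ReadRecord], path: str | os.PathLike, header_comment: str = ""
) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        reads_to_frame(reads).to_csv(fh, sep="\t", index=False)


def levenshtein(a: str, b: str, limit: int | None = None) -> int:
    """Edit distance via edlib; with ``limit`` set, values above it return
    ``limit + 1`` (edlib reports -1 past the cutoff)."""
    if limit is None:
        return edlib.align(a, b, task="distance")["editDistance"]
    d = edlib.align(a, b, task="distance", k=limit)["editDistance"]
    return d if d != -1 else limit + 1


def _dedup_key(read: ReadRecord, scope: str) -> tuple:
    if scope == "barcode-gene":
        return (read.barcode, read.gene_id)
    if scope == "barcode":
        return (read.barcode,)
    if scope == "global":
        return ()
    raise ValueError(f"unknown dedup scope {scope!r}")


def dedup_umis(
    reads: list[ReadRecord],
    max_distance: int = 3,
    scope: str = "barcode-gene",
) -> list[ReadRecord]:
    """Drop reads whose UMI is an apparent sequencing-error copy.

    Within each scope group (default: one cell's reads for one gene), UMIs
    are ranked by read count descending, ties broken lexicographically.
    Scanning in rank order, a UMI — with all of its reads — is discarded if
    its Levenshtein distance to any already-retained UMI of the group is
    ``<= max_distance``.  Returns surviving reads in input order; the
    procedure is idempotent and invariant to input row order.
    """
    groups: dict[tuple, Counter] = defaultdict(Counter)
    for r in reads:
        groups[_dedup_key(r, scope)][r.umi] += 1

    kept: dict[tuple, set[str]] = {}
    for key, counts in groups.items():
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        retained: list[str] = []
        for umi, _ in ranked:
            if all(
                levenshtein(umi, other, limit=max_distance) > max_distance
                for other in retained
            ):
                retained.append(umi)
        kept[key] = set(retained)

    return [r for r in reads if r.umi in kept[_dedup_key(r, scope)]]


def filter_rare_chains(
    reads: list[ReadRecord], min_count: int = 5
) -> list[ReadRecord]:
    """Keep reads whose exact gene-scoped intron chain occurs ``>= min_count``
    times across all samples pooled (the empty chain is its own class)."""
    counts = Counter(r.chain_key for r in reads)
    return [r for r in reads if counts[r.chain_key] >= min_count]


def relabel_cell_type(reads: list[ReadRecord], label: str) -> list[ReadRecord]:
    """Return copies of ``reads`` with a single cell-type label (pseudobulk
    pooling: sample identity is kept, only the cell-type dimension merges)."""
    return [replace(r, cell_type=label) for r in reads]


def use_subtype_labels(reads: list[ReadRecord]) -> list[ReadRecord]:
    """Re-key reads by their subtype column (drops reads without one)."""
    return [replace(r, cell_type=r.subtype) for r in reads if r.subtype]
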