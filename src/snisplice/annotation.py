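"""Gene-annotation input/output and exon/junction enumeration.

Gene models are reconstructed from the ``exon`` features of a GENCODE-style
GTF (CDS/UTR features are ignored: splicing analysis only needs exon chains).
Coordinates stay 1-based inclusive internally; BED output converts to
0-based half-open at the boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gffutils

from .intervals import GenomicInterval, Junction


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass
class GeneModel:
    """One gene: ordered exon lists per transcript, all on one chrom/strand."""

    gene_id: str
    name: str
    chrom: str
    strand: str
    transcripts: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    transcript_biotypes: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.transcripts:
            raise AnnotationError(f"gene {self.gene_id} has no transcripts")
        for tx_id, exons in self.transcripts.items():
            if not exons:
                raise AnnotationError(f"transcript {tx_id} has no exons")
            for ex in exons:
                if ex.chrom != self.chrom or ex.strand != self.strand:
                    raise AnnotationError(
                        f"transcript {tx_id}: exon {ex} does not match gene "
                        f"{self.gene_id} on {self.chrom}({self.strand})"
                    )
            for a, b in zip(exons, exons[1:]):
                if b.start <= a.end:
                    raise AnnotationError(
                        f"transcript {tx_id} of gene {self.gene_id} has "
                        f"overlapping or unsorted exons at {a.start}-{a.end} "
                        f"and {b.start}-{b.end}"
                    )

    @property
    def span(self) -> GenomicInterval:
        start = min(e.start for exs in self.transcripts.values() for e in exs)
        end = max(e.end for exs in self.transcripts.values() for e in exs)
        return GenomicInterval(self.chrom, start, end, self.strand)


def _prescan_gtf(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise AnnotationError(
                    f"{path}: malformed GTF record at line {lineno} "
                    f"({len(fields)} fields, expected 9)"
                )


def load_gene_models(
    annotation_path: str | os.PathLike,
    biotype_filter: set[str] | None = None,
) -> dict[str, GeneModel]:
    """Load gene models from a GTF file.

    Parameters
    ----------
    annotation_path
        GTF file (GENCODE dialect; ``gene_id`` and ``transcript_id``
        attributes required on exon features).
    biotype_filter
        If given, keep only transcripts whose ``transcript_type`` /
        ``transcript_biotype`` attribute is in this set (e.g.
        ``{"protein_coding"}``); transcripts without a biotype attribute are
        kept.

    Returns
    -------
    dict mapping gene_id -> :class:`GeneModel`.
    """
    path = os.fspath(annotation_path)
    _prescan_gtf(path)
    with open(path) as fh:
        if not any(line.strip() and not line.startswith("#") for line in fh):
            return {}
    try:
        db = gffutils.create_db(
            path,
            dbfn=":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise AnnotationError(f"failed to parse GTF {path}: {exc}") from exc

    genes: dict[str, GeneModel] = {}
    for exon in db.features_of_type("exon", order_by=("seqid", "start")):
        attrs = exon.attributes
        if "gene_id" not in attrs:
            raise AnnotationError(f"exon at {exon.seqid}:{exon.start} lacks gene_id")
        if "transcript_id" not in attrs:
            raise AnnotationError(
                f"exon of gene {attrs['gene_id'][0]} at {exon.seqid}:{exon.start} "
                "has no transcript parent (transcript_id missing)"
            )
        gene_id = attrs["gene_id"][0]
        tx_id = attrs["transcript_id"][0]
        biotype = None
        for key in ("transcript_type", "transcript_biotype"):
            if key in attrs:
                biotype = attrs[key][0]
                break
        if biotype_filter is not None and biotype is not None:
            if biotype not in biotype_filter:
                continue
        name = attrs["gene_name"][0] if "gene_name" in attrs else gene_id
        model = genes.setdefault(
            gene_id, GeneModel(gene_id, name, exon.seqid, exon.strand)
        )
        iv = GenomicInterval(exon.seqid, exon.start, exon.end, exon.strand)
        model.transcripts.setdefault(tx_id, []).append(iv)
        if biotype is not None:
            model.transcript_biotypes[tx_id] = biotype

    for model in genes.values():
        for exons in model.transcripts.values():
            exons.sort(key=lambda e: (e.start, e.end))
        model.validate()
    return genes


def write_gtf(genes: dict[str, GeneModel], path: str | os.PathLike) -> None:
    """Write gene models back out as GTF (gene/transcript/exon features)."""
    with open(path, "w") as fh:
        for gene in sorted(genes.values(), key=lambda g: (g.chrom, g.span.start)):
            span = gene.span
            attrs = f'gene_id "{gene.gene_id}"; gene_name "{gene.name}";'
            fh.write(
                "\t".join(
                    [gene.chrom, "snisplice", "gene", str(span.start), str(span.end),
                     ".", gene.strand, ".", attrs]
                ) + "\n"
            )
            for tx_id, exons in sorted(gene.transcripts.items()):
                tattrs = attrs + f' transcript_id "{tx_id}";'
                biotype = gene.transcript_biotypes.get(tx_id)
                if biotype is not None:
                    tattrs += f' transcript_type "{biotype}";'
                fh.write(
                    "\t".join(
                        [gene.chrom, "snisplice", "transcript",
                         str(exons[0].start), str(exons[-1].end),
                         ".", gene.strand, ".", tattrs]
                    ) + "\n"
                )
                for i, ex in enumerate(exons, start=1):
                    fh.write(
                        "\t".join(
                            [gene.chrom, "snisplice", "exon",
                             str(ex.start), str(ex.end), ".", gene.strand, ".",
                             tattrs + f' exon_number "{i}";']
                        ) + "\n"
                    )


def internal_exons(gene: GeneModel) -> list[GenomicInterval]:
    """Exons that are neither first nor last in at least one transcript.

    An exon terminal in one transcript but internal in another is returned;
    deduplication is by (chrom, start, end, strand).
    """
    seen: set[GenomicInterval] = set()
    for exons in gene.transcripts.values():
        for ex in exons[1:-1]:
            seen.add(ex)
    return sorted(seen)


def junction_catalog(gene: GeneModel) -> set[Junction]:
    """All distinct adjacent-exon junctions over all transcripts of a gene."""
    out: set[Junction] = set()
    for exons in gene.transcripts.values():
        for a, b in zip(exons, exons[1:]):
            out.add(Junction.from_intron(gene.chrom, a.end + 1, b.start - 1, gene.strand))
    return out


def internal_exons_bed(
    genes: dict[str, GeneModel], path: str | os.PathLike
) -> int:
    """Write BED6 of all internal exons (0-based half-open); returns row count."""
    n = 0
    with open(path, "w") as fh:
        for gene in sorted(genes.values(), key=lambda g: (g.chrom, g.span.start)):
            for ex in internal_exons(gene):
                fields = ex.to_bed_fields(name=gene.gene_id)
                fh.write("\t".join(str(f) for f in fields) + "\n")
                n += 1
    return n
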