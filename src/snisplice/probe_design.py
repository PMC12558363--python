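"""Junction-spanning hybridization-capture probe design.

For every exon-exon junction of the target genes, a 140-base
spliced-transcript window is assembled (70 exonic bases on each side of the
junction, walking across additional exons when a neighbor is shorter than
70).  Near transcript ends the maximal window is kept if it still reaches
130 bases; shorter windows are discarded.  A 120-mer is then chosen inside
each window, multimapping probes (> ``max_hits`` genomic matches) are
dropped, and genes retaining fewer than ``min_probes_per_gene`` probes are
removed entirely.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Callable, Mapping

from .annotation import GeneModel
from .intervals import GenomicInterval, Junction

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def load_genome(path: str | os.PathLike) -> dict[str, str]:
    """Load a FASTA genome into memory as uppercase strings."""
    from pyfaidx import Fasta

    fa = Fasta(os.fspath(path))
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


@dataclass
class ProbeCandidate:
    """One junction-spanning capture window and its selected 120-mer."""

    gene_id: str
    transcript_id: str
    junction: Junction
    blocks: list[GenomicInterval]  # exonic blocks of the window, genomic order
    window_seq: str  # transcription-order sequence
    breakpoint: int  # bases of window upstream of the junction
    probe_seq: str | None = None
    probe_offset: int | None = None
    n_genomic_hits_window: int | None = None
    n_genomic_hits: int | None = None  # hits of the final 120-mer
    notes: list[str] = field(default_factory=list)

    @property
    def window_length(self) -> int:
        return len(self.window_seq)

    @property
    def name(self) -> str:
        j = self.junction
        return f"{self.gene_id}|{j.chrom}:{j.donor_pos}-{j.acceptor_pos}"


def _exon_seq(genome: Mapping[str, str], iv: GenomicInterval) -> str:
    return genome[iv.chrom][iv.start - 1 : iv.end].upper()


def _walk(
    exons: list[GenomicInterval],
    genome: Mapping[str, str],
    strand: str,
    from_index: int,
    upstream: bool,
    need: int,
) -> tuple[str, list[GenomicInterval]]:
    """Collect up to ``need`` spliced bases walking away from a junction.

    ``exons`` are in transcription order; ``from_index`` is the exon
    adjacent to the junction on the requested side.  Returns the sequence
    in transcription order plus the genomic sub-intervals used.
    """
    seq_parts: list[str] = []
    blocks: list[GenomicInterval] = []
    idx = from_index
    remaining = need
    step = -1 if upstream else 1
    while remaining > 0 and 0 <= idx < len(exons):
        ex = exons[idx]
        take = min(remaining, ex.length)
        if upstream:
            # last `take` bases in transcription order
            if strand == "+":
                sub = GenomicInterval(ex.chrom, ex.end - take + 1, ex.end, strand)
            else:
                sub = GenomicInterval(ex.chrom, ex.start, ex.start + take - 1, strand)
            seq = _exon_seq(genome, sub)
            if strand == "-":
                seq = revcomp(seq)
            seq_parts.insert(0, seq)
            blocks.insert(0, sub)
        else:
            if strand == "+":
                sub = GenomicInterval(ex.chrom, ex.start, ex.start + take - 1, strand)
            else:
                sub = GenomicInterval(ex.chrom, ex.end - take + 1, ex.end, strand)
            seq = _exon_seq(genome, sub)
            if strand == "-":
                seq = revcomp(seq)
            seq_parts.append(seq)
            blocks.append(sub)
        remaining -= take
        idx += step
    return "".join(seq_parts), blocks


def enumerate_junction_windows(
    genes: Mapping[str, GeneModel],
    genome: Mapping[str, str],
    side: int = 70,
    min_window: int = 130,
) -> list[ProbeCandidate]:
    """One candidate window per (junction, distinct sequence) per gene.

    Every junction present in at least one transcript is processed per
    transcript (neighboring exons may differ between transcripts sharing a
    junction); candidates are deduplicated by window sequence within each
    gene.  Windows shorter than ``min_window`` transcript bases are
    discarded.
    """
    out: list[ProbeCandidate] = []
    for gene in genes.values():
        seen_seqs: set[str] = set()
        for tx_id, exons_genomic in sorted(gene.transcripts.items()):
            tx_exons = (
                exons_genomic if gene.strand == "+" else exons_genomic[::-1]
            )  # transcription order
            for i in range(len(tx_exons) - 1):
                up_ex, down_ex = tx_exons[i], tx_exons[i + 1]
                if gene.strand == "+":
                    junction = Junction.from_intron(
                        gene.chrom, up_ex.end + 1, down_ex.start - 1, "+"
                    )
                else:
                    junction = Junction.from_intron(
                        gene.chrom, down_ex.end + 1, up_ex.start - 1, "-"
                    )
                up_seq, up_blocks = _walk(
                    tx_exons, genome, gene.strand, i, upstream=True, need=side
                )
                down_seq, down_blocks = _walk(
                    tx_exons, genome, gene.strand, i + 1, upstream=False, need=side
                )
                window = up_seq + down_seq
                if len(window) < min_window:
                    continue
                if window in seen_seqs:
                    continue
                seen_seqs.add(window)
                blocks = sorted(up_blocks + down_blocks, key=lambda b: b.start)
                out.append(
                    ProbeCandidate(
                        gene_id=gene.gene_id,
                        transcript_id=tx_id,
                        junction=junction,
                        blocks=blocks,
                        window_seq=window,
                        breakpoint=len(up_seq),
                    )
                )
    return out


def exact_match_mappability(genome: Mapping[str, str]) -> Callable[[str], int]:
    """Default mappability oracle: overlapping exact-match occurrences of a
    sequence (or its reverse complement) anywhere in the genome."""

    def count(seq: str) -> int:
        seq = seq.upper()
        targets = {seq, revcomp(seq)}
        total = 0
        for chrom_seq in genome.values():
            for t in targets:
                start = chrom_seq.find(t)
                while start != -1:
                    total += 1
                    start = chrom_seq.find(t, start + 1)
        # a palindromic probe would be double-counted; not a practical case
        return total

    return count


def gc_fraction(seq: str) -> float:
    return sum(1 for b in seq.upper() if b in "GC") / len(seq)


def default_probe_score(seq: str) -> float:
    """Transparent hybridization proxy: 1 if GC fraction lies in
    [0.30, 0.70], else 0."""
    return 1.0 if 0.30 <= gc_fraction(seq) <= 0.70 else 0.0


def select_120mer(
    candidate: ProbeCandidate,
    probe_length: int = 120,
    score: Callable[[str], float] = default_probe_score,
) -> ProbeCandidate:
    """Pick the probe 120-mer inside the window.

    Offsets keeping the junction breakpoint strictly inside the probe are
    scored; the argmax wins, ties broken by junction centrality (breakpoint
    closest to the probe midpoint), then by leftmost offset.
    """
    window, b = candidate.window_seq, candidate.breakpoint
    lo = max(0, b - (probe_length - 1))
    hi = min(len(window) - probe_length, b - 1)
    best = None
    for off in range(lo, hi + 1):
        seq = window[off : off + probe_length]
        s = score(seq)
        centrality = abs((b - off) - probe_length // 2)
        rank = (-s, centrality, off)
        if best is None or rank < best[0]:
            best = (rank, off, seq)
    if best is None:
        raise ValueError(
            f"window of {candidate.name} has no offset containing the junction"
        )
    candidate.probe_offset = best[1]
    candidate.probe_seq = best[2]
    return candidate


def filter_and_select_probes(
    candidates: list[ProbeCandidate],
    mappability: Callable[[str], int],
    min_probes_per_gene: int = 5,
    max_hits: int = 5,
    probe_length: int = 120,
    score: Callable[[str], float] = default_probe_score,
) -> list[ProbeCandidate]:
    """Select 120-mers, drop multimappers, drop underpowered genes.

    The multimapping filter applies to the final 120-mer (window hit counts
    are logged alongside); genes keeping fewer than ``min_probes_per_gene``
    probes are removed entirely.  ``mappability`` must be supplied — there
    is no silent pass-through.
    """
    if mappability is None:
        raise ValueError("a mappability oracle is required")
    survivors: dict[str, list[ProbeCandidate]] = {}
    for cand in candidates:
        select_120mer(cand, probe_length=probe_length, score=score)
        cand.n_genomic_hits_window = mappability(cand.window_seq)
        cand.n_genomic_hits = mappability(cand.probe_seq)
        if cand.n_genomic_hits > max_hits:
            cand.notes.append(f"multimapping:{cand.n_genomic_hits}")
            continue
        survivors.setdefault(cand.gene_id, []).append(cand)
    out: list[ProbeCandidate] = []
    for gene_id, cands in sorted(survivors.items()):
        if len(cands) < min_probes_per_gene:
            continue
        out.extend(cands)
    return out


def write_probe_fasta(probes: list[ProbeCandidate], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for p in probes:
            fh.write(f">{p.name}\n{p.probe_seq}\n")


def write_probe_bed12(probes: list[ProbeCandidate], path: str | os.PathLike) -> None:
    """BED12 of each probe's window blocks (0-based half-open)."""
    with open(path, "w") as fh:
        for p in probes:
            chrom = p.junction.chrom
            start = min(b.start for b in p.blocks) - 1
            end = max(b.end for b in p.blocks)
            sizes = ",".join(str(b.length) for b in p.blocks)
            starts = ",".join(str(b.start - 1 - start) for b in p.blocks)
            fh.write(
                "\t".join(
                    [chrom, str(start), str(end), p.name, "0",
                     p.blocks[0].strand, str(start), str(end), "0",
                     str(len(p.blocks)), sizes, starts]
                ) + "\n"
            )
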