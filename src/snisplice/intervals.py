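"""Core genomic coordinate types.

All coordinates are 1-based and inclusive on both ends (GTF convention).
Conversion to 0-based half-open happens only at BED boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

STRANDS = ("+", "-")


@dataclass(frozen=True, order=True, slots=True)
class GenomicInterval:
    """A closed genomic interval [start, end] on one strand.

    ``start`` and ``end`` are 1-based inclusive; ``start <= end`` always.
    """

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"interval start {self.start} > end {self.end} on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def to_bed_fields(self, name: str = ".", score: int = 0) -> tuple:
        """BED6 fields (0-based half-open)."""
        return (self.chrom, self.start - 1, self.end, name, score, self.strand)


@dataclass(frozen=True, order=True, slots=True)
class Junction:
    """One splice junction (= one intron).

    ``donor_pos`` is the first intronic base at the intron's 5' end in
    transcription order; ``acceptor_pos`` the last intronic base at its 3'
    end.  On the minus strand the donor therefore has the larger genomic
    coordinate.
    """

    chrom: str
    donor_pos: int
    acceptor_pos: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")
        if self.strand == "+" and self.donor_pos > self.acceptor_pos:
            raise ValueError("plus-strand junction must have donor <= acceptor")
        if self.strand == "-" and self.donor_pos < self.acceptor_pos:
            raise ValueError("minus-strand junction must have donor >= acceptor")

    @classmethod
    def from_intron(
        cls, chrom: str, start: int, end: int, strand: str
    ) -> "Junction":
        """Build from genomic intron coordinates (start <= end, inclusive)."""
        if start > end:
            raise ValueError(f"intron start {start} > end {end}")
        if strand == "+":
            return cls(chrom, start, end, strand)
        return cls(chrom, end, start, strand)

    @property
    def start(self) -> int:
        """Genomic (strand-independent) intron start."""
        return min(self.donor_pos, self.acceptor_pos)

    @property
    def end(self) -> int:
        """Genomic (strand-independent) intron end."""
        return max(self.donor_pos, self.acceptor_pos)

    @property
    def intron_length(self) -> int:
        return self.end - self.start + 1
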