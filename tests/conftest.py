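import pytest

from snisplice.intervals import GenomicInterval
from snisplice.reads import ReadRecord


def make_read(
    read_id="r1",
    sample_id="case1",
    condition="case",
    cell_type="ExN",
    subtype="",
    barcode="AAAACCCCGGGGTTTT",
    umi="ACGTACGTAC",
    gene_id="g1",
    chrom="chr1",
    start=1,
    end=5000,
    strand="+",
    introns=(),
):
    return ReadRecord(
        read_id=read_id, sample_id=sample_id, condition=condition,
        cell_type=cell_type, subtype=subtype, barcode=barcode, umi=umi,
        gene_id=gene_id, span=GenomicInterval(chrom, start, end, strand),
        introns=tuple(introns),
    )


@pytest.fixture
def toy_gtf(tmp_path):
    """One gene, two transcripts (3 and 2 exons) on the plus strand."""
    lines = []

    def feat(kind, start, end, attrs):
        lines.append(
            f"chr1\ttest\t{kind}\t{start}\t{end}\t.\t+\t.\t{attrs}"
        )

    g = 'gene_id "G1"; gene_name "GENE1";'
    t1 = g + ' transcript_id "T1";'
    t2 = g + ' transcript_id "T2";'
    feat("gene", 100, 1000, g)
    feat("transcript", 100, 1000, t1)
    feat("exon", 100, 200, t1)
    feat("exon", 400, 500, t1)
    feat("exon", 800, 1000, t1)
    feat("transcript", 100, 1000, t2)
    feat("exon", 100, 200, t2)
    feat("exon", 800, 1000, t2)
    path = tmp_path / "toy.gtf"
    path.write_text("\n".join(lines) + "\n")
    return path
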