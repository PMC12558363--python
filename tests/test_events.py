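import pytest

from snisplice.annotation import GeneModel
from snisplice.events import (
    AltExon,
    ReadClass,
    classify_read,
    count_events,
    discover_alternative_exons,
)
from snisplice.intervals import GenomicInterval

from conftest import make_read

# gene layout: five 100-bp exons separated by 300-bp introns
EXONS = [(1000, 1099), (1400, 1499), (1800, 1899), (2200, 2299), (2600, 2699)]
INTRONS = [(1100, 1399), (1500, 1799), (1900, 2199), (2300, 2599)]
ALT = AltExon("g1", GenomicInterval("chr1", 1800, 1899, "+"), "annotated")

INCLUSION_CHAIN = tuple(INTRONS)
SKIP_CHAIN = (INTRONS[0], (1500, 2199), INTRONS[3])  # one intron spans the exon
RETENTION_CHAIN = (INTRONS[0], INTRONS[3])


def gene_model():
    m = GeneModel("g1", "g1", "chr1", "+")
    m.transcripts["t1"] = [GenomicInterval("chr1", s, e, "+") for s, e in EXONS]
    m.validate()
    return m


def full_read(read_id="r", introns=INCLUSION_CHAIN, **kw):
    return make_read(read_id=read_id, gene_id="g1", start=1000, end=2699,
                     introns=introns, **kw)


class TestClassifyRead:
    def test_full_coverage_with_both_flanking_junctions_is_inclusion(self):
        assert classify_read(full_read(), ALT) is ReadClass.INCLUSION

    def test_single_intron_covering_exon_and_flanks_is_exclusion(self):
        assert classify_read(full_read(introns=SKIP_CHAIN), ALT) is ReadClass.EXCLUSION

    def test_skip_with_insufficient_flank_is_uninformative(self):
        # intron starts only 30 bases upstream of the exon (needs >= 50)
        near = (INTRONS[0], (1770, 2199), INTRONS[3])
        assert classify_read(full_read(introns=near), ALT) is ReadClass.UNINFORMATIVE

    def test_flank_boundary_is_inclusive(self):
        exact = ((1750, 1949),)  # exon.start-50 .. exon.end+50
        read = make_read(gene_id="g1", start=1600, end=2100, introns=exact)
        assert classify_read(read, ALT) is ReadClass.EXCLUSION

    def test_intron_retention_read_is_uninformative(self):
        assert (
            classify_read(full_read(introns=RETENTION_CHAIN), ALT)
            is ReadClass.UNINFORMATIVE
        )

    def test_truncated_read_supporting_adjacent_junction_is_inclusion(self):
        # alignment ends inside the exon; last junction matches the exon's
        # upstream boundary
        read = make_read(gene_id="g1", start=1000, end=1850,
                         introns=(INTRONS[0], INTRONS[1]))
        assert classify_read(read, ALT) is ReadClass.INCLUSION

    def test_truncated_read_without_adjacent_junction_is_uninformative(self):
        read = make_read(gene_id="g1", start=1000, end=1850, introns=(INTRONS[0],))
        assert classify_read(read, ALT) is ReadClass.UNINFORMATIVE

    def test_read_not_touching_exon_is_non_overlapping(self):
        read = make_read(gene_id="g1", start=1000, end=1499, introns=(INTRONS[0],))
        assert classify_read(read, ALT) is ReadClass.NON_OVERLAPPING

    def test_double_junction_skip_is_uninformative(self):
        # skipping via two stacked junctions (unannotated exonlet in between)
        stacked = (INTRONS[0], (1500, 1839), (1860, 2199), INTRONS[3])
        assert (
            classify_read(full_read(introns=stacked), ALT)
            is ReadClass.UNINFORMATIVE
        )

    def test_junction_tolerance_admits_near_matches(self):
        wobble = ((1100, 1399), (1500, 1797), (1902, 2199), (2300, 2599))
        read = full_read(introns=wobble)
        assert classify_read(read, ALT) is ReadClass.UNINFORMATIVE
        assert (
            classify_read(read, ALT, junction_tolerance=2)
            is ReadClass.INCLUSION
        )

    def test_gene_mismatch_raises(self):
        read = make_read(gene_id="g2", start=1000, end=2699)
        with pytest.raises(ValueError, match="gene"):
            classify_read(read, ALT)

    def test_categories_are_exhaustive_and_exclusive(self):
        reads = [
            full_read(),
            full_read(introns=SKIP_CHAIN),
            full_read(introns=RETENTION_CHAIN),
            make_read(gene_id="g1", start=1000, end=1499, introns=()),
            make_read(gene_id="g1", start=1820, end=1880, introns=()),
        ]
        for r in reads:
            cls = classify_read(r, ALT)
            assert cls in ReadClass


class TestDiscoverAlternativeExons:
    def test_exon_needs_both_inclusion_and_exclusion_evidence(self):
        models = {"g1": gene_model()}
        only_included = [full_read(read_id=f"r{i}") for i in range(5)]
        assert discover_alternative_exons(only_included, models) == []

    def test_annotated_exon_with_both_behaviors_returned(self):
        models = {"g1": gene_model()}
        reads = [full_read(read_id=f"i{i}") for i in range(5)] + [
            full_read(read_id=f"s{i}", introns=SKIP_CHAIN) for i in range(5)
        ]
        found = discover_alternative_exons(reads, models)
        assert [e.key for e in found] == [("g1", "chr1", 1800, 1899, "+")]
        assert found[0].source == "annotated"

    def test_unannotated_cryptic_exon_discovered_as_observed(self):
        models = {"g1": gene_model()}
        # cryptic 60-bp exon inside intron 2, seen in two reads
        cryptic = (INTRONS[0], INTRONS[1], (1900, 2000), (2061, 2199), INTRONS[3])
        reads = [full_read(read_id=f"c{i}", introns=cryptic) for i in range(2)] + [
            full_read(read_id=f"n{i}") for i in range(5)
        ]
        found = discover_alternative_exons(reads, models)
        observed = [e for e in found if e.source == "observed"]
        assert len(observed) == 1
        assert observed[0].interval == GenomicInterval("chr1", 2001, 2060, "+")

    def test_single_read_support_insufficient_for_observed_exon(self):
        models = {"g1": gene_model()}
        cryptic = (INTRONS[0], INTRONS[1], (1900, 2000), (2061, 2199), INTRONS[3])
        reads = [full_read(read_id="c0", introns=cryptic)] + [
            full_read(read_id=f"n{i}") for i in range(5)
        ]
        assert all(
            e.source != "observed"
            for e in discover_alternative_exons(reads, models)
        )


class TestCountEvents:
    def test_tally_and_total_includes_uninformative(self):
        reads = (
            [full_read(read_id=f"i{i}") for i in range(4)]
            + [full_read(read_id=f"e{i}", introns=SKIP_CHAIN) for i in range(4)]
            + [full_read(read_id=f"u{i}", introns=RETENTION_CHAIN) for i in range(2)]
        )
        counts = count_events(reads, [ALT], per_sample=False)
        assert len(counts) == 1
        row = counts.iloc[0]
        assert (row.inclusion, row.exclusion, row.total) == (4, 4, 10)

    def test_groups_with_no_overlapping_reads_get_zero_rows(self):
        reads = [full_read(read_id="a")] + [
            make_read(read_id="far", gene_id="g1", cell_type="Astro",
                      condition="control", start=1000, end=1099, introns=())
        ]
        counts = count_events(reads, [ALT], per_sample=False)
        zero = counts[(counts.cell_type == "Astro")]
        assert len(zero) == 1
        assert zero.iloc[0].total == 0

    def test_per_sample_counts_sum_to_condition_counts(self):
        reads = [
            full_read(read_id=f"r{i}", sample_id=f"case{i % 3 + 1}")
            for i in range(9)
        ]
        per_sample = count_events(reads, [ALT], per_sample=True)
        pooled = count_events(reads, [ALT], per_sample=False)
        for col in ("inclusion", "exclusion", "total"):
            assert per_sample[col].sum() == pooled[col].sum()

    def test_inclusion_plus_exclusion_never_exceeds_total(self):
        reads = (
            [full_read(read_id=f"i{i}") for i in range(3)]
            + [full_read(read_id=f"e{i}", introns=SKIP_CHAIN) for i in range(2)]
            + [full_read(read_id=f"u{i}", introns=RETENTION_CHAIN) for i in range(4)]
        )
        counts = count_events(reads, [ALT])
        assert ((counts.inclusion + counts.exclusion) <= counts.total).all()
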