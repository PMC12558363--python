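# snisplice

Cell-type-resolved case-control differential splicing from single-nucleus
long reads.

## What problem this solves

Bulk RNA-seq averages splicing over all cells of a tissue, so a splicing
change confined to one cell type — say, astrocytes in a neurodegenerative
cortex — can be invisible in the pooled signal. Barcoded single-nucleus
long-read sequencing assigns every full-length cDNA molecule a cell type
and a complete exon–intron chain, which makes it possible to test exon
usage between disease cases and controls *within* each cell type.

`snisplice` implements that analysis for a 6-case / 6-control,
multi-cell-type study design:

- **Read cleaning** — UMIs within a Levenshtein distance of 3 of a more
  frequent UMI in the same cell–gene group are treated as sequencing-error
  copies and their reads discarded; reads whose exact intron chain occurs
  fewer than 5 times across all samples are dropped.
- **Exon testing** — for each alternative internal exon, reads are
  classified as inclusion events (entire exon covered with both splice
  junctions matched, or a truncated read supporting the one junction it
  covers), exclusion events (a single intron spanning the exon plus ≥ 50
  bases of flank on each side), or neither. Percent spliced in is
  Ψ = inclusion / (inclusion + exclusion) and ΔΨ = Ψ_case − Ψ_control.
  Pooled 2×2 tables are tested with Fisher's exact test, gated by
  Cochran's chi-squared validity rule, and corrected per cell type with
  Benjamini–Yekutieli. A call additionally requires q ≤ 0.05,
  |ΔΨ| ≥ 0.20, pooled Ψ ∈ [5%, 95%], ≥ 10 informative reads per
  condition, informative/total coverage ≥ 0.8, informative reads in at
  least two-thirds of samples per group, a two-thirds per-sample ordering
  consistency rule, and (optionally) retention of at least half the effect
  in age-matched sample subsets.
- **Splice-site testing** — introns sharing one end form alternative
  donor/acceptor groups; the top two sites per group give a site-level Ψ,
  tested case vs control (q ≤ 0.05, |ΔΨ| ≥ 0.10) with an 80%
  group-total retention rule.
- **Comparative analyses** — pseudobulk masking (which cell-type calls
  disappear when cell types are pooled), Pearson correlation of ΔΨ
  between cell types with Fisher-z intervals, and the odds ratio for
  overlap between differentially spliced and differentially expressed
  genes.
- **Probe design** — junction-spanning 140-base capture windows (70
  spliced bases per side, walking across short exons), reduced to
  120-mers, with multimapper and per-gene minimum filters.
- **Simulation** — a generator that plants per-(exon, cell type,
  condition) inclusion probabilities, per-condition splice-site usage,
  and UMI errors, so every stage can be validated against known truth.

## Worked example

```python
from snisplice.simulate import planted_effect_config, simulate_dataset, gene_models_for
from snisplice.reads import frame_to_reads, dedup_umis, filter_rare_chains
from snisplice.events import discover_alternative_exons, count_events
from snisplice.diff_splicing import test_exons

config = planted_effect_config(
    n_genes=4, psi_case=0.7, psi_control=0.3,
    cell_types={"ExN": 20}, reads_per_cell_mean=2.0,
    umi_error_rate=0.02, seed=42,
)
table, truth = simulate_dataset(config)
reads = filter_rare_chains(dedup_umis(frame_to_reads(table)))
models = gene_models_for(config)
exons = discover_alternative_exons(reads, models)
counts = count_events(reads, exons)
results = test_exons(counts)
cols = ["gene_id", "psi_case", "psi_control", "delta_psi", "q_by", "significant"]
print(results[cols].round(3).to_string(index=False))
```

prints

```
gene_id  psi_case  psi_control  delta_psi  q_by  significant
  g0000     0.743        0.308      0.435   0.0         True
  g0001     0.696        0.292      0.404   0.0         True
  g0002     0.675        0.310      0.365   0.0         True
  g0003     0.704        0.295      0.408   0.0         True
```

Four exons were planted at Ψ = 0.7 in cases vs 0.3 in controls; after
UMI dedup, chain filtering, event counting and the full filter cascade,
all four are recovered with ΔΨ estimates near the planted 0.4 and
Benjamini–Yekutieli q-values indistinguishable from zero at this depth
(~480 informative reads per exon).

The same pipeline is available from the shell:

```bash
snisplice simulate --config sim.yaml --out-reads reads.tsv \
    --out-truth truth.tsv --out-gtf annot.gtf
snisplice run-all --config pipeline.yaml   # dedup → ... → masking
snisplice design-probes --gtf annot.gtf --genome genome.fa \
    --out-fasta probes.fa
```

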