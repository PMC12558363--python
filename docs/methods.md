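# Methods

This note documents the statistical model, the filter cascade, the
synthetic-data generator, and the numerical and design choices behind
`snisplice`.

## Coordinates and data model

All genomic coordinates are 1-based and inclusive on both ends (the GTF
convention); conversion to 0-based half-open happens only when writing
BED. A junction (intron) is stored strand-aware: the donor is the first
intronic base at the intron's 5′ end in transcription order, so donor and
acceptor swap genomic order on the minus strand. Exon identity is
(chrom, start, end, strand) scoped by gene, which prevents collisions
between overlapping genes. Gene models are built from `exon` features
only; CDS/UTR features are irrelevant to splicing chains and ignored. All
transcripts are used by default; a biotype filter
(e.g. `protein_coding`) can be switched on where an analysis should
mirror a coding-only target set.

## Read cleaning

**UMI deduplication.** Within each (barcode, gene) group, UMIs are ranked
by read count descending with lexicographic tie-breaks; scanning in rank
order, a UMI and all its reads are discarded when its Levenshtein
distance to any already-retained UMI is ≤ 3 ("less than 4"). Comparing
against the *retained* set, rather than all input UMIs, prevents chains
of mutually close low-count UMIs from eliminating each other after their
common attractor is removed, and makes the procedure idempotent and
order-invariant. The grouping scope is configurable
(`barcode-gene` | `barcode` | `global`); per cell-and-gene is the
default because UMI collisions are only meaningful within a cell-and-gene
context. Distances are computed with edlib with an early-exit cutoff at
distance 3.

**Rare-chain filter.** A read is kept only if its exact, gene-scoped,
coordinate-exact intron chain (the empty chain is its own class) occurs
at least 5 times across all samples pooled. Dedup runs first, then the
chain filter.

## Exon events

An alternative exon is an internal exon (flanked by splice junctions on
both sides) with both behaviors in the data: included — appearing as a
junction-bounded aligned segment — in at least one read, and skipped —
spanned by a single intron — in at least one other. Candidates are the
annotated internal exons plus *observed* segments; an unannotated
(cryptic) segment additionally needs its junction-bounded form in ≥ 2
distinct reads to suppress alignment artifacts (configurable).

Classification of a read against an exon, with `flank = 50`:

- **inclusion** — aligned bases cover the whole exon and the chain
  matches both boundary junctions exactly; or the alignment starts/ends
  strictly inside the exon and the junction *adjacent to the covered
  boundary* matches. Requiring adjacency means degraded 5′/3′ read ends
  with no supporting junction do not vote.
- **exclusion** — a single intron covers `[start − flank, end + flank]`.
  A read skipping the exon via two stacked junctions (an intervening
  exonlet within the flank) is deliberately not an exclusion event: the
  conservative reading of the flank rule.
- **non-overlapping** — span does not intersect the exon; excluded from
  totals.
- **uninformative** — everything else (intron-retaining reads, skips
  with insufficient flank, unsupported truncations). These count toward
  the total, which drives the coverage filter below.

Junction matching is coordinate-exact (`--junction-tolerance` defaults
to 0): splice-site accuracy is the upstream mapper's responsibility, and
a wobble window would blur donor/acceptor analyses.

## The exon test and its filter cascade

Per cell type, counts are pooled over samples within each condition and

Ψ = inclusion / (inclusion + exclusion),  ΔΨ = Ψ_case − Ψ_control,

so negative ΔΨ means more skipping in cases. The 2×2
inclusion/exclusion × case/control table is tested with the two-sided
Fisher exact test. The "chi-squared criterion" gating which tables are
assessed is implemented as Cochran's rule — all four expected counts
(row total × column total / grand total) ≥ 5 — the standard validity
criterion for 2×2 approximations. Gated-out exons are excluded from the
multiple-testing family so that m counts only assessed tests; the
Benjamini–Yekutieli step-up correction (valid under arbitrary
dependence) runs per cell type, with pseudobulk forming its own family.

A significant call requires **all** of:

| filter | default | notes |
|---|---|---|
| FDR | q ≤ 0.05 | BY per cell type |
| effect size | \|ΔΨ\| ≥ 0.20 | |
| Ψ range | pooled Ψ ∈ [0.05, 0.95] | applied to the pooled Ψ across both conditions |
| read depth | ≥ 10 informative reads per condition | |
| coverage | (inclusion + exclusion) / total ≥ 0.8 | both conditions pooled |
| sample support | ≥ ⌈2n/3⌉ samples per group with ≥ 1 informative read | |
| sample ordering | see below | |
| age matching | optional, see below | |

**Ordering rule.** With pooled control Ψ above pooled case Ψ, at least
⌈2/3 · n_ctrl⌉ informative control samples must each strictly exceed
the per-sample Ψ of at least ⌈2/3 · n_case⌉ informative case samples
(roles swap in the opposite direction; a pooled tie fails). Ceilings and
ties-count-against are the conservative, deterministic choices; samples
with zero informative reads are excluded from both sides of the rule.
Per-sample Ψ uses only that sample's informative reads.

**Age-matched robustness.** Case and control groups in post-mortem
designs are rarely age-balanced. `age_matched_check` selects the
4-samples-per-group subsets minimizing the absolute difference in group
mean age (exhaustive over the 15 × 15 combinations at n = 6),
recomputes ΔΨ on the subset, and requires the subset ΔΨ to keep the
full ΔΨ's sign and at least 50% of its magnitude. Groups with fewer
than 4 aged samples leave the flag recorded as undefined rather than
failed.

## Splice-site usage

Introns are sorted into groups sharing the gene, strand and one fixed
end: donor groups share the acceptor coordinate, acceptor groups the
donor. Intron counts are derived internally from read chains; an import
path accepts external per-intron count tables from transcript
quantifiers. Per group the two sites with the highest totals over all
samples are kept (ties broken by ascending genomic coordinate —
deterministic, and ΔΨ magnitude is unaffected by which label wins);
Ψ = top / (top + second) per condition. A group is discarded when either
condition has no reads across the top two sites or when the top-two
table's grand total falls below 80% of the whole group's total (grand
totals, not per-condition totals). Fisher + BY run per
(cell type, kind) family; significance needs q ≤ 0.05 and
|ΔΨ| ≥ 0.10.

## Comparative analyses

**Pseudobulk masking.** Pseudobulk keeps sample identity and merges only
the cell-type label, so the support and ordering filters still apply —
pooling all case cells against all control cells. An exon significant in
a cell type is *masked* if not significant in pseudobulk under identical
criteria; exons absent from the pseudobulk table count as masked and are
reported separately. The 95% CI on the masked fraction is a Wilson score
interval. Excitatory-subtype (cortical-layer) analyses reuse the same
exon test with the subtype column as the grouping key; no separate code
path.

**ΔΨ correlation.** Pearson r over exons quantifiable in both strata
(default: significant in at least one), CI via the Fisher z-transform;
fewer than 3 pairs or zero variance is reported as undefined rather than
NaN-propagated.

**Expression overlap.** Genes with ≥ 1 significant exon versus genes at
|log2FC| ≥ 0.1 and FDR ≤ 0.05 in the supplied DE table, both restricted
to the universe tested for both; sample odds ratio (a·d)/(b·c) with a
two-sided Fisher p, plus the Haldane–Anscombe (+0.5) OR whenever a cell
is zero.

## Probe design

For every junction of every transcript, 70 spliced-transcript bases are
taken on each side, walking across adjacent exons shorter than 70 bases;
near transcript ends the maximal window is kept if ≥ 130 bases, else the
junction is discarded. Transcripts sharing a junction but differing in
neighboring exons yield one candidate per distinct sequence,
deduplicated per gene. The 120-mer inside the window is chosen by a
transparent hybridization proxy — score 1 if GC ∈ [0.30, 0.70] else 0 —
tie-broken by junction centrality then leftmost offset, always keeping
the junction breakpoint strictly inside the probe; the scorer is
injectable for anything more elaborate. Mappability is likewise an
injected oracle (default: exact overlapping string matches of the probe
or its reverse complement in the supplied genome) rather than an
embedded aligner; probes with more than 5 hits are dropped (the filter
applies to the final 120-mer; window hit counts are logged), then genes
retaining fewer than 5 probes are removed entirely.

## The synthetic-data generator

The generator emulates the targeted study design: 6 case and 6 control
donors, several cell types with per-sample cell counts, and one
alternative internal exon per simulated gene (5 exons of 100 bp with
300 bp introns by default, so the skipping intron always exceeds the
50-base flank rule). Reads are emitted as full intron-chain records;
sequence is modeled only for barcodes and UMIs because the downstream
stages consume chains, not bases. Per cell and gene, read counts are
negative binomial (mean 1, dispersion 10 by default; the depth
distribution of real capture data is not pinned down, so both are
configurable). Each read includes its gene's alternative exon with the
planted probability for its (cell type, condition), skips it via the
merged flanking intron otherwise, or — with probability 0.05 — retains
both flanking introns, producing an uninformative overlapping read that
exercises the coverage filter. Optional per-gene alternative donors
shift one intron's 5′ end by 12 bases with per-condition usage
probabilities, feeding the splice-site module.

Per-sample heterogeneity: the sample-level inclusion probability is a
Beta draw centered on the planted group value with concentration 300
(between-donor sd ≈ 0.02–0.03 at Ψ = 0.5) — enough variability to make
the per-sample support and ordering filters do real work, while keeping
planted effects orderable, which is what the two-thirds rules assume of
a reproducible effect. UMIs are unique per (barcode, gene) and drawn at
pairwise edit distance ≥ 4 within a group, so noise-free data passes
deduplication untouched by construction; UMI noise substitutes 1 base
(configurable up to 3) in a configurable fraction of UMIs, with the true
UMIs retained in the truth object.

What the generator does **not** model: capture efficiency, TSS/poly(A)
structure, base-call errors beyond UMIs, barcode sharing between
samples, doublets, or expression counts for the DE side (DE gene lists
for the overlap analysis are planted directly). Passing tests therefore
demonstrate the statistical machinery under the stated sampling model,
not robustness to alignment or capture artifacts in real data.

## Numerical choices and degenerate inputs

- Fisher p comes from `scipy.stats.fisher_exact`; the test suite checks
  it against full hypergeometric enumeration to 1e-10. Tables with a zero
  margin have undefined p (NaN) and always fail the gate.
- BY q-values come from `statsmodels` and are checked against a direct
  step-up implementation; q is reported in input order.
- Ψ of a group with no informative reads is NaN and the exon is flagged
  `not_assessed`, never silently zero.
- Two-thirds thresholds use ceilings; all ordering ties count against
  passing.
- Site-group top-two ties break by genomic coordinate; probe 120-mer
  ties by centrality then leftmost offset. Every pipeline output is
  byte-reproducible for a fixed seed and configuration, and each table
  header records the seed and a config fingerprint.

## Validation problem sizes

The shipped validation suite uses desk-scale problem sizes chosen to
make the statistical checks sharp while keeping runs short: the null
calibration simulates 500 exons × 12 samples × 10 seeds (~5,000 gated
tests); power/recovery uses 50 exons at ~300 informative reads per
condition, where the binomial sd of a ΔΨ estimate is ≈ 0.04 — hence
accuracy is asserted as ≥ 95% of estimates within ±0.10 of truth, the
level a perfect estimator achieves at this depth; masking uses a
10%-abundance cell type carrying a ΔΨ = 0.5 effect against a null
majority; splice-site recovery plants a 0.3 donor-usage shift at ~1,400
junction reads per condition.

## Known limitations

- The exon test treats reads as independent; residual PCR duplicates
  surviving UMI dedup would overstate confidence.
- Overdispersion between donors is handled by the per-sample filters,
  not by the pooled Fisher test itself; a beta-binomial test would model
  it directly but would depart from the target analysis.
- One-sided junction support at an unannotated exon contributes to
  inclusion only for truncated reads (the adjacency rule); fully
  spanning reads matching one side only are logged as uninformative.
- Mappability by exact string matching ignores near-exact repeats; the
  oracle is pluggable for alignment-based counting.
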