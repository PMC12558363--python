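"""Synthetic read-table generator with planted ground truth.

Emulates the study design the pipeline targets: 6 case and 6 control
donors, several cell types with configurable per-sample cell counts, and
per-(gene, cell type, condition) planted exon-inclusion probabilities.
Reads are emitted as full intron-chain records (no base-level sequence
except barcodes and UMIs); sequencing error is modeled on UMIs only, since
the downstream stages consume chains, not raw signal.

Each simulated gene carries one alternative internal exon.  A read either
includes it (chain contains both flanking junctions), skips it (one merged
intron covering the exon plus the full flanking introns, far beyond the
50-base flank rule), or — with small probability — retains both flanking
introns, which makes it an uninformative overlapping read and exercises the
coverage filter.  Optionally a gene carries an alternative donor site on
one of its other introns with per-condition usage probabilities, feeding
the splice-site module.

Per-sample heterogeneity: the sample-level inclusion probability is drawn
from a Beta distribution centered on the planted group value with a
configurable concentration, then read outcomes are binomial within the
sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reads import READ_TABLE_COLUMNS, levenshtein

_BASES = np.array(list("ACGT"))


class SimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class AltDonorSpec:
    """An alternative donor on one intron: the variant site sits ``shift``
    bases downstream of the canonical donor (into the intron)."""

    intron_index: int = 0
    shift: int = 12
    usage_case: float = 0.5  # probability of the canonical site in cases
    usage_control: float = 0.5

    def usage(self, condition: str) -> float:
        return self.usage_case if condition == "case" else self.usage_control


@dataclass(frozen=True)
class GeneStructure:
    """A regular multi-exon gene with one designated alternative exon."""

    gene_id: str
    chrom: str = "chr1"
    start: int = 1000
    strand: str = "+"
    n_exons: int = 5
    exon_length: int = 100
    intron_length: int = 300
    alt_exon_index: int = 2
    alt_donor: AltDonorSpec | None = None

    def __post_init__(self) -> None:
        if not (0 < self.alt_exon_index < self.n_exons - 1):
            raise SimConfigError(
                f"{self.gene_id}: alt exon must be internal "
                f"(index {self.alt_exon_index} of {self.n_exons} exons)"
            )
        if self.alt_donor is not None:
            i = self.alt_donor.intron_index
            if i in (self.alt_exon_index - 1, self.alt_exon_index):
                raise SimConfigError(
                    f"{self.gene_id}: alternative donor on an intron flanking "
                    "the alternative exon would confound both analyses"
                )
            if not 0 <= i < self.n_exons - 1:
                raise SimConfigError(f"{self.gene_id}: alt donor intron index {i}")
            if not 0 < self.alt_donor.shift < self.intron_length - 1:
                raise SimConfigError(f"{self.gene_id}: donor shift out of range")

    @property
    def exons(self) -> list[tuple[int, int]]:
        step = self.exon_length + self.intron_length
        return [
            (self.start + i * step, self.start + i * step + self.exon_length - 1)
            for i in range(self.n_exons)
        ]

    @property
    def introns(self) -> list[tuple[int, int]]:
        ex = self.exons
        return [(a[1] + 1, b[0] - 1) for a, b in zip(ex, ex[1:])]

    @property
    def span(self) -> tuple[int, int]:
        ex = self.exons
        return ex[0][0], ex[-1][1]

    @property
    def alt_exon(self) -> tuple[int, int]:
        return self.exons[self.alt_exon_index]

    def chain(self, include_exon: bool, retention: bool, canonical_donor: bool) -> str:
        """Intron-chain string for one read of this gene."""
        introns = list(self.introns)
        if self.alt_donor is not None and not canonical_donor:
            s, e = introns[self.alt_donor.intron_index]
            if self.strand == "+":
                introns[self.alt_donor.intron_index] = (s + self.alt_donor.shift, e)
            else:
                introns[self.alt_donor.intron_index] = (s, e - self.alt_donor.shift)
        i = self.alt_exon_index
        if retention:
            del introns[i - 1 : i + 1]
        elif not include_exon:
            merged = (introns[i - 1][0], introns[i][1])
            introns[i - 1 : i + 1] = [merged]
        return ";".join(f"{s}-{e}" for s, e in introns)


@dataclass
class SimConfig:
    """Study-design and noise parameters of one simulated dataset."""

    genes: list[GeneStructure]
    n_case_samples: int = 6
    n_control_samples: int = 6
    cell_types: dict[str, int] = field(default_factory=lambda: {"ExN": 20})
    # (gene_id, cell_type, condition) -> inclusion probability; missing keys
    # fall back to default_psi
    planted_psi: dict[tuple[str, str, str], float] = field(default_factory=dict)
    default_psi: float = 0.5
    reads_per_cell_mean: float = 1.0
    reads_per_cell_dispersion: float | None = 10.0
    p_intron_retention: float = 0.05
    sample_jitter_concentration: float | None = 300.0
    umi_length: int = 10
    barcode_length: int = 16
    umi_error_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for key, p in self.planted_psi.items():
            if not 0.0 <= p <= 1.0:
                raise SimConfigError(f"planted psi {p} for {key} outside [0, 1]")
        for g in self.genes:
            if g.alt_donor is not None:
                for u in (g.alt_donor.usage_case, g.alt_donor.usage_control):
                    if not 0.0 <= u <= 1.0:
                        raise SimConfigError(
                            f"site usage {u} for {g.gene_id} outside [0, 1]"
                        )
        for name, p in [
            ("default_psi", self.default_psi),
            ("p_intron_retention", self.p_intron_retention),
            ("umi_error_rate", self.umi_error_rate),
        ]:
            if not 0.0 <= p <= 1.0:
                raise SimConfigError(f"{name}={p} outside [0, 1]")
        if self.reads_per_cell_mean <= 0:
            raise SimConfigError("reads_per_cell_mean must be positive")

    @property
    def samples(self) -> list[tuple[str, str]]:
        return [
            (f"case{i + 1}", "case") for i in range(self.n_case_samples)
        ] + [
            (f"control{i + 1}", "control") for i in range(self.n_control_samples)
        ]

    def psi_for(self, gene_id: str, cell_type: str, condition: str) -> float:
        return self.planted_psi.get((gene_id, cell_type, condition), self.default_psi)


@dataclass
class SimTruth:
    """Planted ground truth for downstream validation."""

    # (gene_id, cell_type, condition) -> group-level planted psi
    psi: dict[tuple[str, str, str], float] = field(default_factory=dict)
    # (gene_id, cell_type) -> psi_case - psi_control
    delta_psi: dict[tuple[str, str], float] = field(default_factory=dict)
    # gene_id -> (chrom, start, end, strand) of the alternative exon
    exon_coords: dict[str, tuple[str, int, int, str]] = field(default_factory=dict)
    # (gene_id, condition) -> canonical-donor usage probability
    site_usage: dict[tuple[str, str], float] = field(default_factory=dict)
    # read_id -> UMI before error injection
    true_umis: dict[str, str] = field(default_factory=dict)
    # (gene_id, cell_type, condition, sample_id) -> jittered sample psi
    sample_psi: dict[tuple[str, str, str, str], float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (gene_id, cell_type), d in sorted(self.delta_psi.items()):
            chrom, s, e, strand = self.exon_coords[gene_id]
            rows.append(
                (gene_id, chrom, s, e, strand, cell_type,
                 self.psi[(gene_id, cell_type, "case")],
                 self.psi[(gene_id, cell_type, "control")], d)
            )
        return pd.DataFrame(
            rows,
            columns=["gene_id", "chrom", "exon_start", "exon_end", "strand",
                     "cell_type", "psi_case", "psi_control", "delta_psi"],
        )


def random_dna(rng: np.random.Generator, n: int, length: int) -> list[str]:
    arr = _BASES[rng.integers(0, 4, size=(n, length))]
    return ["".join(row) for row in arr]


def _draw_group_umis(
    rng: np.random.Generator, k: int, length: int, min_distance: int = 4
) -> list[str]:
    """k UMIs pairwise >= ``min_distance`` edits apart, so that noise-free
    data survives deduplication untouched."""
    out: list[str] = []
    while len(out) < k:
        cand = "".join(_BASES[rng.integers(0, 4, size=length)])
        if all(levenshtein(cand, u, limit=min_distance - 1) >= min_distance for u in out):
            out.append(cand)
    return out


def _sample_level_psi(
    rng: np.random.Generator, p: float, concentration: float | None
) -> float:
    if concentration is None or p in (0.0, 1.0):
        return p
    return float(rng.beta(p * concentration, (1.0 - p) * concentration))


def simulate_dataset(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Generate a read table and its ground truth.

    Deterministic given ``config`` (including its seed): the same config
    yields a byte-identical table.  If ``config.umi_error_rate > 0``, UMI
    noise is injected before returning; original UMIs are kept in the
    truth object.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = SimTruth()

    for g in config.genes:
        s, e = g.alt_exon
        truth.exon_coords[g.gene_id] = (g.chrom, s, e, g.strand)
        for ct in config.cell_types:
            pc = config.psi_for(g.gene_id, ct, "case")
            pk = config.psi_for(g.gene_id, ct, "control")
            truth.psi[(g.gene_id, ct, "case")] = pc
            truth.psi[(g.gene_id, ct, "control")] = pk
            truth.delta_psi[(g.gene_id, ct)] = pc - pk
        if g.alt_donor is not None:
            truth.site_usage[(g.gene_id, "case")] = g.alt_donor.usage_case
            truth.site_usage[(g.gene_id, "control")] = g.alt_donor.usage_control

    columns: dict[str, list] = {c: [] for c in READ_TABLE_COLUMNS}
    read_counter = 0

    for sample_id, condition in config.samples:
        for ct, n_cells in config.cell_types.items():
            barcodes = random_dna(rng, n_cells, config.barcode_length)
            for g in config.genes:
                p_group = config.psi_for(g.gene_id, ct, condition)
                p_sample = _sample_level_psi(
                    rng, p_group, config.sample_jitter_concentration
                )
                truth.sample_psi[(g.gene_id, ct, condition, sample_id)] = p_sample

                m = config.reads_per_cell_mean
                if config.reads_per_cell_dispersion is None:
                    cell_reads = rng.poisson(m, size=n_cells)
                else:
                    r = config.reads_per_cell_dispersion
                    cell_reads = rng.negative_binomial(r, r / (r + m), size=n_cells)
                total = int(cell_reads.sum())
                if total == 0:
                    continue
                include = rng.random(total) < p_sample
                retain = rng.random(total) < config.p_intron_retention
                if g.alt_donor is not None:
                    canonical = rng.random(total) < g.alt_donor.usage(condition)
                else:
                    canonical = np.ones(total, dtype=bool)

                chains = {
                    (inc, ret, can): g.chain(inc, ret, can)
                    for inc in (False, True)
                    for ret in (False, True)
                    for can in (False, True)
                }
                span_start, span_end = g.span
                idx = 0
                for cell, k in enumerate(cell_reads):
                    if k == 0:
                        continue
                    umis = _draw_group_umis(rng, int(k), config.umi_length)
                    for u in umis:
                        rid = f"r{read_counter:08d}"
                        read_counter += 1
                        columns["read_id"].append(rid)
                        columns["sample_id"].append(sample_id)
                        columns["condition"].append(condition)
                        columns["cell_type"].append(ct)
                        columns["subtype"].append("")
                        columns["barcode"].append(barcodes[cell])
                        columns["umi"].append(u)
                        columns["gene_id"].append(g.gene_id)
                        columns["chrom"].append(g.chrom)
                        columns["read_start"].append(span_start)
                        columns["read_end"].append(span_end)
                        columns["strand"].append(g.strand)
                        columns["intron_chain"].append(
                            chains[(bool(include[idx]), bool(retain[idx]),
                                    bool(canonical[idx]))]
                        )
                        truth.true_umis[rid] = u
                        idx += 1

    table = pd.DataFrame(columns, columns=READ_TABLE_COLUMNS)
    if config.umi_error_rate > 0:
        table = inject_umi_noise(
            table, config.umi_error_rate,
            rng=np.random.default_rng(config.seed + 1_000_003), truth=truth,
        )
    return table, truth


def inject_umi_noise(
    table: pd.DataFrame,
    rate: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    max_edits: int = 1,
    truth: SimTruth | None = None,
) -> pd.DataFrame:
    """Substitute bases in a fraction ``rate`` of UMIs.

    Each affected UMI receives ``max_edits`` substitutions at distinct
    positions (edit distance <= ``max_edits`` <= 3 from its truth).  The
    original UMIs are recorded in ``truth.true_umis`` when a truth object
    is supplied.  Returns a new table; the input is not modified.
    """
    if not 0.0 <= rate <= 1.0:
        raise SimConfigError(f"umi error rate {rate} outside [0, 1]")
    if not 1 <= max_edits <= 3:
        raise SimConfigError("max_edits must be between 1 and 3")
    if rng is None:
        rng = np.random.default_rng(seed)
    table = table.copy()
    umis = table["umi"].tolist()
    hit = rng.random(len(umis)) < rate
    for i in np.flatnonzero(hit):
        umi = list(umis[i])
        positions = rng.choice(len(umi), size=max_edits, replace=False)
        for pos in positions:
            alternatives = [b for b in "ACGT" if b != umi[pos]]
            umi[pos] = alternatives[rng.integers(0, 3)]
        if truth is not None:
            truth.true_umis[table["read_id"].iat[i]] = umis[i]
        umis[i] = "".join(umi)
    table["umi"] = umis
    return table


def gene_models_for(config: SimConfig):
    """Gene models matching the simulated annotation: per gene one
    inclusion transcript and one transcript skipping the alternative exon."""
    from .annotation import GeneModel
    from .intervals import GenomicInterval

    models: dict[str, GeneModel] = {}
    for g in config.genes:
        exons = [GenomicInterval(g.chrom, s, e, g.strand) for s, e in g.exons]
        model = GeneModel(g.gene_id, g.gene_id, g.chrom, g.strand)
        model.transcripts[f"{g.gene_id}.t1"] = exons
        model.transcripts[f"{g.gene_id}.t2"] = (
            exons[: g.alt_exon_index] + exons[g.alt_exon_index + 1 :]
        )
        model.validate()
        models[g.gene_id] = model
    return models


def sim_config_from_yaml(source) -> SimConfig:
    """Build a :class:`SimConfig` from a YAML file path or parsed dict.

    Schema: scalar SimConfig fields plus ``n_genes`` and two planting
    lists — ``effects`` entries ``{genes: [lo, hi], cell_type: name|'*',
    psi_case, psi_control}`` and ``alt_donors`` entries ``{genes: [lo, hi],
    usage_case, usage_control, shift}`` — addressing genes by index range
    (inclusive).
    """
    import yaml

    if isinstance(source, dict):
        spec = dict(source)
    else:
        with open(source) as fh:
            spec = yaml.safe_load(fh) or {}

    n_genes = int(spec.pop("n_genes", 10))
    effects = spec.pop("effects", [])
    alt_donors = spec.pop("alt_donors", [])
    gene_kwargs = spec.pop("gene_structure", {})

    donor_by_index: dict[int, AltDonorSpec] = {}
    for entry in alt_donors:
        lo, hi = entry["genes"]
        for i in range(lo, hi + 1):
            donor_by_index[i] = AltDonorSpec(
                intron_index=int(entry.get("intron_index", 0)),
                shift=int(entry.get("shift", 12)),
                usage_case=float(entry["usage_case"]),
                usage_control=float(entry["usage_control"]),
            )
    genes = [
        GeneStructure(
            gene_id=f"g{i:04d}", chrom="chr1", start=1000 + i * 3000,
            alt_donor=donor_by_index.get(i), **gene_kwargs,
        )
        for i in range(n_genes)
    ]

    if "cell_types" in spec:
        spec["cell_types"] = {str(k): int(v) for k, v in spec["cell_types"].items()}
    cell_types = spec.get("cell_types", {"ExN": 20})

    planted: dict[tuple[str, str, str], float] = {}
    for entry in effects:
        lo, hi = entry["genes"]
        cts = list(cell_types) if entry.get("cell_type", "*") == "*" else [entry["cell_type"]]
        for i in range(lo, hi + 1):
            for ct in cts:
                planted[(genes[i].gene_id, ct, "case")] = float(entry["psi_case"])
                planted[(genes[i].gene_id, ct, "control")] = float(entry["psi_control"])

    return SimConfig(genes=genes, planted_psi=planted, **spec)


def planted_effect_config(
    n_genes: int,
    psi_case: float,
    psi_control: float,
    cell_types: dict[str, int] | None = None,
    reads_per_cell_mean: float = 1.0,
    seed: int = 0,
    **kwargs,
) -> SimConfig:
    """Convenience builder: ``n_genes`` identical genes with the same
    planted (case, control) inclusion probabilities in every cell type."""
    genes = [
        GeneStructure(gene_id=f"g{i:04d}", chrom="chr1", start=1000 + i * 3000)
        for i in range(n_genes)
    ]
    cell_types = cell_types or {"ExN": 20}
    planted = {
        (g.gene_id, ct, cond): (psi_case if cond == "case" else psi_control)
        for g in genes
        for ct in cell_types
        for cond in ("case", "control")
    }
    return SimConfig(
        genes=genes, cell_types=cell_types, planted_psi=planted,
        reads_per_cell_mean=reads_per_cell_mean, seed=seed, **kwargs,
    )
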