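"""Self-contained validation scenarios with planted ground truth.

Every function here builds its inputs from scratch (simulated reads or
constructed fixtures), runs the package's own pipeline on them, and
returns measured quantities.  The module also houses independent oracles
(hypergeometric enumeration, the BY step-up formula, a quadratic
rank-order UMI scan with a textbook DP edit distance) used to cross-check
the statistical primitives against a second, library-free route.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pandas as pd

from .diff_splicing import TestConfig, by_adjust, fisher_exact_2x2, test_exons
from .events import count_events, discover_alternative_exons
from .intervals import GenomicInterval
from .reads import ReadRecord, dedup_umis, filter_rare_chains, frame_to_reads, relabel_cell_type
from .simulate import (
    AltDonorSpec,
    GeneStructure,
    SimConfig,
    gene_models_for,
    simulate_dataset,
)
from .splice_sites import test_site_usage

# ---------------------------------------------------------------------------
# independent oracles


def hypergeom_fisher_p(table) -> float:
    """Two-sided Fisher p by full enumeration over all tables with the
    observed margins, summing hypergeometric probabilities <= that of the
    observed table (with a small relative tolerance for float ties)."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return float("nan")

    def prob(x: int) -> float:
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def by_stepup_formula(p_values) -> np.ndarray:
    """Hand application of the Benjamini-Yekutieli step-up formula."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    c_m = sum(1.0 / k for k in range(1, m + 1))
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, min(1.0, p[i] * m * c_m / rank))
        q_sorted[rank - 1] = running
    q = np.empty(m)
    q[order] = q_sorted
    return q


def dp_levenshtein(a: str, b: str) -> int:
    """Textbook Wagner-Fischer edit distance (independent of edlib)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(
                prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)
            ))
        prev = cur
    return prev[-1]


def brute_force_umi_survivors(
    umi_counts: dict[str, int], max_distance: int = 3
) -> set[str]:
    """All-pairs oracle for the rank-ordered greedy UMI retention rule."""
    ranked = sorted(umi_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    umis = [u for u, _ in ranked]
    dist = {
        (u, v): dp_levenshtein(u, v)
        for i, u in enumerate(umis)
        for v in umis[:i]
    }
    retained: list[str] = []
    for u in umis:
        close = any(
            dist.get((u, v), dist.get((v, u))) <= max_distance for v in retained
        )
        if not close:
            retained.append(u)
    return set(retained)


# ---------------------------------------------------------------------------
# oracle-equivalence measurements


def fisher_vs_enumeration(seed: int, n_tables: int = 1000, max_margin: int = 40) -> dict:
    """Max |p difference| between the Fisher implementation and the
    enumeration oracle over random tables with margins <= max_margin."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    done = 0
    while done < n_tables:
        a, b, c, d = rng.integers(0, 11, size=4)
        if min(a + b, c + d, a + c, b + d) == 0:
            continue
        p_impl, _ = fisher_exact_2x2([[a, b], [c, d]])
        p_oracle = hypergeom_fisher_p([[a, b], [c, d]])
        worst = max(worst, abs(p_impl - p_oracle))
        done += 1
    return {"max_abs_diff": worst, "n": n_tables}


def by_vs_formula(seed: int, n_trials: int = 200, max_m: int = 50) -> dict:
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_trials):
        m = int(rng.integers(1, max_m + 1))
        p = rng.random(m)
        worst = max(worst, float(np.max(np.abs(by_adjust(p) - by_stepup_formula(p)))))
    return {"max_abs_diff": worst, "n": n_trials}


def _records_for_umis(umis: list[str]) -> list[ReadRecord]:
    span = GenomicInterval("chr1", 100, 200, "+")
    return [
        ReadRecord(f"r{i}", "s1", "case", "ct", "", "BC1", umi, "g1", span, ())
        for i, umi in enumerate(umis)
    ]


def dedup_vs_oracle(seed: int, n_groups: int = 50, max_group: int = 200) -> dict:
    """Fraction of random UMI groups where dedup survivors equal the
    all-pairs oracle's (single-edit variants injected to force conflicts)."""
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    agree = 0
    for _ in range(n_groups):
        n = int(rng.integers(5, max_group + 1))
        umis: list[str] = []
        for _ in range(n):
            if umis and rng.random() < 0.4:
                src = list(umis[rng.integers(0, len(umis))])
                pos = rng.integers(0, len(src))
                src[pos] = bases[rng.integers(0, 4)]
                umis.append("".join(src))
            else:
                umis.append("".join(bases[i] for i in rng.integers(0, 4, 10)))
        counts = Counter(umis)
        expected = brute_force_umi_survivors(counts)
        survivors = {r.umi for r in dedup_umis(_records_for_umis(umis))}
        agree += survivors == expected
    return {"agreement": agree / n_groups, "n": n_groups}


# ---------------------------------------------------------------------------
# simulation scenarios run through the full pipeline


def run_exon_pipeline(
    config: SimConfig, test_config: TestConfig | None = None,
    pseudobulk: bool = False,
) -> pd.DataFrame:
    """Simulate -> dedup -> chain filter -> discovery -> counting -> test."""
    table, _ = simulate_dataset(config)
    reads = frame_to_reads(table)
    reads = dedup_umis(reads)
    reads = filter_rare_chains(reads)
    if pseudobulk:
        reads = relabel_cell_type(reads, "pseudobulk")
    models = gene_models_for(config)
    exons = discover_alternative_exons(reads, models)
    counts = count_events(reads, exons)
    return test_exons(counts, test_config)


def _null_config(seed: int, n_exons: int) -> SimConfig:
    rng = np.random.default_rng(seed)
    genes = [
        GeneStructure(gene_id=f"g{i:04d}", chrom="chr1", start=1000 + i * 3000)
        for i in range(n_exons)
    ]
    planted = {}
    for g in genes:
        psi0 = float(rng.uniform(0.25, 0.75))
        planted[(g.gene_id, "ExN", "case")] = psi0
        planted[(g.gene_id, "ExN", "control")] = psi0
    return SimConfig(
        genes=genes, cell_types={"ExN": 12}, planted_psi=planted,
        reads_per_cell_mean=1.0, umi_error_rate=0.02, seed=seed,
    )


def null_calibration(seed: int, n_exons: int = 500, n_seeds: int = 10) -> dict:
    """False-call rate with no planted effect: fraction of gated exons
    declared significant, pooled over independent simulation seeds."""
    gated = 0
    called = 0
    for i in range(n_seeds):
        sub_seed = seed * 1000 + i
        res = run_exon_pipeline(_null_config(sub_seed, n_exons))
        in_family = res["q_by"].notna()
        gated += int(in_family.sum())
        called += int(res.loc[in_family, "significant"].sum())
    return {
        "significant_fraction": called / gated if gated else 0.0,
        "n_gated": gated, "n_seeds": n_seeds,
    }


def power_recovery(seed: int, n_exons: int = 50) -> dict:
    """Detection power and delta-psi accuracy for strong planted effects
    (delta psi = +/-0.4, ~300 informative reads per condition per exon)."""
    genes = [
        GeneStructure(gene_id=f"g{i:04d}", chrom="chr1", start=1000 + i * 3000)
        for i in range(n_exons)
    ]
    planted = {}
    truth_dpsi = {}
    for i, g in enumerate(genes):
        if i < n_exons // 2:
            pc, pk = 0.7, 0.3
        else:
            pc, pk = 0.3, 0.7
        planted[(g.gene_id, "ExN", "case")] = pc
        planted[(g.gene_id, "ExN", "control")] = pk
        truth_dpsi[g.gene_id] = pc - pk
    config = SimConfig(
        genes=genes, cell_types={"ExN": 25}, planted_psi=planted,
        reads_per_cell_mean=2.1, umi_error_rate=0.02, seed=seed,
    )
    res = run_exon_pipeline(config)
    res = res[res["gene_id"].isin(truth_dpsi)]
    errors = [
        abs(row.delta_psi - truth_dpsi[row.gene_id]) for row in res.itertuples()
    ]
    informative = (
        res[["inclusion_case", "exclusion_case"]].sum(axis=1).mean()
    )
    return {
        "called_fraction": float(res["significant"].sum()) / n_exons,
        "max_delta_psi_error": max(errors) if errors else float("nan"),
        "fraction_within_0.1": float(np.mean([e <= 0.10 for e in errors])),
        "mean_informative_per_condition": float(informative),
        "n_exons_tested": len(res),
        "n": n_exons,
    }


def masking_demo(seed: int, n_exons: int = 5) -> dict:
    """A planted effect confined to a 10%-abundance cell type: significant
    there, invisible (diluted) in pseudobulk."""
    genes = [
        GeneStructure(gene_id=f"g{i:04d}", chrom="chr1", start=1000 + i * 3000)
        for i in range(n_exons)
    ]
    planted = {}
    for g in genes:
        planted[(g.gene_id, "minor", "case")] = 0.75
        planted[(g.gene_id, "minor", "control")] = 0.25
        planted[(g.gene_id, "major", "case")] = 0.25
        planted[(g.gene_id, "major", "control")] = 0.25
    config = SimConfig(
        genes=genes, cell_types={"minor": 5, "major": 45},
        planted_psi=planted, reads_per_cell_mean=2.0,
        umi_error_rate=0.02, seed=seed,
    )
    table, _ = simulate_dataset(config)
    reads = frame_to_reads(table)
    reads = dedup_umis(reads)
    reads = filter_rare_chains(reads)
    models = gene_models_for(config)
    exons = discover_alternative_exons(reads, models)
    counts = count_events(reads, exons)
    res = test_exons(counts)
    pb_counts = count_events(relabel_cell_type(reads, "pseudobulk"), exons)
    pb_res = test_exons(pb_counts)

    minor = res[res["cell_type"] == "minor"]
    from .comparative import pseudobulk_masking

    summaries = {s.cell_type: s for s in pseudobulk_masking(res, pb_res)}
    minor_summary = summaries.get("minor")
    return {
        "minor_significant": int(minor["significant"].sum()),
        "pseudobulk_significant": int(pb_res["significant"].sum()),
        "masked_fraction": (
            minor_summary.fraction_masked if minor_summary else float("nan")
        ),
        "n": n_exons,
    }


def site_shift_recovery(seed: int, n_genes: int = 5) -> dict:
    """Planted alternative-donor usage shift of 0.3, measured back through
    the splice-site module."""
    genes = [
        GeneStructure(
            gene_id=f"g{i:04d}", chrom="chr1", start=1000 + i * 3000,
            alt_donor=AltDonorSpec(intron_index=0, shift=12,
                                   usage_case=0.8, usage_control=0.5),
        )
        for i in range(n_genes)
    ]
    config = SimConfig(
        genes=genes, cell_types={"ExN": 30}, reads_per_cell_mean=4.0,
        umi_error_rate=0.02, seed=seed,
    )
    table, truth = simulate_dataset(config)
    reads = frame_to_reads(table)
    reads = dedup_umis(reads)
    reads = filter_rare_chains(reads)
    res = test_site_usage(reads)
    # exon skipping itself creates a second donor group per gene; pick the
    # planted one by its fixed acceptor coordinate (intron 0's 3' end)
    donors = res[res["kind"] == "donor"].set_index(["gene_id", "fixed_end"])
    errors = []
    estimates = []
    n_sig = 0
    for g in genes:
        planted_shift = (
            truth.site_usage[(g.gene_id, "case")]
            - truth.site_usage[(g.gene_id, "control")]
        )
        row = donors.loc[(g.gene_id, g.introns[0][1])]
        estimates.append(float(row["delta_psi"]))
        errors.append(abs(estimates[-1] - planted_shift))
        n_sig += bool(row["significant"])
    return {
        "max_recovery_error": max(errors),
        "mean_estimated_shift": float(np.mean(estimates)),
        "n_significant": n_sig,
        "n": n_genes,
    }


# ---------------------------------------------------------------------------
# probe-design toy fixture


def probe_toy_fixture(seed: int = 7):
    """Toy annotation (3 genes, 12 junctions) plus a synthetic genome with
    a repeat region, exercising the short-exon extension, the <130-base
    discard, the multimapper discard, and the <5-probe gene drop.

    Returns (gene models, genome, expected hand-enumeration dict).
    """
    from .annotation import GeneModel
    from .probe_design import (
        default_probe_score,
        enumerate_junction_windows,
        select_120mer,
    )

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    chrom_len = 20000
    seq = "".join(bases[rng.integers(0, 4, chrom_len)])

    def gene(gene_id, start, exon_lengths, intron=200):
        exons = []
        pos = start
        for L in exon_lengths:
            exons.append(GenomicInterval("chrT", pos, pos + L - 1, "+"))
            pos += L + intron
        m = GeneModel(gene_id, gene_id, "chrT", "+")
        m.transcripts[f"{gene_id}.t1"] = exons
        m.validate()
        return m

    # geneA: 7 exons, 6 junctions; exon 4 is 40 bp with an 80 bp neighbor
    # upstream, so the window for junction 4-5 must extend across two exons.
    gene_a = gene("geneA", 500, [100, 100, 100, 80, 40, 100, 100])
    # geneB: first exon 55 bp -> junction 1 window is 55+70=125 < 130,
    # discarded; only 1 candidate survives -> the whole gene is dropped.
    gene_b = gene("geneB", 6000, [55, 100, 100])
    # geneC: 5 exons, 4 junctions, all clean -> dropped (fewer than 5 probes).
    gene_c = gene("geneC", 9000, [100, 100, 100, 100, 100])
    models = {g.gene_id: g for g in (gene_a, gene_b, gene_c)}

    genome = {"chrT": seq}
    # plant a repeat: 6 copies of geneA junction-0's selected 120-mer in a
    # decoy contig, pushing that probe past the 5-hit cap
    candidates = enumerate_junction_windows(models, genome)
    target = next(
        c for c in candidates
        if c.gene_id == "geneA" and c.junction.donor_pos == gene_a.transcripts["geneA.t1"][0].end + 1
    )
    select_120mer(target, score=default_probe_score)
    spacer = "".join(bases[rng.integers(0, 4, 50)])
    genome["chrRepeat"] = spacer + (target.probe_seq + spacer) * 6

    expected = {
        "n_candidates": 11,  # 12 junctions - 1 short window (geneB jn 1)
        "retained_genes": {"geneA"},
        "retained_probes": 5,  # geneA: 6 junctions - 1 multimapper
        "dropped_multimapper": target.name,
    }
    return models, genome, expected


def probe_toy(seed: int = 7) -> dict:
    from .probe_design import (
        enumerate_junction_windows,
        exact_match_mappability,
        filter_and_select_probes,
    )

    models, genome, expected = probe_toy_fixture(seed)
    candidates = enumerate_junction_windows(models, genome)
    probes = filter_and_select_probes(
        candidates, exact_match_mappability(genome)
    )
    return {
        "n_candidates": len(candidates),
        "n_probes": len(probes),
        "n_genes": len({p.gene_id for p in probes}),
        "expected_candidates": expected["n_candidates"],
        "expected_probes": expected["retained_probes"],
        "n": len(candidates),
    }


# ---------------------------------------------------------------------------
# worked examples from printed values


def ptprk_worked_examples() -> dict:
    """Delta psi recomputed from the printed inclusion fractions of the
    PTPRK exon: 90% -> 83% in excitatory and 90% -> 37% in inhibitory
    neurons, in percentage points."""
    from .diff_splicing import delta_psi, psi

    excitatory = delta_psi(psi(83, 17), psi(90, 10)) * 100
    inhibitory = delta_psi(psi(37, 63), psi(90, 10)) * 100
    return {
        "excitatory_delta_psi_pct": round(excitatory, 10),
        "inhibitory_delta_psi_pct": round(inhibitory, 10),
    }
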