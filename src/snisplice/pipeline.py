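"""End-to-end pipeline orchestration.

Runs dedup -> rare-chain filter -> exon discovery and event counting ->
per-cell-type, per-subtype and pseudobulk exon tests -> splice-site tests
-> masking / correlation / expression-overlap summaries, and writes a
manifest recording versions, seed, thresholds, and row counts per stage.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import load_gene_models
from .comparative import (
    de_gene_set,
    delta_psi_correlation,
    expression_overlap,
    masking_to_frame,
    pseudobulk_masking,
)
from .diff_splicing import TestConfig, test_exons, write_results
from .events import count_events, discover_alternative_exons, write_counts
from .reads import (
    dedup_umis,
    filter_rare_chains,
    parse_read_table,
    relabel_cell_type,
    use_subtype_labels,
)
from .splice_sites import SiteTestConfig, test_site_usage, write_site_results

log = logging.getLogger("snisplice")

PSEUDOBULK_LABEL = "pseudobulk"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class PipelineConfig:
    reads: str
    gtf: str
    out_dir: str
    de_table: str | None = None
    test: TestConfig = field(default_factory=TestConfig)
    site_test: SiteTestConfig = field(default_factory=SiteTestConfig)
    dedup_max_distance: int = 3
    dedup_scope: str = "barcode-gene"
    chain_min_count: int = 5
    min_observed_support: int = 2
    run_subtypes: bool = True
    run_overlap: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def digest(self) -> str:
        """Fingerprint of the analysis parameters (where outputs land and
        how verbosely we log do not change the analysis)."""
        payload = {**asdict(self), "version": __version__}
        payload.pop("out_dir")
        payload.pop("log_level")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _header(config: PipelineConfig) -> str:
    return f"snisplice {__version__} seed={config.seed} config_sha={config.digest()}"


def _stage(name: str, func, *args, **kwargs):
    try:
        return func(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage '{name}' failed: {exc}") from exc


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the output directory."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_sha": config.digest(),
        "thresholds": {
            "exon_test": asdict(config.test),
            "site_test": asdict(config.site_test),
            "dedup_max_distance": config.dedup_max_distance,
            "chain_min_count": config.chain_min_count,
        },
        "stages": {},
    }
    if config.run_overlap and not config.de_table:
        raise PipelineError(
            "stage 'overlap' requested but no DE table was provided"
        )

    reads = _stage("parse", parse_read_table, config.reads)
    manifest["stages"]["parse"] = {"rows": len(reads)}
    log.info("parsed %d reads", len(reads))

    reads = _stage(
        "dedup", dedup_umis, reads,
        max_distance=config.dedup_max_distance, scope=config.dedup_scope,
    )
    manifest["stages"]["dedup"] = {"rows": len(reads)}

    reads = _stage(
        "filter-chains", filter_rare_chains, reads, min_count=config.chain_min_count
    )
    manifest["stages"]["filter_chains"] = {"rows": len(reads)}

    models = _stage("annotation", load_gene_models, config.gtf)
    exons = _stage(
        "discover", discover_alternative_exons, reads, models,
        min_observed_support=config.min_observed_support,
    )
    counts = _stage(
        "count-events", count_events, reads, exons, flank=config.test.flank
    )
    write_counts(counts, out / "counts.tsv", _header(config))
    manifest["stages"]["count_events"] = {
        "alt_exons": len(exons), "rows": len(counts)
    }

    results = _stage("test-exons", test_exons, counts, config.test)
    write_results(results, out / "exon_tests.tsv", _header(config))
    manifest["stages"]["test_exons"] = {
        "rows": len(results), "significant": int(results["significant"].sum())
    }

    pb_reads = relabel_cell_type(reads, PSEUDOBULK_LABEL)
    pb_counts = _stage(
        "count-events-pseudobulk", count_events, pb_reads, exons,
        flank=config.test.flank,
    )
    pb_results = _stage("test-exons-pseudobulk", test_exons, pb_counts, config.test)
    write_results(pb_results, out / "exon_tests.pseudobulk.tsv", _header(config))
    manifest["stages"]["test_exons_pseudobulk"] = {
        "rows": len(pb_results),
        "significant": int(pb_results["significant"].sum()),
    }

    subtype_reads = use_subtype_labels(reads)
    if config.run_subtypes and subtype_reads:
        st_counts = _stage(
            "count-events-subtypes", count_events, subtype_reads, exons,
            flank=config.test.flank,
        )
        st_results = _stage("test-exons-subtypes", test_exons, st_counts, config.test)
        write_results(st_results, out / "exon_tests.subtypes.tsv", _header(config))
        manifest["stages"]["test_exons_subtypes"] = {"rows": len(st_results)}

    site_results = _stage("test-sites", test_site_usage, reads, config.site_test)
    write_site_results(site_results, out / "site_tests.tsv", _header(config))
    manifest["stages"]["test_sites"] = {
        "rows": len(site_results),
        "significant": int(site_results["significant"].sum()),
    }

    masking = _stage("masking", pseudobulk_masking, results, pb_results)
    masking_df = masking_to_frame(masking)
    _write_tsv(masking_df, out / "masking.tsv", _header(config))
    manifest["stages"]["masking"] = {"rows": len(masking_df)}

    corr_rows = []
    cell_types = sorted(results["cell_type"].unique())
    for a, b in itertools.combinations(cell_types, 2):
        corr = delta_psi_correlation(
            results[results["cell_type"] == a], results[results["cell_type"] == b]
        )
        corr_rows.append({"cell_type_a": a, "cell_type_b": b, **corr})
    corr_df = pd.DataFrame(corr_rows)
    _write_tsv(corr_df, out / "correlations.tsv", _header(config))
    manifest["stages"]["correlations"] = {"rows": len(corr_df)}

    if config.run_overlap:
        de_table = _stage(
            "overlap", pd.read_csv, config.de_table, sep="\t", comment="#"
        )
        overlap_rows = []
        for ct in cell_types:
            ct_res = results[results["cell_type"] == ct]
            spliced = set(ct_res.loc[ct_res["significant"], "gene_id"])
            tested_splicing = set(ct_res.loc[ct_res["q_by"].notna(), "gene_id"])
            de_sig, de_universe = de_gene_set(de_table, cell_type=ct)
            universe = tested_splicing & de_universe
            if not universe:
                continue
            r = expression_overlap(spliced, de_sig, universe, cell_type=ct)
            overlap_rows.append(
                {"cell_type": ct, "both": r.both, "spliced_only": r.spliced_only,
                 "de_only": r.de_only, "neither": r.neither,
                 "odds_ratio": r.odds_ratio,
                 "odds_ratio_corrected": r.odds_ratio_corrected,
                 "p_value": r.p_value}
            )
        _write_tsv(pd.DataFrame(overlap_rows), out / "overlap.tsv", _header(config))
        manifest["stages"]["overlap"] = {"rows": len(overlap_rows)}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def _write_tsv(df: pd.DataFrame, path: os.PathLike, header_comment: str) -> None:
    with open(path, "w") as fh:
        for line in header_comment.splitlines():
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
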