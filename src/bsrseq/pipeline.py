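"""End-to-end orchestration: simulate -> filter -> linkage -> intersect ->
DEG contrasts -> candidate integration, with a run manifest.

All stage outputs are plain TSV/JSON/GFF3; identical config and seed give
byte-identical outputs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .bsa_linkage import (
    LinkageModelConfig,
    assign_snps_to_genes,
    call_high_probability,
    intersect_high_probability,
    linkage_scan,
    summarize_by_chromosome,
)
from .candidate_integration import integrate_snp_deg, overlap_deg_sets
from .errors import ConfigError, StageError
from .expression_deg import DegConfig, call_degs, significant_degs, summarize_fold_bins
from .formats_io import (
    ReadQcConfig,
    read_allele_counts,
    read_count_matrix,
    read_gene_models,
    write_gene_models,
)
from .snp_filtering import SnpFilterConfig, filter_sites
from .synthetic_data import (
    CONDITIONS,
    POOLS,
    SimulationConfig,
    sample_name,
    simulate_dataset,
)

log = logging.getLogger("bsrseq")


@dataclass
class PipelineConfig:
    """Nested configuration of every stage plus global seed and output dir."""

    seed: int = 42
    outdir: str = "bsrseq_out"
    simulate: bool = True
    counts_files: dict = field(default_factory=dict)  # condition -> TSV path
    expression_file: str | None = None
    genes_file: str | None = None
    log_level: str = "INFO"
    read_qc: ReadQcConfig = field(default_factory=ReadQcConfig)
    snp_filter: SnpFilterConfig = field(default_factory=SnpFilterConfig)
    linkage: LinkageModelConfig = field(default_factory=LinkageModelConfig)
    deg: DegConfig = field(default_factory=DegConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self):
        # the global seed governs the simulation unless overridden explicitly
        self.simulation = dataclasses.replace(self.simulation, seed=self.seed)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sections = {
            "read_qc": ReadQcConfig,
            "snp_filter": SnpFilterConfig,
            "linkage": LinkageModelConfig,
            "deg": DegConfig,
            "simulation": SimulationConfig,
        }
        kwargs = {}
        for key, value in data.items():
            if key in sections:
                if isinstance(value, dict):
                    if key == "simulation" and "chromosomes" in value:
                        value = dict(value)
                        value["chromosomes"] = tuple(
                            (str(n), int(l)) for n, l in value["chromosomes"]
                        )
                    value = sections[key](**value)
                kwargs[key] = value
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages and return the run manifest.

    Inputs either come from ``cfg.counts_files`` / ``cfg.expression_file`` /
    ``cfg.genes_file`` or are simulated when ``cfg.simulate``.  Every stage
    failure is re-raised as a StageError naming the stage.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    # -- inputs --------------------------------------------------------------
    stage = "inputs"
    try:
        if cfg.simulate:
            data = simulate_dataset(cfg.simulation)
            tables = data.allele_counts
            expression = data.expression
            genes = data.genes
            for cond, table in tables.items():
                path = outdir / f"allele_counts_{cond}.tsv"
                table.to_tsv(path)
                outputs[f"allele_counts_{cond}"] = path
            path = outdir / "expression_counts.tsv"
            expression.to_tsv(path)
            outputs["expression_counts"] = path
            path = outdir / "genes.gff3"
            write_gene_models(genes, path)
            outputs["genes"] = path
            path = outdir / "truth_snps.tsv"
            data.truth.snps.to_csv(path, sep="\t", index=False)
            outputs["truth_snps"] = path
            path = outdir / "truth_de.tsv"
            data.de_truth.to_csv(path, sep="\t", index=False)
            outputs["truth_de"] = path
        else:
            missing = [c for c in CONDITIONS if c not in cfg.counts_files]
            if missing:
                raise ConfigError(f"no counts file for conditions {missing} "
                                  "and simulation disabled")
            tables = {
                cond: read_allele_counts(cfg.counts_files[cond])
                for cond in CONDITIONS
            }
            expression = (
                read_count_matrix(cfg.expression_file) if cfg.expression_file else None
            )
            genes = read_gene_models(cfg.genes_file) if cfg.genes_file else []
            data = None
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # -- SNP filtering (typing pooled across conditions) ---------------------
    stage = "filter-snps"
    try:
        combined = pd.concat([t.frame for t in tables.values()], ignore_index=True)
        from .formats_io import AlleleCountTable

        filtered = filter_sites(AlleleCountTable(combined), cfg.snp_filter)
        path = outdir / "filtered_counts.tsv"
        filtered.table.to_tsv(path)
        outputs["filtered_counts"] = path
        path = outdir / "filter_summary.json"
        _write_json(filtered.summary, path)
        outputs["filter_summary"] = path
        log.info("filter-snps: %s", filtered.summary)
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # -- linkage per condition ----------------------------------------------
    stage = "linkage"
    try:
        scans = {}
        calls = {}
        for cond in CONDITIONS:
            scan = linkage_scan(filtered, cond, cfg.linkage)
            scans[cond] = scan
            calls[cond] = call_high_probability(scan, cfg.linkage.call_threshold)
            path = outdir / f"linkage_{cond}.tsv"
            scan.to_csv(path, sep="\t", index=False)
            outputs[f"linkage_{cond}"] = path
            # plot-ready track: position vs posterior with the call flag
            track = scan[["chrom", "pos", "posterior", "high_probability"]]
            path = outdir / f"linkage_track_{cond}.tsv"
            track.to_csv(path, sep="\t", index=False)
            outputs[f"linkage_track_{cond}"] = path
            log.info("linkage[%s]: %d sites, %d high-probability",
                     cond, len(scan), len(calls[cond]))
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # -- cross-condition intersection ----------------------------------------
    stage = "intersect"
    try:
        overlap, report = intersect_high_probability(
            calls[CONDITIONS[0]], calls[CONDITIONS[1]]
        )
        path = outdir / "high_prob_overlap.tsv"
        overlap.to_csv(path, sep="\t", index=False)
        outputs["high_prob_overlap"] = path
        report["per_chromosome"] = {
            cond: summarize_by_chromosome(calls[cond]) for cond in CONDITIONS
        }
        path = outdir / "overlap_report.json"
        _write_json(report, path)
        outputs["overlap_report"] = path
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # -- DEG contrasts -------------------------------------------------------
    stage = "deg"
    deg_tables: dict[str, pd.DataFrame] = {}
    try:
        if expression is not None:
            reps = range(1, cfg.simulation.n_replicates + 1)
            contrasts = {
                "tolerant_waterlogged_vs_normal": (
                    [sample_name("tolerant", "waterlogged", r) for r in reps],
                    [sample_name("tolerant", "normal", r) for r in reps],
                ),
                "sensitive_waterlogged_vs_normal": (
                    [sample_name("sensitive", "waterlogged", r) for r in reps],
                    [sample_name("sensitive", "normal", r) for r in reps],
                ),
                "tolerant_vs_sensitive_normal": (
                    [sample_name("tolerant", "normal", r) for r in reps],
                    [sample_name("sensitive", "normal", r) for r in reps],
                ),
                "tolerant_vs_sensitive_waterlogged": (
                    [sample_name("tolerant", "waterlogged", r) for r in reps],
                    [sample_name("sensitive", "waterlogged", r) for r in reps],
                ),
            }
            for label, (side_a, side_b) in contrasts.items():
                if not set(side_a) <= set(expression.samples):
                    continue
                deg = call_degs(expression, side_a, side_b, cfg.deg)
                deg_tables[label] = deg
                path = outdir / f"deg_{label}.tsv"
                deg.to_csv(path, sep="\t")
                outputs[f"deg_{label}"] = path
                path = outdir / f"deg_bins_{label}.json"
                _write_json(summarize_fold_bins(significant_degs(deg)), path)
                outputs[f"deg_bins_{label}"] = path
                log.info("deg[%s]: %d significant", label,
                         int(deg["significant"].sum()))
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # -- candidate integration ----------------------------------------------
    stage = "integrate"
    try:
        annotated, histogram = assign_snps_to_genes(overlap, genes)
        cross_pool = {
            label: deg_tables[label]
            for label in ("tolerant_vs_sensitive_normal",
                          "tolerant_vs_sensitive_waterlogged")
            if label in deg_tables
        }
        candidates = integrate_snp_deg(annotated, cross_pool, genes)
        path = outdir / "candidates.tsv"
        candidates.to_csv(path, sep="\t", index=False)
        outputs["candidates"] = path
        integration_report = {"snps_per_gene_histogram": histogram}
        if len(cross_pool) == 2:
            labels = list(cross_pool)
            integration_report["deg_overlap"] = overlap_deg_sets(
                cross_pool[labels[0]], cross_pool[labels[1]]
            ).counts
        path = outdir / "integration_report.json"
        _write_json(integration_report, path)
        outputs["integration_report"] = path
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # -- manifest ------------------------------------------------------------
    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "outputs": {name: _sha256(path) for name, path in sorted(outputs.items())},
    }
    _write_json(manifest, outdir / "manifest.json")
    return manifest
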