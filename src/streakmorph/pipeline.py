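"""Run configuration and end-to-end pipeline orchestration.

A run consumes the annotation tables (sections, RPE traces, protein
matrix + group mapping), executes the metric, mosaic, statistics and
differential-abundance stages in order, and writes one output directory:
densities.tsv, summary.json, mosaic.tsv, mosaic_summary.json, stats.tsv,
diff_results.tsv, run_log.json and a manifest with SHA-256 checksums of
every input and output plus all seeds.  Given identical inputs and seeds
the numeric outputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .groupstats import stats_table
from .io import (
    SchemaError,
    load_protein_matrix,
    sections_from_table,
    traces_from_table,
    validate_and_load,
    write_table,
)
from .photoreceptors import density_table, per_animal_means, region_summary
from .proteomics import group_completeness_filter, log2_transform, permutation_fdr_ttest
from .rpe import analyze_region

logger = logging.getLogger("streakmorph")

CONFIG_VERSION = 1


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    sections: str | None = None
    traces: str | None = None
    proteins: str | None = None
    groups: str | None = None
    out_dir: str = "streakmorph_out"
    regions: list[str] = field(default_factory=lambda: ["VS", "NP", "FP"])
    window_width_um: float = 100.0
    window_thickness_um: float = 12.0
    segment_length_um: float = 250.0
    metrics: list[str] = field(
        default_factory=lambda: [
            "cone_density",
            "rod_density",
            "rcr",
            "os_length",
            "rpe_height",
            "phagosomes_per_cell",
        ]
    )
    binucleate_mode: str = "midpoint"  # or "remove"
    n_permutations: int = 250
    fdr_threshold: float = 0.05
    s0: str | float = "auto"
    seed: int = 0
    log_level: str = "INFO"
    config_version: int = CONFIG_VERSION

    def __post_init__(self) -> None:
        if self.config_version != CONFIG_VERSION:
            raise ValueError(
                f"unsupported config_version {self.config_version} "
                f"(this package reads version {CONFIG_VERSION})"
            )
        if self.window_width_um <= 0 or self.window_thickness_um <= 0:
            raise ValueError("window geometry must be positive")
        if self.segment_length_um <= 0:
            raise ValueError("segment_length_um must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - stage name must surface
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


@_stage("densities")
def _run_densities(config: RunConfig, outdir: Path) -> list[Path]:
    df = validate_and_load(config.sections, "sections")
    records = sections_from_table(df, known_regions=config.regions)
    dens = density_table(records)
    rows = []
    for d in dens:
        rows.append(
            {
                "region": d.region,
                "n_animals": d.n_animals,
                "cone_density_per_mm2_mean": d.cone_density_mean,
                "cone_density_per_mm2_sd": d.cone_density_sd,
                "rod_density_per_mm2_mean": d.rod_density_mean,
                "rod_density_per_mm2_sd": d.rod_density_sd,
                "rcr_mean": d.rcr_mean,
                "rcr_sd": d.rcr_sd,
                "rcr_median": d.rcr_median,
                "rcr_q25": d.rcr_q25,
                "rcr_q75": d.rcr_q75,
                "rcr_of_means": d.rcr_of_means,
            }
        )
    order = {r: i for i, r in enumerate(config.regions)}
    table = pd.DataFrame(rows).sort_values("region", key=lambda s: s.map(order))
    p1 = write_table(table, outdir / "densities.tsv")

    summaries = {}
    for metric in config.metrics:
        summaries[metric] = region_summary(records, metric).to_dict(orient="records")
    p2 = outdir / "summary.json"
    p2.write_text(json.dumps(summaries, indent=2, default=float))
    return [p1, p2]


@_stage("mosaic")
def _run_mosaic(config: RunConfig, outdir: Path) -> list[Path]:
    df = validate_and_load(config.traces, "traces")
    traces = traces_from_table(df)
    unknown = {t.region for t in traces} - set(config.regions)
    if unknown:
        raise SchemaError(f"unknown region label(s) in traces: {sorted(unknown)}")
    rows = []
    summary = {}
    for region in config.regions:
        region_traces = [t for t in traces if t.region == region]
        if not region_traces:
            continue
        res = analyze_region(region_traces, region=region, mode=config.binucleate_mode)
        rows.append(
            {
                "region": region,
                "n_traces": len(region_traces),
                "n_nuclei": int(sum(t.n_nuclei for t in region_traces)),
                "median_distance_um": res.median_distance,
                "lower_threshold_um": res.lower_threshold,
                "upper_threshold_um": res.upper_threshold,
                "binucleate_fraction": res.binucleate_fraction,
                "binucleate_cell_prob": res.binucleate_cell_prob,
                "dropout_fraction": res.dropout_fraction,
                "mean_corrected_distance_um": res.mean_corrected_distance,
                "cell_area_um2": res.cell_area,
                "cell_area_per_gap_um2": res.cell_area_per_gap,
                "hexagon_side_um": res.hexagon_side,
                "hexagon_height_um": res.hexagon_height,
            }
        )
        summary[region] = rows[-1]
    p1 = write_table(pd.DataFrame(rows), outdir / "mosaic.tsv")
    p2 = outdir / "mosaic_summary.json"
    p2.write_text(json.dumps(summary, indent=2, default=float))
    return [p1, p2]


@_stage("stats")
def _run_stats(config: RunConfig, outdir: Path) -> list[Path]:
    df = validate_and_load(config.sections, "sections")
    records = sections_from_table(df, known_regions=config.regions)
    tables = []
    for metric in config.metrics:
        per_animal = per_animal_means(records, metric)
        present = [r for r in config.regions if r in set(per_animal["region"])]
        if len(present) < 2:
            continue
        tables.append(stats_table(per_animal, metric, group_order=present))
        # the two-group comparisons the study reports for RPE metrics:
        # visual streak against the far periphery
        if len(present) == 3 and metric in ("rpe_height", "phagosomes_per_cell"):
            two = per_animal[per_animal["region"].isin([present[0], present[-1]])]
            tables.append(
                stats_table(two, metric, group_order=[present[0], present[-1]])
            )
    out = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    return [write_table(out, outdir / "stats.tsv")]


@_stage("proteomics")
def _run_proteomics(config: RunConfig, outdir: Path) -> list[Path]:
    matrix = load_protein_matrix(config.proteins, config.groups)
    filtered, n_kept, n_removed = group_completeness_filter(matrix)
    logged = log2_transform(filtered)
    results, info = permutation_fdr_ttest(
        logged,
        n_permutations=config.n_permutations,
        fdr_threshold=config.fdr_threshold,
        seed=config.seed,
        s0=config.s0 if config.s0 == "auto" else float(config.s0),
    )
    p1 = write_table(results, outdir / "diff_results.tsv")
    run_log = {
        "seed": config.seed,
        "n_permutations_requested": config.n_permutations,
        "n_permutations_used": info.n_permutations,
        "exhaustive_enumeration": info.exhaustive,
        "s0": info.s0,
        "fdr_threshold": config.fdr_threshold,
        "proteins_retained": n_kept,
        "proteins_removed": n_removed,
        "n_significant": int(results["significant"].sum()),
    }
    p2 = outdir / "run_log.json"
    p2.write_text(json.dumps(run_log, indent=2))
    return [p1, p2]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage with inputs configured, write a manifest, and
    return it."""
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    outputs: list[Path] = []
    stages_run: list[str] = []
    if config.sections:
        logger.info("densities stage: %s", config.sections)
        outputs += _run_densities(config, outdir)
        stages_run.append("densities")
        logger.info("stats stage")
        outputs += _run_stats(config, outdir)
        stages_run.append("stats")
    if config.traces:
        logger.info("mosaic stage: %s", config.traces)
        outputs += _run_mosaic(config, outdir)
        stages_run.append("mosaic")
    if config.proteins and config.groups:
        logger.info("proteomics stage: %s", config.proteins)
        outputs += _run_proteomics(config, outdir)
        stages_run.append("proteomics")
    if not stages_run:
        raise PipelineError("no inputs configured: nothing to run")

    inputs = {
        name: {"path": str(p), "sha256": _sha256(Path(p))}
        for name, p in (
            ("sections", config.sections),
            ("traces", config.traces),
            ("proteins", config.proteins),
            ("groups", config.groups),
        )
        if p
    }
    manifest = {
        "package": "streakmorph",
        "version": __version__,
        "seed": config.seed,
        "stages": stages_run,
        "config": {k: v for k, v in asdict(config).items()},
        "inputs": inputs,
        "outputs": {
            p.name: {"path": str(p), "sha256": _sha256(p)} for p in outputs
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
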