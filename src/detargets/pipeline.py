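"""End-to-end orchestration: simulate -> normalize/DE -> ORA -> targets,
with a deterministic run manifest.

Given one config and seed the whole run is reproducible byte for byte:
all tables go through :func:`detargets.formats.write_results` and the
manifest contains no timestamps.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .formats import (
    ExpressionTable,
    IntervalTable,
    PipelineError,
    ValidationError,
    read_bed,
    read_expression,
    read_gene_list,
    read_gmt,
    read_probe_map,
    write_results,
)
from . import diffexpr, ora, targets as tg
from .simulate import SimConfig, simulate_experiment

logger = logging.getLogger("detargets")


@dataclass
class RunConfig:
    """All paths, thresholds and flags of one pipeline run."""

    out_dir: Path = Path("detargets_out")
    expression_path: Path | None = None
    groups_path: Path | None = None
    genes_path: Path | None = None
    peak_paths: dict[str, Path] = field(default_factory=dict)
    gmt_path: Path | None = None
    background_path: Path | None = None
    probe_map_path: Path | None = None
    fdr_threshold: float = 0.05
    window_bp: int = 1000
    min_set_size: int = 2
    anchor: str = "gene"
    scale: str = "log2"
    skip_normalize: bool = False
    welch: bool = False
    seed: int = 0
    simulate: SimConfig | None = None

    def validate(self) -> None:
        if not 0 < self.fdr_threshold < 1:
            raise ValidationError("fdr_threshold must lie in (0, 1)")
        if self.window_bp < 0:
            raise ValidationError("window_bp must be >= 0")
        if self.min_set_size < 1:
            raise ValidationError("min_set_size must be >= 1")
        if self.anchor not in ("gene", "tss"):
            raise ValidationError("anchor must be 'gene' or 'tss'")


def _require(path: Path | None, what: str) -> Path:
    if path is None:
        raise ValidationError(f"{what} not configured")
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{what} not found: {path}")
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and return the manifest.

    Stage errors propagate as :class:`ValidationError` /
    :class:`PipelineError` carrying a stage-named message.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    manifest: dict = {
        "versions": {
            "detargets": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
        "seed": config.seed,
        "parameters": {
            "fdr_threshold": config.fdr_threshold,
            "window_bp": config.window_bp,
            "min_set_size": config.min_set_size,
            "anchor": config.anchor,
            "skip_normalize": config.skip_normalize,
            "welch": config.welch,
        },
        "counts": {},
        "warnings": [],
    }
    tables: dict[str, pd.DataFrame] = {}

    # ---- stage: simulate -------------------------------------------------
    genes: IntervalTable | None = None
    peaks: dict[str, IntervalTable] = {}
    expression: ExpressionTable | None = None
    if config.simulate is not None:
        sim = replace(config.simulate, seed=config.seed)
        bundle = simulate_experiment(sim, out_dir / "sim")
        expression = bundle.expression
        genes = bundle.genes
        peaks = bundle.peaks
        manifest["parameters"]["simulate"] = asdict(sim)
        manifest["counts"]["simulated_genes"] = len(bundle.genes)
        manifest["counts"]["simulated_de_up"] = len(bundle.truth.de_up)
        manifest["counts"]["simulated_de_down"] = len(bundle.truth.de_down)

    # ---- stage: load inputs ----------------------------------------------
    try:
        if expression is None:
            expression = read_expression(
                _require(config.expression_path, "expression matrix"),
                _require(config.groups_path, "sample group table"),
                scale=config.scale,
            )
        if genes is None and config.genes_path is not None:
            genes = read_bed(_require(config.genes_path, "gene-model BED"))
        for subunit, path in config.peak_paths.items():
            peaks[subunit] = read_bed(_require(path, f"{subunit} peak BED"))
    except (ValidationError, PipelineError) as exc:
        raise type(exc)(f"stage 'load': {exc}") from exc

    manifest["counts"]["features"] = len(expression.feature_ids)
    manifest["counts"]["samples"] = len(expression.sample_ids)

    # ---- stage: differential expression ----------------------------------
    try:
        probe_map = (read_probe_map(config.probe_map_path)
                     if config.probe_map_path else None)
        det = diffexpr.differential_expression(
            expression,
            fdr_threshold=config.fdr_threshold,
            normalize=not config.skip_normalize,
            welch=config.welch,
            probe_map=probe_map,
        )
    except (ValidationError, PipelineError) as exc:
        raise type(exc)(f"stage 'deg': {exc}") from exc
    up = diffexpr.up_genes(det)
    down = diffexpr.down_genes(det)
    manifest["counts"]["genes_tested"] = len(det)
    manifest["counts"]["de_total"] = int(det["is_de"].sum())
    manifest["counts"]["de_up"] = len(up)
    manifest["counts"]["de_down"] = len(down)
    tables["de_table"] = det
    volcano = det[["diff", "p_value", "q_value"]].copy()
    with np.errstate(divide="ignore"):
        volcano["neg_log10_p"] = -np.log10(det["p_value"])
    tables["volcano"] = volcano

    # ---- stage: ORA -------------------------------------------------------
    if config.gmt_path is not None:
        try:
            collection = read_gmt(_require(config.gmt_path, "GMT file"))
            background = (read_gene_list(_require(config.background_path,
                                                  "background list"))
                          if config.background_path else set(det.index))
            study = up | down
            records = ora.ora_analyze(
                study, collection, background,
                min_set_size=config.min_set_size,
                fdr_threshold=config.fdr_threshold,
            )
        except (ValidationError, PipelineError) as exc:
            raise type(exc)(f"stage 'ora': {exc}") from exc
        tables["ora"] = records
        manifest["counts"]["gene_sets_tested"] = len(records)
        manifest["counts"]["gene_sets_significant"] = int(
            records["significant"].sum()) if len(records) else 0

    # ---- stage: targets ----------------------------------------------------
    if genes is not None and peaks:
        try:
            records = tg.analyze_targets(
                genes, peaks, up, down, set(det.index),
                window_bp=config.window_bp, anchor=config.anchor,
            )
        except (ValidationError, PipelineError) as exc:
            raise type(exc)(f"stage 'targets': {exc}") from exc
        tables["target_enrichment"] = tg.records_to_frame(records)
        background = set(det.index) & set(genes.names)
        manifest["counts"]["target_background"] = len(background)
        manifest["counts"]["universe_without_coordinates"] = (
            len(det) - len(background)
        )
        for r in records:
            manifest["counts"][f"targets_{r.subunit}_{r.direction}"] = len(
                r.target_genes
            )

    paths = write_results(tables, out_dir, summary=manifest)
    manifest["outputs"] = {k: str(v) for k, v in paths.items()}
    return manifest
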