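"""Coupled synthetic expression, gene-model and ChIP-peak generator with
known ground truth.

The generator emulates the statistical structure of a small two-group
microarray study of fetal versus adult neutrophils: two groups of three
arrays, ~12,000 genes of which ~1% are differentially expressed (split
evenly up/down, log2 effect sizes 0.8-2.0), and per-subunit promoter
binding whose odds are multiplied by a configurable true odds ratio
(default 4.0 for RelB, 1.0 for the other NF-kB subunits) among up-DE
genes.  Every stage is a pure function of (config, seed); per-stage child
random streams are derived from the master seed by fixed labels, so
adding a stage never perturbs earlier stages.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .formats import (
    ExpressionTable,
    IntervalTable,
    PipelineError,
    ValidationError,
    write_bed,
    write_expression,
    write_json,
)

#: fixed labels for per-stage child random streams
_STAGE_LABELS = {"genome": 0, "expression": 1, "peaks": 2}

GROUP_A = "fetal"
GROUP_B = "adult"

CHROM = "chrS"


def _default_or_true() -> dict[str, float]:
    return {"p65": 1.0, "p50": 1.0, "RelB": 4.0, "p52": 1.0}


@dataclass
class SimConfig:
    """All knobs of the generator; defaults are the emulated study design."""

    n_genes: int = 12000
    n_per_group: int = 3
    pi_de: float = 0.01
    effect_size_range: tuple[float, float] = (0.8, 2.0)   # log2 units
    mu0: float = 7.0                                      # baseline mean, log2
    sd_mu: float = 2.0
    sd_noise_range: tuple[float, float] = (0.15, 0.45)
    p0_bound: float = 0.15
    or_true: dict[str, float] = field(default_factory=_default_or_true)
    enriched_direction: str = "up"   # which DE direction carries the OR
    gene_length_range: tuple[int, int] = (2000, 10000)    # bp
    intergap_range: tuple[int, int] = (5000, 50000)       # bp
    n_bg_peaks: int = 2000
    peak_length: int = 300
    window_bp: int = 1000
    exponentiate: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 0 or self.n_per_group < 2:
            raise ValidationError("need n_genes >= 0 and n_per_group >= 2")
        if not 0 <= self.pi_de <= 1 or not 0 <= self.p0_bound <= 1:
            raise ValidationError("pi_de and p0_bound must lie in [0, 1]")
        for name in ("effect_size_range", "sd_noise_range",
                     "gene_length_range", "intergap_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValidationError(f"{name} must be an ordered "
                                      "non-negative range")
        if any(v <= 0 for v in self.or_true.values()):
            raise ValidationError("or_true factors must be > 0")
        if self.enriched_direction not in ("up", "down", "both"):
            raise ValidationError("enriched_direction must be up/down/both")
        if self.n_bg_peaks < 0 or self.peak_length <= 0 or self.window_bp < 0:
            raise ValidationError("invalid peak geometry")

    @property
    def subunits(self) -> list[str]:
        return list(self.or_true)


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment."""

    de_up: set[str] = field(default_factory=set)
    de_down: set[str] = field(default_factory=set)
    bound: dict[str, set[str]] = field(default_factory=dict)
    or_true: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.de_up & self.de_down:
            raise ValidationError("de_up and de_down must be disjoint")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Child random stream for one named stage of the simulation."""
    label = _STAGE_LABELS[stage]
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(label,))
    )


# ---------------------------------------------------------------------------
# Stage 1: gene models
# ---------------------------------------------------------------------------

def simulate_genome(config: SimConfig, rng: np.random.Generator) -> IntervalTable:
    """Non-overlapping, coordinate-sorted gene intervals on one synthetic
    chromosome; lengths and intergenic gaps drawn uniformly from the
    configured ranges."""
    config.validate()
    n = config.n_genes
    lengths = rng.integers(config.gene_length_range[0],
                           config.gene_length_range[1] + 1, size=n)
    gaps = rng.integers(config.intergap_range[0],
                        config.intergap_range[1] + 1, size=n)
    strands = rng.choice(np.array(["+", "-"]), size=n)
    starts = np.cumsum(gaps) + np.concatenate(([0], np.cumsum(lengths)[:-1]))
    ends = starts + lengths
    width = max(5, len(str(max(n, 1))))
    names = [f"g{i + 1:0{width}d}" for i in range(n)]
    df = pd.DataFrame(
        {"chrom": CHROM, "start": starts.astype(np.int64),
         "end": ends.astype(np.int64), "name": names, "strand": strands}
    )
    if not n:
        df = pd.DataFrame(columns=["chrom", "start", "end", "name", "strand"]
                          ).astype({"start": np.int64, "end": np.int64})
    return IntervalTable(df)


# ---------------------------------------------------------------------------
# Stage 2: expression
# ---------------------------------------------------------------------------

def simulate_expression(config: SimConfig, genes: IntervalTable,
                        rng: np.random.Generator):
    """Log2-scale expression for two groups of ``n_per_group`` samples.

    Per gene: baseline ~ Normal(mu0, sd_mu); DE genes get a group-B shift
    of -delta ("up": higher in group A, the fetal analogue) or +delta
    ("down"), delta ~ Uniform(effect_size_range); i.i.d. noise
    Normal(0, sd_g) with sd_g ~ Uniform(sd_noise_range).

    Returns ``(ExpressionTable, SimTruth)`` with the binding fields of the
    truth still empty.
    """
    config.validate()
    if not len(genes):
        raise ValidationError("gene-model table is empty")
    names = np.array(genes.names)
    n = len(names)
    k = config.n_per_group
    n_de = int(np.floor(config.pi_de * n))
    if config.pi_de > 0 and n_de < 2:
        warnings.warn("pi_de * n_genes < 2: simulating zero DE genes",
                      stacklevel=2)
        n_de = 0
    de_idx = rng.choice(n, size=n_de, replace=False)
    n_up = n_de // 2
    up_idx = de_idx[:n_up]
    down_idx = de_idx[n_up:]
    baseline = rng.normal(config.mu0, config.sd_mu, size=n)
    deltas = rng.uniform(*config.effect_size_range, size=n_de)
    sd_g = rng.uniform(*config.sd_noise_range, size=n)
    noise = rng.normal(0.0, 1.0, size=(n, 2 * k)) * sd_g[:, None]

    X = baseline[:, None] + noise
    shift_b = np.zeros(n)
    shift_b[up_idx] = -deltas[:n_up]
    shift_b[down_idx] = deltas[n_up:]
    X[:, k:] += shift_b[:, None]  # columns k.. are group B (adult)

    samples = [f"{GROUP_A}_{i + 1}" for i in range(k)] + \
              [f"{GROUP_B}_{i + 1}" for i in range(k)]
    values = pd.DataFrame(X, index=pd.Index(names, name="feature_id"),
                          columns=samples)
    scale = "log2"
    if config.exponentiate:
        values = 2.0 ** values
        scale = "linear"
    groups = pd.Series([GROUP_A] * k + [GROUP_B] * k, index=samples,
                       name="group")
    table = ExpressionTable(values, groups, scale=scale)
    truth = SimTruth(de_up=set(names[up_idx]), de_down=set(names[down_idx]),
                     or_true=dict(config.or_true))
    return table, truth


# ---------------------------------------------------------------------------
# Stage 3: peaks
# ---------------------------------------------------------------------------

def _enriched_gene_set(config: SimConfig, truth: SimTruth) -> set[str]:
    if config.enriched_direction == "up":
        return set(truth.de_up)
    if config.enriched_direction == "down":
        return set(truth.de_down)
    return set(truth.de_up) | set(truth.de_down)


def simulate_peaks(config: SimConfig, genes: IntervalTable, truth: SimTruth,
                   rng: np.random.Generator) -> dict[str, IntervalTable]:
    """Per-subunit peak calls with known bound-gene truth.

    For each subunit, a gene is truth-bound with probability ``p1`` where
    ``odds(p1) = odds(p0_bound) * or_true`` for genes of the enriched DE
    direction and ``odds(p0_bound)`` otherwise.  Each truth-bound gene
    receives one peak placed uniformly at a gap <= ``window_bp`` from the
    gene; ``n_bg_peaks`` decoys land in intergenic space at gap >
    ``window_bp`` from every gene, so the downstream 1 kb rule recovers
    the truth exactly.  Updates ``truth.bound`` in place and returns the
    per-subunit peak tables.
    """
    config.validate()
    if not len(genes):
        raise ValidationError("gene-model table is empty")
    gdf = genes.sorted_by_position().df
    g_start = gdf["start"].to_numpy()
    g_end = gdf["end"].to_numpy()
    names = gdf["name"].to_numpy()
    n = len(names)
    w = config.window_bp
    L = config.peak_length
    enriched = np.isin(names, sorted(_enriched_gene_set(config, truth)))

    p0 = config.p0_bound
    peaks: dict[str, IntervalTable] = {}
    # intergenic free segments: before the first gene, between genes, and a
    # tail whose length is one extra intergap draw
    for subunit in config.subunits:
        r = config.or_true[subunit]
        if p0 in (0.0, 1.0):
            p1 = p0
        else:
            o1 = (p0 / (1.0 - p0)) * r
            p1 = o1 / (1.0 + o1)
        pvec = np.where(enriched, p1, p0)
        bound_mask = rng.random(n) < pvec
        b_start = g_start[bound_mask]
        b_end = g_end[bound_mask]
        lo = np.maximum(b_start - w - L, 0)
        hi = b_end + w  # inclusive upper bound for the peak start
        starts = rng.integers(lo, hi + 1)
        tp = pd.DataFrame(
            {"chrom": CHROM, "start": starts, "end": starts + L,
             "name": [f"{subunit}_tp{i + 1:05d}" for i in range(len(starts))],
             "strand": "."}
        )
        # decoys: uniform over intergenic positions > window from any gene
        tail = int(rng.integers(config.intergap_range[0],
                                config.intergap_range[1] + 1))
        seg_lo = np.concatenate(([0], g_end + w + 1))
        seg_hi = np.concatenate((g_start - w - 1 - L, [g_end[-1] + tail - L]))
        widths = np.maximum(seg_hi - seg_lo + 1, 0)
        total = widths.sum()
        if config.n_bg_peaks > 0:
            if total <= 0:
                raise PipelineError(
                    "insufficient intergenic space for decoy peaks; "
                    "increase intergap_range"
                )
            seg = rng.choice(len(widths), size=config.n_bg_peaks,
                             p=widths / total)
            offs = rng.integers(0, widths[seg])
            d_start = seg_lo[seg] + offs
            bg = pd.DataFrame(
                {"chrom": CHROM, "start": d_start, "end": d_start + L,
                 "name": [f"{subunit}_bg{i + 1:05d}"
                          for i in range(len(d_start))],
                 "strand": "."}
            )
            all_peaks = pd.concat([tp, bg], ignore_index=True)
        else:
            all_peaks = tp
        if not len(all_peaks):
            all_peaks = pd.DataFrame(
                columns=["chrom", "start", "end", "name", "strand"]
            ).astype({"start": np.int64, "end": np.int64})
        peaks[subunit] = IntervalTable(all_peaks).sorted_by_position()
        truth.bound[subunit] = set(names[bound_mask])
    return peaks


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class SimBundle:
    """Everything one simulated experiment produced."""

    config: SimConfig
    genes: IntervalTable
    expression: ExpressionTable
    peaks: dict[str, IntervalTable]
    truth: SimTruth
    paths: dict[str, Path] = field(default_factory=dict)


def simulate_experiment(config: SimConfig,
                        out_dir: str | Path | None = None) -> SimBundle:
    """Run all three generator stages from one master seed and optionally
    write every standard-format file (expression/groups TSV, genes BED,
    one BED per subunit, truth JSON).  Byte-identical per (config, seed).
    """
    config.validate()
    genes = simulate_genome(config, stage_rng(config.seed, "genome"))
    expression, truth = simulate_expression(
        config, genes, stage_rng(config.seed, "expression")
    )
    peaks = simulate_peaks(config, genes, truth, stage_rng(config.seed, "peaks"))
    bundle = SimBundle(config=config, genes=genes, expression=expression,
                       peaks=peaks, truth=truth)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "expression": out_dir / "expression.tsv",
            "groups": out_dir / "groups.tsv",
            "genes": out_dir / "genes.bed",
            "truth": out_dir / "truth.json",
        }
        write_expression(expression, paths["expression"], paths["groups"])
        write_bed(genes, paths["genes"])
        for subunit, table in peaks.items():
            paths[f"peaks_{subunit}"] = out_dir / f"peaks_{subunit}.bed"
            write_bed(table, paths[f"peaks_{subunit}"])
        truth_obj = {
            "de_up": sorted(truth.de_up),
            "de_down": sorted(truth.de_down),
            "bound": {s: sorted(v) for s, v in truth.bound.items()},
            "or_true": truth.or_true,
            "seed": config.seed,
            "scale": expression.scale,
        }
        write_json(truth_obj, paths["truth"])
        bundle.paths = paths
    return bundle
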