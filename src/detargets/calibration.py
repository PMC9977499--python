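"""Simulation-based calibration of the enrichment and DE statistics.

These helpers run the generator at its default study conditions and push
the output through the real analysis chain, measuring how well the known
ground truth is recovered: the sampling distribution of the estimated
binding odds ratio at the design's DE-set size (~60 up-regulated genes),
the type-I behaviour of the directional Fisher test when the true odds
ratio is 1, the false-positive behaviour of the BH-controlled DE calls on
null data, and the recall of spiked DE genes.
"""
from __future__ import annotations

from dataclasses import replace

import numpy as np

from .diffexpr import differential_expression, down_genes, up_genes
from .simulate import SimConfig, simulate_experiment
from .targets import assign_binding, subunit_enrichment

_MOD = 2 ** 31


def _seed(base: int, stream: int, i: int) -> int:
    # distinct sub-seeds per calibration stream, kept below 2**31
    return (int(base) * 1_000_003 + stream * 10_007 + i) % _MOD


def relb_or_estimate(seed: int, config: SimConfig | None = None,
                     subunit: str = "RelB") -> float:
    """Sample odds ratio of binding among the true up-DE genes.

    Simulates one experiment, assigns binding by the 1 kb rule and builds
    the Fisher table for the truth up-set over all simulated genes — the
    estimator whose consistency for the generator's true odds ratio the
    calibration suite checks.
    """
    cfg = replace(config or SimConfig(), seed=seed)
    bundle = simulate_experiment(cfg)
    bound = assign_binding(bundle.genes, bundle.peaks[subunit],
                           window_bp=cfg.window_bp)
    rec = subunit_enrichment(bundle.truth.de_up, bound,
                             set(bundle.genes.names), subunit, "up")
    return rec.odds_ratio


def relb_null_fisher_p(seed: int, subunit: str = "RelB") -> float:
    """Fisher p for the truth up-set when every subunit's true OR is 1."""
    cfg = SimConfig(or_true={"p65": 1.0, "p50": 1.0, "RelB": 1.0,
                             "p52": 1.0}, seed=seed)
    bundle = simulate_experiment(cfg)
    bound = assign_binding(bundle.genes, bundle.peaks[subunit],
                           window_bp=cfg.window_bp)
    rec = subunit_enrichment(bundle.truth.de_up, bound,
                             set(bundle.genes.names), subunit, "up")
    return rec.p_value


def median_or_recovery(base_seed: int, n_seeds: int = 25) -> float:
    """Median estimated up-direction odds ratio over replicate seeds."""
    ors = [relb_or_estimate(_seed(base_seed, 1, i)) for i in range(n_seeds)]
    return float(np.median(ors))


def null_rejection_rate(base_seed: int, n_reps: int = 200,
                        alpha: float = 0.05) -> float:
    """Fraction of or_true=1 replicates with Fisher p below alpha."""
    hits = sum(relb_null_fisher_p(_seed(base_seed, 2, i)) < alpha
               for i in range(n_reps))
    return hits / n_reps


def null_de_call_count(seed: int, n_genes: int = 2000,
                       fdr_threshold: float = 0.05) -> int:
    """Number of FDR<threshold DE calls on a pi_de=0 (null) simulation."""
    cfg = SimConfig(n_genes=n_genes, pi_de=0.0, n_bg_peaks=0,
                    or_true={"RelB": 1.0}, seed=seed)
    bundle = simulate_experiment(cfg)
    det = differential_expression(bundle.expression,
                                  fdr_threshold=fdr_threshold)
    return int(det["is_de"].sum())


def de_recall(seed: int, config: SimConfig | None = None,
              fdr_threshold: float = 0.05) -> float:
    """Fraction of truth-DE genes recovered at the FDR threshold."""
    cfg = replace(config or SimConfig(), seed=seed)
    bundle = simulate_experiment(cfg)
    det = differential_expression(bundle.expression,
                                  fdr_threshold=fdr_threshold)
    called = up_genes(det) | down_genes(det)
    truth = bundle.truth.de_up | bundle.truth.de_down
    if not truth:
        return float("nan")
    return len(called & truth) / len(truth)
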