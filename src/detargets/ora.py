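"""Hypergeometric over-representation analysis (ORA) of a study gene list
against GMT gene-set collections.

For a background universe of ``N`` genes containing a set of size ``K``,
and a study list of size ``n`` overlapping the set in ``k`` genes, the
enrichment p-value is the hypergeometric upper tail ``P[X >= k]`` and the
fold enrichment is ``(k/n) / (K/N)``.  Only over-representation is tested
(upper tail); q-values are BH across the sets actually tested in one run.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .diffexpr import bh_adjust
from .formats import GeneSetCollection, ValidationError

logger = logging.getLogger("detargets")

ORA_COLUMNS = ["set_name", "k", "n", "K", "N", "fold_enrichment",
               "p_value", "q_value", "significant"]


@dataclass
class EnrichmentRecord:
    """One gene set's over-representation result."""

    set_name: str
    k: int
    n: int
    K: int
    N: int
    fold_enrichment: float
    p_value: float
    q_value: float = float("nan")


def _log_choose(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """``P[X >= k]`` for ``X ~ Hypergeometric(N, K, n)``.

    ``N`` genes in the urn, ``K`` of them in the set, ``n`` drawn.
    Summed in log space for numerical stability.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise ValidationError(f"{name} must be a non-negative integer")
    k, K, n, N = int(k), int(K), int(n), int(N)
    if K > N or n > N:
        raise ValidationError("K and n cannot exceed N")
    if k > min(K, n):
        raise ValidationError("k cannot exceed min(K, n)")
    lo = max(0, n - (N - K))
    if k <= lo:
        return 1.0
    hi = min(K, n)
    j = np.arange(k, hi + 1)
    logpmf = (_log_choose(K, j) + _log_choose(N - K, n - j)
              - _log_choose(N, n))
    return float(min(1.0, np.exp(logsumexp(logpmf))))


def ora_analyze(study, collection: GeneSetCollection, background,
                min_set_size: int = 2,
                fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Test every gene set for over-representation in the study list.

    Each set is first intersected with the background; sets whose
    within-background size ``K`` falls below ``min_set_size`` are excluded
    before testing, so BH runs across tested sets only.  Study genes
    outside the background are dropped with a logged count.  Records are
    sorted by q ascending, then fold enrichment descending.
    """
    background = set(background)
    if not background:
        raise ValidationError("background gene universe is empty")
    study0 = set(study)
    study_set = study0 & background
    dropped = len(study0) - len(study_set)
    if dropped:
        logger.info("ora_analyze: dropped %d study genes outside the "
                    "background", dropped)
    if not study_set:
        raise ValidationError(
            "study list is empty after background intersection"
        )
    n = len(study_set)
    N = len(background)
    rows: list[EnrichmentRecord] = []
    for name, members in collection.sets.items():
        in_bg = set(members) & background
        K = len(in_bg)
        if K < min_set_size:
            continue
        k = len(in_bg & study_set)
        fold = (k / n) / (K / N)
        p = hypergeom_upper_tail(k, K, n, N)
        rows.append(EnrichmentRecord(name, k, n, K, N, fold, p))
    if not rows:
        return pd.DataFrame(columns=ORA_COLUMNS)
    q = bh_adjust([r.p_value for r in rows])
    for r, qv in zip(rows, q):
        r.q_value = float(qv)
    df = pd.DataFrame(
        {
            "set_name": [r.set_name for r in rows],
            "k": [r.k for r in rows],
            "n": [r.n for r in rows],
            "K": [r.K for r in rows],
            "N": [r.N for r in rows],
            "fold_enrichment": [r.fold_enrichment for r in rows],
            "p_value": [r.p_value for r in rows],
            "q_value": [r.q_value for r in rows],
        }
    )
    df["significant"] = df["q_value"] < fdr_threshold
    df = df.sort_values(
        ["q_value", "fold_enrichment", "set_name"],
        ascending=[True, False, True], kind="mergesort",
    ).reset_index(drop=True)
    return df


def plot_fold_enrichment(records: pd.DataFrame, path, top: int = 10) -> None:
    """Horizontal bar chart of the top gene sets by fold enrichment
    (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shown = records.head(top).iloc[::-1]
    fig, ax = plt.subplots(figsize=(6, max(2, 0.4 * len(shown))))
    ax.barh(shown["set_name"], shown["fold_enrichment"], color="#4477aa")
    ax.set_xlabel("fold enrichment")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
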