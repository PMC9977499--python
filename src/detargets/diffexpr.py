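"""Normalization, per-gene two-sample testing and FDR-controlled
differential-expression calls.

The model is the classical microarray workflow: intensities are quantile
normalized so every array shares one empirical distribution, linear
intensities are log2-transformed, each gene is tested with a pooled-variance
(Student) two-sample t-test between the two groups, p-values are adjusted
with the Benjamini-Hochberg step-up procedure, and genes are called
differentially expressed at adjusted p (q) strictly below the FDR threshold.
Direction is ``up`` when the group-A mean exceeds the group-B mean.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .formats import ExpressionTable, ValidationError

logger = logging.getLogger("detargets")

DE_COLUMNS = ["mean_A", "mean_B", "diff", "t_stat", "df", "p_value",
              "q_value", "direction", "is_de"]


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def quantile_normalize(table: ExpressionTable) -> ExpressionTable:
    """Force every sample (column) onto the same empirical distribution.

    Rank ``r`` in each column is replaced by the mean of the r-th order
    statistics across columns; values tied within a column receive the
    average of the reference values of their tied ranks.  Idempotent.
    """
    X = table.values.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValidationError("quantile normalization requires finite values")
    n, m = X.shape
    if m == 0 or n == 0:
        return table.with_values(table.values.copy())
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(m):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        sc = col[order]
        # average the reference over runs of tied values
        starts = np.r_[0, np.flatnonzero(np.diff(sc) != 0) + 1]
        sums = np.add.reduceat(ref, starts)
        lengths = np.diff(np.r_[starts, n])
        run_means = sums / lengths
        assigned = np.repeat(run_means, lengths)
        out[order, j] = assigned
    values = pd.DataFrame(out, index=table.values.index,
                          columns=table.values.columns)
    return table.with_values(values)


def log2_transform(table: ExpressionTable) -> ExpressionTable:
    """Elementwise log2 of strictly positive linear intensities."""
    if table.scale != "linear":
        raise ValidationError("log2_transform expects a linear-scale table")
    X = table.values.to_numpy(dtype=float)
    bad = X <= 0
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"non-positive value at feature {table.feature_ids[i]!r}, "
            f"sample {table.sample_ids[j]!r}"
        )
    values = pd.DataFrame(np.log2(X), index=table.values.index,
                          columns=table.values.columns)
    return table.with_values(values, scale="log2")


# ---------------------------------------------------------------------------
# Per-gene tests
# ---------------------------------------------------------------------------

def _t_test_matrix(Xa: np.ndarray, Xb: np.ndarray, welch: bool = False):
    """Row-wise two-sample t-test.  Returns (t, df, p) arrays.

    Degenerate rows with zero variance in both groups get the sentinel
    t = 0 (p = 1) when the means agree and t = +/-inf (p = 0) otherwise,
    so gene counts are conserved instead of rows being dropped.
    """
    na, nb = Xa.shape[1], Xb.shape[1]
    if na < 2 or nb < 2:
        raise ValidationError("each group needs at least 2 observations")
    ma = Xa.mean(axis=1)
    mb = Xb.mean(axis=1)
    ssa = ((Xa - ma[:, None]) ** 2).sum(axis=1)
    ssb = ((Xb - mb[:, None]) ** 2).sum(axis=1)
    if welch:
        va = ssa / (na - 1)
        vb = ssb / (nb - 1)
        sem2 = va / na + vb / nb
        with np.errstate(divide="ignore", invalid="ignore"):
            df = sem2 ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
        df = np.where(np.isfinite(df), df, float(na + nb - 2))
        se = np.sqrt(sem2)
    else:
        df = np.full(len(ma), float(na + nb - 2))
        pooled = (ssa + ssb) / (na + nb - 2)
        se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    zero = se == 0
    safe_se = np.where(zero, 1.0, se)
    t = (ma - mb) / safe_se
    t[zero & (ma > mb)] = np.inf
    t[zero & (ma < mb)] = -np.inf
    t[zero & (ma == mb)] = 0.0
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.minimum(p, 1.0)
    p[zero & (ma == mb)] = 1.0
    return t, df, p


def student_t_two_sample(a, b, welch: bool = False):
    """Two-sample t-test for one gene.

    Pooled-variance Student statistic by default (``df = |a|+|b|-2``),
    Welch's approximation behind the ``welch`` flag.  Two-tailed p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise ValidationError("inputs must be 1-D numeric vectors")
    t, df, p = _t_test_matrix(a[None, :], b[None, :], welch=welch)
    return float(t[0]), float(df[0]), float(p[0])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} m * p_(j) / j`` on the ascending order, capped
    at 1, returned in input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p-values must be a 1-D vector")
    if p.size == 0:
        return p.copy()
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# The DE table
# ---------------------------------------------------------------------------

def de_statistics(table: ExpressionTable, group_a: str | None = None,
                  welch: bool = False) -> pd.DataFrame:
    """Per-feature means, difference, t, p and BH q between the two groups.

    ``group_a`` defaults to the first group in sample order; ``diff`` is
    ``mean_A - mean_B`` and ``direction`` is ``up`` iff ``diff > 0``.
    """
    labels = table.group_labels()
    if len(labels) != 2:
        raise ValidationError(
            f"exactly two sample groups required, found {labels}"
        )
    if group_a is None:
        group_a = labels[0]
    if group_a not in labels:
        raise ValidationError(f"unknown group {group_a!r}; groups are {labels}")
    group_b = labels[1] if group_a == labels[0] else labels[0]
    Xa = table.values[table.samples_of(group_a)].to_numpy(dtype=float)
    Xb = table.values[table.samples_of(group_b)].to_numpy(dtype=float)
    t, df, p = _t_test_matrix(Xa, Xb, welch=welch)
    q = bh_adjust(p)
    diff = Xa.mean(axis=1) - Xb.mean(axis=1)
    det = pd.DataFrame(
        {
            "mean_A": Xa.mean(axis=1),
            "mean_B": Xb.mean(axis=1),
            "diff": diff,
            "t_stat": t,
            "df": df,
            "p_value": p,
            "q_value": q,
            "direction": np.where(diff > 0, "up", "down"),
            "is_de": False,
        },
        index=pd.Index(table.feature_ids, name="feature_id"),
    )
    det.attrs["group_a"] = group_a
    det.attrs["group_b"] = group_b
    return det


def call_de(det: pd.DataFrame, fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Set ``is_de`` by strict ``q < fdr_threshold``."""
    if not 0 < fdr_threshold < 1:
        raise ValidationError("fdr_threshold must lie in (0, 1)")
    out = det.copy()
    out["is_de"] = out["q_value"] < fdr_threshold
    out.attrs.update(det.attrs)
    out.attrs["fdr_threshold"] = fdr_threshold
    return out


def _unambiguous(det: pd.DataFrame) -> pd.Series:
    if "ambiguous" in det.columns:
        return ~det["ambiguous"]
    return pd.Series(True, index=det.index)


def up_genes(det: pd.DataFrame) -> set[str]:
    """IDs called DE with direction up (ambiguous genes excluded)."""
    mask = det["is_de"] & (det["direction"] == "up") & _unambiguous(det)
    return set(det.index[mask])


def down_genes(det: pd.DataFrame) -> set[str]:
    """IDs called DE with direction down (ambiguous genes excluded)."""
    mask = det["is_de"] & (det["direction"] == "down") & _unambiguous(det)
    return set(det.index[mask])


def collapse_probes_to_genes(det: pd.DataFrame, probe_map: pd.DataFrame,
                             fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Summarise a probe-level DE table to gene level.

    Each gene inherits the statistics of its representative probe — the
    one with the smallest q (ties broken by smallest p, then lexicographic
    probe ID).  Genes whose *significant* probes (q < threshold) disagree
    in sign are flagged ``ambiguous`` and excluded from the up/down sets.
    Probes absent from the map are dropped with a logged count.  BH must
    already have been applied at probe level.
    """
    if probe_map is None or len(probe_map) == 0:
        raise ValidationError("probe-to-gene map is empty")
    pm = probe_map[["probe_id", "gene_id"]].astype(str)
    mapped = pm[pm["probe_id"].isin(det.index)]
    n_unmapped = det.index.difference(pm["probe_id"]).size
    if n_unmapped:
        logger.info("collapse_probes_to_genes: dropped %d unmapped probes",
                    n_unmapped)
    if not len(mapped):
        raise ValidationError("no probe in the DE table appears in the map")
    probe_stats = det.loc[mapped["probe_id"]].reset_index()
    probe_stats = probe_stats.rename(columns={"feature_id": "probe_id"})
    probe_stats["gene_id"] = mapped["gene_id"].to_numpy()
    probe_stats = probe_stats.sort_values(
        ["gene_id", "q_value", "p_value", "probe_id"], kind="mergesort"
    )
    rep = probe_stats.groupby("gene_id", sort=True).first()

    sig = probe_stats[probe_stats["q_value"] < fdr_threshold]
    sign_counts = sig.groupby("gene_id")["diff"].agg(
        lambda s: (s > 0).any() and (s <= 0).any()
    )
    ambiguous = set(sign_counts.index[sign_counts])
    if ambiguous:
        logger.info("collapse_probes_to_genes: %d genes with sign-conflicting "
                    "significant probes marked ambiguous: %s",
                    len(ambiguous), sorted(ambiguous))

    n_probes = probe_stats.groupby("gene_id").size()
    gene = rep[["mean_A", "mean_B", "diff", "t_stat", "df", "p_value",
                "q_value", "direction", "is_de", "probe_id"]].copy()
    gene["n_probes"] = n_probes
    gene["ambiguous"] = gene.index.isin(ambiguous)
    gene.index.name = "feature_id"
    gene.attrs.update(det.attrs)
    gene.attrs["n_unmapped_probes"] = int(n_unmapped)
    return gene


def differential_expression(table: ExpressionTable,
                            fdr_threshold: float = 0.05,
                            normalize: bool = True,
                            welch: bool = False,
                            probe_map: pd.DataFrame | None = None,
                            group_a: str | None = None) -> pd.DataFrame:
    """Full DE stage: (quantile normalize) -> (log2 if linear) -> t-test
    -> BH -> DE calls -> (probe collapsing)."""
    if normalize:
        table = quantile_normalize(table)
    if table.scale == "linear":
        table = log2_transform(table)
    det = de_statistics(table, group_a=group_a, welch=welch)
    det = call_de(det, fdr_threshold)
    if probe_map is not None:
        det = collapse_probes_to_genes(det, probe_map, fdr_threshold)
        det = call_de(det, fdr_threshold)
    return det
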