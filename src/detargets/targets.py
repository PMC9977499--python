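"""Transcription-factor target-gene identification from ChIP-Seq peaks.

A gene is *bound* by a subunit when at least one of that subunit's peaks
overlaps the gene body or lies within ``window_bp`` (default 1000 bp,
boundary inclusive) of it — the "1 kb rule".  For each subunit and each
direction of differential expression, a 2x2 table (DE x bound over the
background universe) is tested with Fisher's exact test; *target genes*
are the genes that are both differentially expressed and bound, and the
target fraction is their percentage among the directional DE genes.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .formats import IntervalTable, ValidationError

logger = logging.getLogger("detargets")

#: canonical (p65, p50) and noncanonical (RelB, p52) NF-kB subunits
SUBUNITS = ("p65", "p50", "RelB", "p52")

TARGET_COLUMNS = ["subunit", "direction", "a", "b", "c", "d", "odds_ratio",
                  "p_value", "n_targets", "fraction_pct", "target_genes"]


# ---------------------------------------------------------------------------
# Peak-to-gene assignment
# ---------------------------------------------------------------------------

def _anchor_intervals(genes: IntervalTable, anchor: str):
    df = genes.df
    if anchor == "gene":
        return df["chrom"].to_numpy(), df["start"].to_numpy(), df["end"].to_numpy()
    if anchor == "tss":
        # TSS = 5' end: interval start on +/. strands, end-1 on -
        tss = np.where(df["strand"].to_numpy() == "-",
                       df["end"].to_numpy() - 1, df["start"].to_numpy())
        return df["chrom"].to_numpy(), tss, tss + 1
    raise ValidationError(f"unknown anchor {anchor!r}; use 'gene' or 'tss'")


def assign_binding(genes: IntervalTable, peaks: IntervalTable,
                   window_bp: int = 1000, anchor: str = "gene") -> set[str]:
    """Names of genes with a peak overlapping or within ``window_bp``.

    The gap between a gene [gs, ge) and a peak [ps, pe) is
    ``max(gs - pe, ps - ge)`` (negative on overlap); the gene is bound iff
    the gap is <= ``window_bp``, boundary inclusive.  Strand is ignored
    for the default gene-body anchor.  Implemented as a sorted sweep per
    chromosome, equivalent to the quadratic all-pairs check.
    """
    if window_bp < 0:
        raise ValidationError("window_bp must be >= 0")
    bound: set[str] = set()
    if not len(genes) or not len(peaks):
        return bound
    g_chrom, g_start, g_end = _anchor_intervals(genes, anchor)
    g_name = genes.df["name"].to_numpy()
    pdf = peaks.df
    for chrom, part in pdf.groupby("chrom", sort=False):
        sel = g_chrom == chrom
        if not sel.any():
            continue
        order = np.argsort(part["start"].to_numpy(), kind="mergesort")
        p_start = part["start"].to_numpy()[order]
        p_end_runmax = np.maximum.accumulate(part["end"].to_numpy()[order])
        # peaks with start <= gene_end + window among which some end must
        # reach back to gene_start - window
        idx = np.searchsorted(p_start, g_end[sel] + window_bp, side="right")
        ok = idx > 0
        reach = np.zeros(sel.sum(), dtype=bool)
        reach[ok] = p_end_runmax[idx[ok] - 1] >= g_start[sel][ok] - window_bp
        bound.update(g_name[sel][reach])
    return bound


def binding_matrix(genes: IntervalTable,
                   peaks_by_subunit: Mapping[str, IntervalTable],
                   window_bp: int = 1000, anchor: str = "gene") -> pd.DataFrame:
    """Boolean gene x subunit table; every gene of the model appears once."""
    mat = pd.DataFrame(index=pd.Index(genes.names, name="gene_id"))
    for subunit, peaks in peaks_by_subunit.items():
        bound = assign_binding(genes, peaks, window_bp=window_bp, anchor=anchor)
        mat[subunit] = mat.index.isin(bound)
    mat.attrs["window_bp"] = window_bp
    mat.attrs["anchor"] = anchor
    return mat


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def fisher_exact_2x2(a: int, b: int, c: int, d: int):
    """Two-sided Fisher's exact test for the table [[a, b], [c, d]].

    Returns ``(odds_ratio, p_value)``.  The odds ratio is the
    unconditional sample estimate ``(a*d)/(b*c)`` with sentinels ``inf``
    (``b*c == 0 < a*d``), ``0`` (``a*d == 0 < b*c``) and ``1`` (both
    products zero).  The p-value sums the conditional hypergeometric pmf
    over all tables with the observed margins whose pmf does not exceed
    the observed pmf by more than a 1e-7 relative tie tolerance; the pmf
    is evaluated in log space.
    """
    cells = (a, b, c, d)
    for v in cells:
        if int(v) != v or v < 0:
            raise ValidationError("table cells must be non-negative integers")
    a, b, c, d = (int(v) for v in cells)
    N = a + b + c + d
    if N == 0:
        raise ValidationError("at least one table margin must be positive")
    ad, bc = a * d, b * c
    if bc == 0:
        odds_ratio = math.inf if ad > 0 else 1.0
    elif ad == 0:
        odds_ratio = 0.0
    else:
        odds_ratio = ad / bc
    r1, c1, r2 = a + b, a + c, c + d
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    x = np.arange(lo, hi + 1)
    logpmf = (
        gammaln(r1 + 1) - gammaln(x + 1) - gammaln(r1 - x + 1)
        + gammaln(r2 + 1) - gammaln(c1 - x + 1) - gammaln(r2 - c1 + x + 1)
        + gammaln(c1 + 1) + gammaln(N - c1 + 1) - gammaln(N + 1)
    )
    log_obs = logpmf[a - lo]
    mask = logpmf <= log_obs + math.log1p(1e-7)
    p = float(min(1.0, np.exp(logsumexp(logpmf[mask]))))
    return odds_ratio, p


def conditional_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Conditional maximum-likelihood odds ratio (noncentral
    hypergeometric), as reported by some exact-test implementations."""
    from scipy.stats.contingency import odds_ratio as _or

    return float(_or([[a, b], [c, d]], kind="conditional").statistic)


# ---------------------------------------------------------------------------
# Target definition and enrichment
# ---------------------------------------------------------------------------

def define_targets(de_genes: Iterable[str], bound: Iterable[str]) -> set[str]:
    """Target genes = differentially expressed AND bound (set intersection)."""
    return set(de_genes) & set(bound)


def target_fraction(n_targets: int, n_de_direction: int) -> int:
    """Percentage of directional DE genes that are targets, rounded
    half-up to the nearest integer percent."""
    if n_de_direction <= 0:
        raise ValidationError("n_de_direction must be positive")
    if not 0 <= n_targets <= n_de_direction:
        raise ValidationError("need 0 <= n_targets <= n_de_direction")
    return int(math.floor(100.0 * n_targets / n_de_direction + 0.5))


@dataclass
class TargetEnrichmentRecord:
    """One subunit x direction binding-enrichment result."""

    subunit: str
    direction: str
    a: int  # DE & bound
    b: int  # DE & unbound
    c: int  # non-DE & bound
    d: int  # non-DE & unbound
    odds_ratio: float
    p_value: float
    target_genes: list[str] = field(default_factory=list)
    fraction_pct: int = 0

    @property
    def table2x2(self):
        return ((self.a, self.b), (self.c, self.d))


def subunit_enrichment(de_set, bound, background, subunit: str,
                       direction: str) -> TargetEnrichmentRecord:
    """Build the DE x bound 2x2 table over the background and test it.

    DE genes outside the background are dropped with a logged count; the
    bound set is intersected with the background.  ``target_genes`` is the
    sorted a-cell and ``fraction_pct`` their rounded percentage of the
    directional DE genes.
    """
    background = set(background)
    if not background:
        raise ValidationError("background gene universe is empty")
    de0 = set(de_set)
    de = de0 & background
    if len(de) < len(de0):
        logger.info("subunit_enrichment[%s/%s]: dropped %d DE genes outside "
                    "the background", subunit, direction, len(de0) - len(de))
    bound_bg = set(bound) & background
    targets = define_targets(de, bound_bg)
    a = len(targets)
    b = len(de) - a
    c = len(bound_bg - de)
    d = len(background) - a - b - c
    odds_ratio, p = fisher_exact_2x2(a, b, c, d)
    if not bound_bg:
        odds_ratio = 0.0  # no binding at all: report depletion sentinel
    fraction = target_fraction(a, a + b) if (a + b) else 0
    return TargetEnrichmentRecord(
        subunit=subunit, direction=direction, a=a, b=b, c=c, d=d,
        odds_ratio=odds_ratio, p_value=p,
        target_genes=sorted(targets), fraction_pct=fraction,
    )


def analyze_targets(genes: IntervalTable,
                    peaks_by_subunit: Mapping[str, IntervalTable],
                    de_up, de_down, universe,
                    window_bp: int = 1000,
                    anchor: str = "gene") -> list[TargetEnrichmentRecord]:
    """Run the full subunit x direction analysis.

    The background is the intersection of the DE-table gene universe with
    the genes that have coordinates in the gene-model table; genes without
    coordinates are excluded with a logged count.
    """
    universe = set(universe)
    with_coords = set(genes.names)
    background = universe & with_coords
    excluded = len(universe) - len(background)
    if excluded:
        logger.info("analyze_targets: excluded %d universe genes without "
                    "coordinates from the background", excluded)
    records: list[TargetEnrichmentRecord] = []
    for subunit, peaks in peaks_by_subunit.items():
        bound = assign_binding(genes, peaks, window_bp=window_bp, anchor=anchor)
        for direction, de_set in (("up", de_up), ("down", de_down)):
            records.append(
                subunit_enrichment(de_set, bound, background, subunit, direction)
            )
    return records


def records_to_frame(records: list[TargetEnrichmentRecord]) -> pd.DataFrame:
    """Flatten enrichment records to a result table (target genes joined
    with ``;``)."""
    return pd.DataFrame(
        {
            "subunit": [r.subunit for r in records],
            "direction": [r.direction for r in records],
            "a": [r.a for r in records],
            "b": [r.b for r in records],
            "c": [r.c for r in records],
            "d": [r.d for r in records],
            "odds_ratio": [r.odds_ratio for r in records],
            "p_value": [r.p_value for r in records],
            "n_targets": [len(r.target_genes) for r in records],
            "fraction_pct": [r.fraction_pct for r in records],
            "target_genes": [";".join(r.target_genes) for r in records],
        },
        columns=TARGET_COLUMNS,
    )
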