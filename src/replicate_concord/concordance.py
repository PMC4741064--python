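"""Pairwise and per-filter concordance statistics for paired call sets.

For one tumor with technical replicates WGS and WGA (key sets A and B):

* overlap ``o = |A ∩ B|``, the individual mutations called in both runs;
* percent overlap per replicate, ``100·o/|A|`` and ``100·o/|B|``;
* Jaccard similarity ``J = o / |A ∪ B| = o / (|A| + |B| − o)``;
* per-filter effects: how much of the overlap vs the symmetric difference a
  filter removes, and how the Jaccard changes when the filter is applied to
  both replicates.

A key counts as removed *from the overlap* if it is removed in either
replicate — it is then no longer present in both kept sets, which makes the
reported post-filter Jaccard identical to recomputing the overlap on the kept
sets. Undefined ratios (0/0, x/0) are explicit ``None`` markers, never
sentinel numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import DataError, ReplicatePair, SnvKey, snv_key_set
from .filters import FilterResult

__all__ = [
    "OverlapSummary",
    "FilterEffect",
    "CorrelationResult",
    "pair_overlap",
    "filter_effect",
    "spearman",
    "complementarity",
    "union_pct_overlap_removed",
    "cohort_summary",
]


@dataclass
class OverlapSummary:
    """Intersection / percent-overlap / Jaccard statistics for one pair."""

    sample_id: str
    n_wgs: int
    n_wga: int
    n_overlap: int
    pct_overlap_wgs: Optional[float]  # 100·|A∩B|/|A|; None when |A| = 0
    pct_overlap_wga: Optional[float]  # 100·|A∩B|/|B|; None when |B| = 0
    jaccard: Optional[float]  # |A∩B|/|A∪B|; None when both sets empty


@dataclass
class FilterEffect:
    """Effect of one filter, applied independently to both replicates."""

    sample_id: str
    filter_name: str
    n_removed_wgs: int
    n_removed_wga: int
    n_removed_overlap: int
    n_removed_difference: int
    pct_overlap_removed: Optional[float]
    diff_over_overlap_ratio: Optional[float]
    jaccard_before: Optional[float]
    jaccard_after: Optional[float]
    pct_jaccard_change: Optional[float]


@dataclass
class CorrelationResult:
    """Spearman rank correlation with the classical S = Σd² statistic."""

    rho: Optional[float]
    s_stat: float
    n: int
    p_value: Optional[float]


def _jaccard(a: set[SnvKey], b: set[SnvKey]) -> Optional[float]:
    union = len(a | b)
    if union == 0:
        return None
    return len(a & b) / union


def pair_overlap(pair: ReplicatePair) -> OverlapSummary:
    """Compute overlap, percent overlap per replicate and Jaccard for a pair.

    A replicate with zero calls yields ``None`` for its percent overlap; two
    empty replicates additionally yield ``None`` for the Jaccard.
    """
    wgs = snv_key_set(pair.wgs_calls)
    wga = snv_key_set(pair.wga_calls)
    n_overlap = len(wgs & wga)
    return OverlapSummary(
        sample_id=pair.sample_id,
        n_wgs=len(wgs),
        n_wga=len(wga),
        n_overlap=n_overlap,
        pct_overlap_wgs=100.0 * n_overlap / len(wgs) if wgs else None,
        pct_overlap_wga=100.0 * n_overlap / len(wga) if wga else None,
        jaccard=_jaccard(wgs, wga),
    )


def filter_effect(
    pair: ReplicatePair,
    wgs_result: FilterResult,
    wga_result: FilterResult,
) -> FilterEffect:
    """Quantify one filter's action on the overlap and difference of a pair.

    ``wgs_result`` and ``wga_result`` must come from the same named filter
    applied independently to the pair's two replicates.
    """
    if wgs_result.filter_name != wga_result.filter_name:
        raise DataError(
            f"filter results disagree on name: {wgs_result.filter_name!r} vs "
            f"{wga_result.filter_name!r}"
        )
    wgs = snv_key_set(pair.wgs_calls)
    wga = snv_key_set(pair.wga_calls)
    overlap = wgs & wga
    removed_any = wgs_result.removed | wga_result.removed
    n_removed_overlap = len(overlap & removed_any)
    n_removed_difference = len((wgs - wga) & wgs_result.removed) + len(
        (wga - wgs) & wga_result.removed
    )
    jaccard_before = _jaccard(wgs, wga)
    jaccard_after = _jaccard(wgs_result.kept, wga_result.kept)

    pct_overlap_removed = (
        100.0 * n_removed_overlap / len(overlap) if overlap else None
    )
    ratio = (
        n_removed_difference / n_removed_overlap if n_removed_overlap else None
    )
    if jaccard_before is None or jaccard_before == 0 or jaccard_after is None:
        pct_jaccard_change = None
    else:
        pct_jaccard_change = 100.0 * (jaccard_after - jaccard_before) / jaccard_before
    return FilterEffect(
        sample_id=pair.sample_id,
        filter_name=wgs_result.filter_name,
        n_removed_wgs=len(wgs_result.removed),
        n_removed_wga=len(wga_result.removed),
        n_removed_overlap=n_removed_overlap,
        n_removed_difference=n_removed_difference,
        pct_overlap_removed=pct_overlap_removed,
        diff_over_overlap_ratio=ratio,
        jaccard_before=jaccard_before,
        jaccard_after=jaccard_after,
        pct_jaccard_change=pct_jaccard_change,
    )


def spearman(xs: Sequence[float], ys: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with average-rank ties.

    Returns rho (Pearson correlation of the rank vectors), the classical
    ``S = Σ(rank xᵢ − rank yᵢ)²`` statistic, and a two-sided p-value from the
    large-sample t approximation. A constant input vector makes rho (and the
    p-value) undefined, reported as ``None``.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.ndim != 1:
        raise DataError(
            f"spearman requires two equal-length vectors, got shapes "
            f"{xs.shape} and {ys.shape}"
        )
    n = xs.size
    if n < 3:
        raise DataError(f"spearman requires n >= 3, got n = {n}")
    rank_x = stats.rankdata(xs)
    rank_y = stats.rankdata(ys)
    s_stat = float(np.sum((rank_x - rank_y) ** 2))
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        return CorrelationResult(rho=None, s_stat=s_stat, n=n, p_value=None)
    rho, p_value = stats.spearmanr(xs, ys)
    if math.isnan(rho):  # defensive; scipy returns nan only for degenerate input
        return CorrelationResult(rho=None, s_stat=s_stat, n=n, p_value=None)
    return CorrelationResult(rho=float(rho), s_stat=s_stat, n=n, p_value=float(p_value))


def complementarity(loh: FilterEffect, vaq: FilterEffect) -> Optional[float]:
    """Sum of the percent-of-overlap removed by the LOH and VAQ filters.

    Note this raw sum counts a key removed by *both* filters twice; see
    :func:`union_pct_overlap_removed` for the union-based coverage that does
    not. Undefined inputs propagate as ``None``.
    """
    if loh.sample_id != vaq.sample_id:
        raise DataError(
            f"complementarity requires effects from one sample, got "
            f"{loh.sample_id!r} and {vaq.sample_id!r}"
        )
    if loh.pct_overlap_removed is None or vaq.pct_overlap_removed is None:
        return None
    return loh.pct_overlap_removed + vaq.pct_overlap_removed


def union_pct_overlap_removed(
    pair: ReplicatePair,
    results: Iterable[FilterResult],
) -> Optional[float]:
    """Percent of the pair's overlap removed by the union of filter results.

    ``results`` may mix results from both replicates and several filters; a
    key leaves the overlap when any of them removed it.
    """
    wgs = snv_key_set(pair.wgs_calls)
    wga = snv_key_set(pair.wga_calls)
    overlap = wgs & wga
    if not overlap:
        return None
    removed: set[SnvKey] = set()
    for result in results:
        removed |= result.removed
    return 100.0 * len(overlap & removed) / len(overlap)


def _describe(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-column mean/stdev/min/max with NA-aware population stdev."""
    rows = []
    for column in frame.columns:
        values = frame[column].astype(float)
        rows.append(
            {
                "metric": column,
                "mean": values.mean(),
                "stdev": float(np.sqrt(values.var(ddof=0))) if values.notna().any() else np.nan,
                "min": values.min(),
                "max": values.max(),
            }
        )
    return pd.DataFrame(rows, columns=["metric", "mean", "stdev", "min", "max"])


def cohort_summary(
    overlaps: Sequence[OverlapSummary],
    effects: Sequence[FilterEffect] = (),
    genome_size_mbp: float = 30.0,
) -> pd.DataFrame:
    """Cohort-level summary table: mean, stdev, min, max per statistic.

    Covers per-pair call counts, overlap size, percent overlaps, the
    per-replicate mutation frequency (calls per Mbp of interrogated genome,
    denominator ``genome_size_mbp``), and — when filter effects are given —
    per-filter removal counts and percent-of-overlap removed.
    """
    if not overlaps:
        raise DataError("no pairs analyzed")
    if genome_size_mbp <= 0:
        raise DataError("genome_size_mbp must be positive")
    base = pd.DataFrame(
        {
            "n_wgs": [o.n_wgs for o in overlaps],
            "n_wga": [o.n_wga for o in overlaps],
            "n_overlap": [o.n_overlap for o in overlaps],
            "pct_overlap_wgs": [o.pct_overlap_wgs for o in overlaps],
            "pct_overlap_wga": [o.pct_overlap_wga for o in overlaps],
            "jaccard": [o.jaccard for o in overlaps],
        },
        index=[o.sample_id for o in overlaps],
    )
    base["mut_per_mbp_wgs"] = base["n_wgs"] / genome_size_mbp
    base["mut_per_mbp_wga"] = base["n_wga"] / genome_size_mbp

    per_filter = pd.DataFrame(index=base.index)
    for effect in effects:
        per_filter.loc[effect.sample_id, f"n_removed_wgs:{effect.filter_name}"] = (
            effect.n_removed_wgs
        )
        per_filter.loc[effect.sample_id, f"n_removed_wga:{effect.filter_name}"] = (
            effect.n_removed_wga
        )
        per_filter.loc[effect.sample_id, f"pct_overlap_removed:{effect.filter_name}"] = (
            np.nan if effect.pct_overlap_removed is None else effect.pct_overlap_removed
        )
    combined = pd.concat([base, per_filter], axis=1)
    return _describe(combined)
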