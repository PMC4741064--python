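"""Cohort-level orchestration: load pairs, run filters, assemble tables.

This is the computational core behind the ``concord`` and
``evaluate-filters`` commands and the analysis scripts; everything here is
plain library code so tests and scripts can drive it directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .concordance import (
    CorrelationResult,
    FilterEffect,
    OverlapSummary,
    cohort_summary,
    complementarity,
    filter_effect,
    pair_overlap,
    spearman,
    union_pct_overlap_removed,
)
from .filters import FilterResult, apply_filters
from .model import (
    ConfigError,
    DataError,
    FilterConfig,
    IndelRecord,
    Replicate,
    ReplicatePair,
    SiteKey,
)
from .vcf_io import VcfDialect, read_metadata, read_somatic_vcf

__all__ = [
    "COMBINED_FILTER_NAME",
    "LoadedPair",
    "CohortResults",
    "load_pairs",
    "evaluate_cohort",
]

logger = logging.getLogger(__name__)

#: Name given to the union-of-all-enabled-filters pseudo-filter.
COMBINED_FILTER_NAME = "ALL"


@dataclass
class LoadedPair:
    """A replicate pair plus the indel spans parsed from each of its VCFs."""

    pair: ReplicatePair
    wgs_indels: list[IndelRecord] = field(default_factory=list)
    wga_indels: list[IndelRecord] = field(default_factory=list)


@dataclass
class CohortResults:
    """Everything one cohort run produces, as tidy tables plus raw objects."""

    overlaps: list[OverlapSummary]
    effects: list[FilterEffect]
    pair_table: pd.DataFrame
    effect_table: Optional[pd.DataFrame]
    summary_table: pd.DataFrame
    correlations: Optional[pd.DataFrame]


def load_pairs(
    manifest_path: str | Path,
    dialect: Optional[VcfDialect] = None,
    metadata_path: Optional[str | Path] = None,
    continue_on_error: bool = False,
) -> list[LoadedPair]:
    """Read a pairs manifest (TSV: sample_id, wgs_vcf, wga_vcf) into memory.

    VCF paths are resolved relative to the manifest's directory unless
    absolute. With ``continue_on_error``, unreadable pairs are logged and
    skipped instead of aborting the cohort.
    """
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path, sep="\t")
    missing = {"sample_id", "wgs_vcf", "wga_vcf"} - set(table.columns)
    if missing:
        raise DataError(f"{manifest_path}: manifest missing column(s) {sorted(missing)}")
    metadata = read_metadata(metadata_path) if metadata_path else None
    base = manifest_path.parent
    loaded: list[LoadedPair] = []
    for row in table.itertuples(index=False):
        sample_id = str(row.sample_id)
        try:
            wgs_calls, wgs_indels = read_somatic_vcf(
                base / str(row.wgs_vcf), dialect, sample_id, Replicate.WGS
            )
            wga_calls, wga_indels = read_somatic_vcf(
                base / str(row.wga_vcf), dialect, sample_id, Replicate.WGA
            )
        except DataError as exc:
            if continue_on_error:
                logger.error("skipping pair %s: %s", sample_id, exc)
                continue
            raise DataError(f"pair {sample_id}: {exc}") from exc
        pair_metadata = None
        if metadata is not None:
            rows = metadata[metadata["sample_id"].astype(str) == sample_id]
            pair_metadata = {
                Replicate(rec.replicate): {
                    key: getattr(rec, key)
                    for key in ("coverage", "pct_mapped")
                    if hasattr(rec, key)
                }
                for rec in rows.itertuples(index=False)
            }
        loaded.append(
            LoadedPair(
                ReplicatePair(sample_id, wgs_calls, wga_calls, metadata=pair_metadata),
                wgs_indels,
                wga_indels,
            )
        )
    if not loaded:
        raise DataError("no pairs analyzed")
    return loaded


def _correlation_row(name: str, result: CorrelationResult) -> dict:
    return {
        "comparison": name,
        "rho": np.nan if result.rho is None else result.rho,
        "s_stat": result.s_stat,
        "n": result.n,
        "p_value": np.nan if result.p_value is None else result.p_value,
    }


def _cohort_correlations(pairs: Sequence[ReplicatePair], overlaps: Sequence[OverlapSummary]):
    rows = []
    if len(overlaps) >= 3:
        rows.append(
            _correlation_row(
                "n_wgs_vs_n_wga",
                spearman([o.n_wgs for o in overlaps], [o.n_wga for o in overlaps]),
            )
        )
        with_pct = [o for o in overlaps if o.pct_overlap_wga is not None]
        if len(with_pct) >= 3:
            rows.append(
                _correlation_row(
                    "n_wga_vs_pct_overlap_wga",
                    spearman(
                        [o.n_wga for o in with_pct],
                        [o.pct_overlap_wga for o in with_pct],
                    ),
                )
            )
    # covariate correlations pool both replicates, as in per-sample QC plots
    n_calls: dict[str, list[float]] = {"coverage": [], "pct_mapped": []}
    covariate: dict[str, list[float]] = {"coverage": [], "pct_mapped": []}
    for pair, overlap in zip(pairs, overlaps):
        if not pair.metadata:
            continue
        for replicate, count in (
            (Replicate.WGS, overlap.n_wgs),
            (Replicate.WGA, overlap.n_wga),
        ):
            scalars = pair.metadata.get(replicate) or {}
            for key in ("coverage", "pct_mapped"):
                value = scalars.get(key)
                if value is not None and not pd.isna(value):
                    n_calls[key].append(count)
                    covariate[key].append(float(value))
    for key in ("coverage", "pct_mapped"):
        if len(n_calls[key]) >= 3:
            rows.append(
                _correlation_row(f"n_calls_vs_{key}", spearman(n_calls[key], covariate[key]))
            )
    if not rows:
        return None
    return pd.DataFrame(rows, columns=["comparison", "rho", "s_stat", "n", "p_value"])


def _effect_frame(effects: Sequence[FilterEffect]) -> Optional[pd.DataFrame]:
    if not effects:
        return None
    frame = pd.DataFrame(
        {
            "sample_id": [e.sample_id for e in effects],
            "filter": [e.filter_name for e in effects],
            "n_removed_wgs": [e.n_removed_wgs for e in effects],
            "n_removed_wga": [e.n_removed_wga for e in effects],
            "n_removed_overlap": [e.n_removed_overlap for e in effects],
            "n_removed_difference": [e.n_removed_difference for e in effects],
            "pct_overlap_removed": [e.pct_overlap_removed for e in effects],
            "diff_over_overlap_ratio": [e.diff_over_overlap_ratio for e in effects],
            "jaccard_before": [e.jaccard_before for e in effects],
            "jaccard_after": [e.jaccard_after for e in effects],
            "pct_jaccard_change": [e.pct_jaccard_change for e in effects],
        }
    )
    return frame


def evaluate_cohort(
    loaded: Sequence[LoadedPair],
    config: Optional[FilterConfig] = None,
    sites: Iterable[SiteKey] = (),
    shared_indels: Iterable[IndelRecord] = (),
    genome_size_mbp: float = 30.0,
    per_filter: bool = True,
) -> CohortResults:
    """Compute overlap statistics and (optionally) per-filter effects.

    Every enabled filter is run independently per replicate on the original
    call set; the ``ALL`` pseudo-filter is the union of their removals. A
    replicate's indel list for the proximity filter is the union of the
    indels parsed from its own VCF and any ``shared_indels``.
    """
    if not loaded:
        raise DataError("no pairs analyzed")
    config = config or FilterConfig()
    sites = list(sites)
    shared_indels = list(shared_indels)

    overlaps: list[OverlapSummary] = []
    effects: list[FilterEffect] = []
    pair_rows: list[dict] = []
    for item in loaded:
        pair = item.pair
        overlap = pair_overlap(pair)
        overlaps.append(overlap)
        row = {
            "sample_id": overlap.sample_id,
            "n_wgs": overlap.n_wgs,
            "n_wga": overlap.n_wga,
            "n_overlap": overlap.n_overlap,
            "pct_overlap_wgs": overlap.pct_overlap_wgs,
            "pct_overlap_wga": overlap.pct_overlap_wga,
            "jaccard": overlap.jaccard,
        }
        if per_filter:
            wgs_results, wgs_combined = apply_filters(
                pair.wgs_calls, config, sites, item.wgs_indels + shared_indels
            )
            wga_results, wga_combined = apply_filters(
                pair.wga_calls, config, sites, item.wga_indels + shared_indels
            )
            by_name: dict[str, FilterEffect] = {}
            for wgs_result, wga_result in zip(wgs_results, wga_results):
                effect = filter_effect(pair, wgs_result, wga_result)
                by_name[effect.filter_name] = effect
                effects.append(effect)
            # union of all enabled filters, the "run everything" analysis
            wgs_all = FilterResult(
                COMBINED_FILTER_NAME,
                wgs_combined,
                {c.key for c in pair.wgs_calls} - wgs_combined,
            )
            wga_all = FilterResult(
                COMBINED_FILTER_NAME,
                wga_combined,
                {c.key for c in pair.wga_calls} - wga_combined,
            )
            all_effect = filter_effect(pair, wgs_all, wga_all)
            effects.append(all_effect)
            row["n_overlap_after_all"] = overlap.n_overlap - all_effect.n_removed_overlap
            if "LOH" in by_name and "VAQ" in by_name:
                row["loh_vaq_pct_sum"] = complementarity(by_name["LOH"], by_name["VAQ"])
                row["loh_vaq_union_pct"] = union_pct_overlap_removed(
                    pair,
                    [
                        result
                        for result in wgs_results + wga_results
                        if result.filter_name in ("LOH", "VAQ")
                    ],
                )
        pair_rows.append(row)

    pair_table = pd.DataFrame(pair_rows)
    named_effects = [e for e in effects if e.filter_name != COMBINED_FILTER_NAME]
    summary = cohort_summary(overlaps, named_effects, genome_size_mbp=genome_size_mbp)
    correlations = _cohort_correlations([item.pair for item in loaded], overlaps)
    results = CohortResults(
        overlaps=overlaps,
        effects=effects,
        pair_table=pair_table,
        effect_table=_effect_frame(effects),
        summary_table=summary,
        correlations=correlations,
    )
    _log_summary(results)
    return results


def _log_summary(results: CohortResults) -> None:
    table = results.pair_table
    logger.info(
        "analyzed %d pairs: mean pct overlap WGS %.1f, WGA %.1f",
        len(table),
        table["pct_overlap_wgs"].mean(),
        table["pct_overlap_wga"].mean(),
    )
    if results.effect_table is not None:
        means = (
            results.effect_table.groupby("filter", sort=False)["pct_overlap_removed"]
            .mean()
            .dropna()
        )
        for name, value in means.items():
            logger.info("filter %s: mean %.1f%% of overlap removed", name, value)
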