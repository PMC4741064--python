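"""The eight somatic-SNV call filters, each a pure partition of a call set.

Every filter is evaluated *independently* on the full, unfiltered call
collection: the proximity filters judge neighborhood on the original set, not
on what some other filter kept. ``apply_filters`` therefore commutes over the
order of enabled filters, and the combined removal is simply the union of the
per-filter removals.

Boundary semantics, fixed once and used everywhere:

* threshold filters remove a call iff its score is strictly below the
  threshold (a score equal to 40 is kept);
* "within N bp" is inclusive (distance <= N removes);
* the alternate-allele-fraction filter removes iff the fraction is strictly
  below the cutoff (exactly 10% is kept).

Missing-field policy is lenient by default: a call whose required field is
missing is kept and counted in ``FilterResult.n_missing_field``; strict mode
raises instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

from .model import (
    FILTER_NAMES,
    WILDCARD_ALT,
    ConfigError,
    DataError,
    FilterConfig,
    IndelRecord,
    SiteKey,
    SnvCall,
    SnvKey,
)

__all__ = [
    "FilterResult",
    "threshold_filter",
    "loh_filter",
    "snv_proximity_filter",
    "indel_proximity_filter",
    "dbsnp_filter",
    "alt_fraction_filter",
    "apply_filters",
]


@dataclass
class FilterResult:
    """Partition (removed, kept) a named filter induces on one call set."""

    filter_name: str
    removed: set[SnvKey]
    kept: set[SnvKey]
    n_missing_field: int = 0

    def __post_init__(self) -> None:
        if self.removed & self.kept:
            raise DataError(
                f"filter {self.filter_name}: removed and kept sets overlap"
            )


def _partition(
    name: str,
    calls: Iterable[SnvCall],
    remove: Callable[[SnvCall], Optional[bool]],
) -> FilterResult:
    """Split calls by a predicate; predicate None means 'field missing'."""
    removed: set[SnvKey] = set()
    kept: set[SnvKey] = set()
    n_missing = 0
    for call in calls:
        verdict = remove(call)
        if verdict is None:
            n_missing += 1
            kept.add(call.key)
        elif verdict:
            removed.add(call.key)
        else:
            kept.add(call.key)
    return FilterResult(name, removed, kept, n_missing)


_FIELD_FILTER_NAMES = {"qual": "GATK", "ssc": "SS", "vaq": "VAQ"}


def threshold_filter(
    calls: Iterable[SnvCall],
    field: str,
    min_value: float,
    *,
    strict: bool = False,
) -> FilterResult:
    """Remove calls whose quality field is strictly below ``min_value``.

    ``field`` is one of ``qual`` (GATK-style calling quality), ``ssc``
    (SomaticScore) or ``vaq`` (Variant Allele Quality). Calls with the field
    missing are kept and counted, unless ``strict`` in which case they raise.
    """
    if field not in _FIELD_FILTER_NAMES:
        raise ConfigError(f"threshold field must be one of qual/ssc/vaq, got {field!r}")
    if min_value < 0:
        raise ConfigError(f"min_value must be >= 0, got {min_value}")

    def remove(call: SnvCall) -> Optional[bool]:
        value = getattr(call, field)
        if value is None:
            if strict:
                raise DataError(f"call {call.key} is missing required field {field!r}")
            return None
        return value < min_value

    return _partition(_FIELD_FILTER_NAMES[field], calls, remove)


def loh_filter(calls: Iterable[SnvCall]) -> FilterResult:
    """Remove calls the caller labeled loss-of-heterozygosity (LOH only)."""
    from .model import SomaticStatus

    def remove(call: SnvCall) -> Optional[bool]:
        if call.status is None:
            return None
        return call.status is SomaticStatus.LOH

    return _partition("LOH", calls, remove)


def snv_proximity_filter(calls: Sequence[SnvCall], window_bp: int) -> FilterResult:
    """Remove every call within ``window_bp`` of *another* putative SNV.

    Both members of any close pair are removed. Neighborhood is judged on the
    input collection as given (single pass): a survivor whose only close
    neighbor was itself removed stays kept.
    """
    if window_bp < 0:
        raise ConfigError("window_bp must be >= 0")
    calls = list(calls)
    by_chrom: dict[str, list[int]] = {}
    for call in calls:
        by_chrom.setdefault(call.key.chrom, []).append(call.key.pos)
    for positions in by_chrom.values():
        positions.sort()

    import bisect

    def remove(call: SnvCall) -> bool:
        positions = by_chrom[call.key.chrom]
        lo = bisect.bisect_left(positions, call.key.pos - window_bp)
        hi = bisect.bisect_right(positions, call.key.pos + window_bp)
        # the window always contains the call itself once
        return (hi - lo) > 1

    return _partition("10bp-SNV", calls, remove)


def indel_proximity_filter(
    calls: Iterable[SnvCall],
    indels: Iterable[IndelRecord],
    window_bp: int,
) -> FilterResult:
    """Remove calls within ``window_bp`` of a putative indel's affected span.

    Distance to an indel is 0 for a position inside [start, end] and the gap
    to the nearer span edge otherwise.
    """
    if window_bp < 0:
        raise ConfigError("window_bp must be >= 0")
    trees: dict[str, IntervalTree] = {}
    for indel in indels:
        tree = trees.setdefault(indel.chrom, IntervalTree())
        # inflate the closed span by the window; IntervalTree is half-open
        tree.addi(indel.start - window_bp, indel.end + window_bp + 1)

    def remove(call: SnvCall) -> bool:
        tree = trees.get(call.key.chrom)
        return bool(tree is not None and tree.overlaps_point(call.key.pos))

    return _partition("10bp-INDEL", calls, remove)


def dbsnp_filter(
    calls: Iterable[SnvCall],
    sites: Iterable[SiteKey],
    mode: str = "position+alt",
) -> FilterResult:
    """Remove calls coinciding with a known-polymorphism site list.

    ``position-only`` matches on (chrom, pos); ``position+alt`` additionally
    requires the site's alt to be the wildcard or equal to the call's alt.
    """
    if mode not in ("position-only", "position+alt"):
        raise ConfigError(f"dbsnp mode must be 'position-only' or 'position+alt', got {mode!r}")
    by_position: set[tuple[str, int]] = set()
    by_allele: set[tuple[str, int, str]] = set()
    wildcard: set[tuple[str, int]] = set()
    for site in sites:
        by_position.add((site.chrom, site.pos))
        if site.alt == WILDCARD_ALT:
            wildcard.add((site.chrom, site.pos))
        else:
            by_allele.add((site.chrom, site.pos, site.alt))

    def remove(call: SnvCall) -> bool:
        locus = (call.key.chrom, call.key.pos)
        if mode == "position-only":
            return locus in by_position
        return locus in wildcard or (call.key.chrom, call.key.pos, call.key.alt) in by_allele

    return _partition("dbSNP", calls, remove)


def alt_fraction_filter(calls: Iterable[SnvCall], min_fraction: float) -> FilterResult:
    """Remove calls whose alternate-allele read fraction is below ``min_fraction``.

    Calls with zero or missing depth are kept and counted as missing.
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise ConfigError("min_fraction must lie in [0, 1]")

    def remove(call: SnvCall) -> Optional[bool]:
        fraction = call.alt_fraction
        if fraction is None:
            return None
        return fraction < min_fraction

    return _partition("lt10pct", calls, remove)


def apply_filters(
    calls: Sequence[SnvCall],
    config: FilterConfig,
    sites: Iterable[SiteKey] = (),
    indels: Iterable[IndelRecord] = (),
) -> tuple[list[FilterResult], set[SnvKey]]:
    """Run every enabled filter independently; return results and union removal.

    Each filter sees the full original call collection, so results do not
    depend on the order of ``config.enabled_filters``.
    """
    calls = list(calls)
    sites = list(sites)
    indels = list(indels)
    runners: Mapping[str, Callable[[], FilterResult]] = {
        "GATK": lambda: threshold_filter(calls, "qual", config.min_qual, strict=config.strict_missing),
        "SS": lambda: threshold_filter(calls, "ssc", config.min_ssc, strict=config.strict_missing),
        "VAQ": lambda: threshold_filter(calls, "vaq", config.min_vaq, strict=config.strict_missing),
        "LOH": lambda: loh_filter(calls),
        "10bp-SNV": lambda: snv_proximity_filter(calls, config.proximity_window_bp),
        "10bp-INDEL": lambda: indel_proximity_filter(calls, indels, config.proximity_window_bp),
        "dbSNP": lambda: dbsnp_filter(calls, sites, config.dbsnp_match_mode),
        "lt10pct": lambda: alt_fraction_filter(calls, config.min_alt_fraction),
    }
    results: list[FilterResult] = []
    combined: set[SnvKey] = set()
    for name in config.enabled_filters:
        if name not in runners:
            raise ConfigError(f"unknown filter name {name!r}; valid names: {list(FILTER_NAMES)}")
        result = runners[name]()
        results.append(result)
        combined |= result.removed
    return results, combined
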