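"""Shared data model for paired-replicate somatic SNV concordance analysis.

The unit of comparison throughout the package is an *individual mutation*,
identified by its genomic key ``(chrom, pos, ref, alt)``. Identity is
allele-aware: two different substitutions at the same site are different
mutations. Chromosome names are compared as exact strings; any normalization
("chr" prefix handling) happens at parse time, never silently here.

Numeric per-call annotations (caller quality, SomaticScore, VAQ, read depths)
may be *missing*, which is represented explicitly as ``None`` — never as 0.
Filters decide what missingness means; the model never imputes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "VALID_BASES",
    "WILDCARD_ALT",
    "FILTER_NAMES",
    "Replicate",
    "SomaticStatus",
    "ConcordError",
    "ConfigError",
    "DataError",
    "DuplicateKeyError",
    "SnvKey",
    "SiteKey",
    "IndelRecord",
    "SnvCall",
    "ReplicatePair",
    "FilterConfig",
    "snv_key_set",
]

VALID_BASES = frozenset("ACGT")

#: Alt marker on a SiteKey that matches any alternate allele (used for
#: interval-derived site lists, where no allele information exists).
WILDCARD_ALT = "*"

#: Canonical names of the eight call filters, in conventional display order.
FILTER_NAMES = (
    "GATK",
    "SS",
    "VAQ",
    "LOH",
    "10bp-SNV",
    "10bp-INDEL",
    "dbSNP",
    "lt10pct",
)


class ConcordError(Exception):
    """Base class for errors raised by this package."""


class ConfigError(ConcordError):
    """Invalid configuration (thresholds, filter names, dialects, flags)."""


class DataError(ConcordError):
    """Invalid or inconsistent input data."""


class DuplicateKeyError(DataError):
    """Two calls within one replicate share a (chrom, pos, ref, alt) key."""


class Replicate(str, Enum):
    """Technical-replicate label.

    WGS: standard whole-genome sequencing protocol (no pre-library
    amplification). WGA: the replicate with an extra whole-genome
    amplification step before library preparation.
    """

    WGS = "WGS"
    WGA = "WGA"


class SomaticStatus(str, Enum):
    """Somatic-status classification attached to a call by the caller."""

    SOMATIC = "SOMATIC"
    GERMLINE = "GERMLINE"
    LOH = "LOH"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True, order=True)
class SnvKey:
    """Identity of one putative somatic SNV: chrom, 1-based pos, ref, alt."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise DataError("SnvKey.chrom must be non-empty")
        if self.pos < 1:
            raise DataError(f"SnvKey.pos must be >= 1, got {self.pos}")
        if self.ref not in VALID_BASES:
            raise DataError(f"SnvKey.ref must be one of A/C/G/T, got {self.ref!r}")
        if self.alt not in VALID_BASES:
            raise DataError(f"SnvKey.alt must be one of A/C/G/T, got {self.alt!r}")
        if self.ref == self.alt:
            raise DataError(f"SnvKey.ref == SnvKey.alt ({self.ref!r}) at {self.chrom}:{self.pos}")

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"


@dataclass(frozen=True, order=True)
class SiteKey:
    """A site in an exclusion list (e.g. dbSNP); alt may be a wildcard."""

    chrom: str
    pos: int
    alt: str = WILDCARD_ALT

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataError(f"SiteKey.pos must be >= 1, got {self.pos}")


@dataclass(frozen=True, order=True)
class IndelRecord:
    """Reference span [start, end] (1-based, inclusive) affected by an indel."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise DataError(f"IndelRecord.start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise DataError(
                f"IndelRecord.end ({self.end}) must be >= start ({self.start})"
            )


@dataclass
class SnvCall:
    """One putative somatic SNV with its per-call annotations.

    ``qual`` is the record-level calling quality (the GATK-style score),
    ``ssc`` the SomaticScore, ``vaq`` the Variant Allele Quality; all are
    caller confidence scores thresholded by the corresponding filters.
    ``depth_total``/``depth_alt`` are tumor-sample read depths. Any of these
    may be ``None`` (explicitly missing).
    """

    key: SnvKey
    qual: Optional[float] = None
    ssc: Optional[float] = None
    vaq: Optional[float] = None
    status: Optional[SomaticStatus] = None
    depth_total: Optional[int] = None
    depth_alt: Optional[int] = None
    sample_id: str = ""
    replicate: Replicate = Replicate.WGS

    def __post_init__(self) -> None:
        for name in ("qual", "ssc", "vaq"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise DataError(f"SnvCall.{name} must be >= 0, got {value} at {self.key}")
        for name in ("depth_total", "depth_alt"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise DataError(f"SnvCall.{name} must be >= 0, got {value} at {self.key}")
        if (
            self.depth_total is not None
            and self.depth_alt is not None
            and self.depth_alt > self.depth_total
        ):
            raise DataError(
                f"SnvCall.depth_alt ({self.depth_alt}) exceeds depth_total "
                f"({self.depth_total}) at {self.key}"
            )

    @property
    def alt_fraction(self) -> Optional[float]:
        """Alternate-allele read fraction, or None when depths are unusable."""
        if self.depth_total is None or self.depth_alt is None or self.depth_total == 0:
            return None
        return self.depth_alt / self.depth_total


def snv_key_set(calls: Iterable[SnvCall]) -> set[SnvKey]:
    """Return the set of SnvKeys of ``calls``; error on duplicates.

    Raises
    ------
    DuplicateKeyError
        If two calls share the same (chrom, pos, ref, alt) identity.
    """
    keys: set[SnvKey] = set()
    for call in calls:
        if call.key in keys:
            raise DuplicateKeyError(f"duplicate SNV key {call.key}")
        keys.add(call.key)
    return keys


@dataclass
class ReplicatePair:
    """One patient's two somatic call sets plus optional covariates.

    ``metadata`` maps a replicate label to per-replicate scalars, e.g.
    ``{Replicate.WGS: {"coverage": 30.0, "pct_mapped": 98.2}}``.
    """

    sample_id: str
    wgs_calls: Sequence[SnvCall]
    wga_calls: Sequence[SnvCall]
    metadata: Optional[Mapping[Replicate, Mapping[str, float]]] = None

    def __post_init__(self) -> None:
        for calls, label in ((self.wgs_calls, Replicate.WGS), (self.wga_calls, Replicate.WGA)):
            for call in calls:
                if call.sample_id != self.sample_id:
                    raise DataError(
                        f"call {call.key} carries sample_id {call.sample_id!r}, "
                        f"pair is {self.sample_id!r}"
                    )
                if call.replicate is not label:
                    raise DataError(
                        f"call {call.key} labeled {call.replicate.value} found in the "
                        f"{label.value} replicate of {self.sample_id}"
                    )
            snv_key_set(calls)  # raises on duplicates

    def calls(self, replicate: Replicate) -> Sequence[SnvCall]:
        return self.wgs_calls if replicate is Replicate.WGS else self.wga_calls


@dataclass
class FilterConfig:
    """Thresholds and switches for the eight call filters.

    Defaults mirror the conventional somatic-calling recommendations: quality
    scores below 40 are discarded, proximity windows are 10 bp, and calls with
    an alternate-allele fraction below 10% are discarded. All comparisons are
    strict (< threshold removes; == threshold keeps).
    """

    min_qual: float = 40.0
    min_ssc: float = 40.0
    min_vaq: float = 40.0
    proximity_window_bp: int = 10
    min_alt_fraction: float = 0.10
    dbsnp_match_mode: str = "position+alt"  # or "position-only"
    enabled_filters: Sequence[str] = FILTER_NAMES
    strict_missing: bool = False

    def __post_init__(self) -> None:
        for name in ("min_qual", "min_ssc", "min_vaq"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.proximity_window_bp < 0:
            raise ConfigError("proximity_window_bp must be >= 0")
        if not 0.0 <= self.min_alt_fraction <= 1.0:
            raise ConfigError("min_alt_fraction must lie in [0, 1]")
        if self.dbsnp_match_mode not in ("position-only", "position+alt"):
            raise ConfigError(
                f"dbsnp_match_mode must be 'position-only' or 'position+alt', "
                f"got {self.dbsnp_match_mode!r}"
            )
        if not self.enabled_filters:
            raise ConfigError("no filters enabled")
        unknown = [n for n in self.enabled_filters if n not in FILTER_NAMES]
        if unknown:
            raise ConfigError(
                f"unknown filter name(s) {unknown}; valid names: {list(FILTER_NAMES)}"
            )
        self.enabled_filters = tuple(self.enabled_filters)
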