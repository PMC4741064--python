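"""Reading and writing the formats the pipeline touches.

Somatic VCFs (SomaticSniper-style per-sample FORMAT fields), dbSNP-like site
lists (VCF or BED3), indel position lists, per-sample metadata tables, and the
tidy tab-separated report tables. All parsing of VCF goes through
:mod:`pysam`; coordinates are 1-based inclusive internally (VCF convention),
with BED's 0-based half-open intervals converted on read.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from hashlib import sha256
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import pysam

from .model import (
    VALID_BASES,
    WILDCARD_ALT,
    ConfigError,
    DataError,
    DuplicateKeyError,
    IndelRecord,
    Replicate,
    SiteKey,
    SnvCall,
    SnvKey,
    SomaticStatus,
)

__all__ = [
    "VcfDialect",
    "read_somatic_vcf",
    "read_site_list",
    "read_indel_list",
    "read_metadata",
    "write_somatic_vcf",
    "write_filtered_vcf",
    "write_site_vcf",
    "write_indel_bed",
    "write_report_tables",
    "write_run_manifest",
]

logger = logging.getLogger(__name__)

#: Somatic-status FORMAT codes, SomaticSniper-style.
DEFAULT_STATUS_CODES: Mapping[int, SomaticStatus] = {
    1: SomaticStatus.GERMLINE,
    2: SomaticStatus.SOMATIC,
    3: SomaticStatus.LOH,
    4: SomaticStatus.UNKNOWN,
}
_STATUS_TO_CODE = {status: code for code, status in DEFAULT_STATUS_CODES.items()}

#: Fixed significant-digit float format used in every report table, so that
#: re-running an analysis reproduces byte-identical output.
FLOAT_FORMAT = "%.6g"


@dataclass
class VcfDialect:
    """How to pull per-call annotations out of a somatic VCF.

    ``qual_source`` is either the literal string ``"QUAL"`` (record-level
    quality column) or the name of a per-sample FORMAT field. Depth handling:
    ``depth_mode="AD"`` reads an allele-depth vector (total = sum, alt = the
    entry for the call's alt allele); ``depth_mode="DP4"`` reads a strand-split
    quartet (total = sum of all four, alt = sum of the last two). The tumor
    sample defaults to the last sample column.
    """

    qual_source: str = "QUAL"
    ssc_field: str = "SSC"
    vaq_field: str = "VAQ"
    status_field: str = "SS"
    depth_mode: str = "AD"  # "AD" or "DP4"
    depth_field: str = "AD"
    status_codes: Mapping[int, SomaticStatus] = field(
        default_factory=lambda: dict(DEFAULT_STATUS_CODES)
    )
    tumor_sample: Optional[str] = None
    chrom_normalization: str = "off"  # off | strip-chr | add-chr
    strict: bool = True

    def __post_init__(self) -> None:
        for name in ("qual_source", "ssc_field", "vaq_field", "status_field", "depth_field"):
            if not getattr(self, name):
                raise ConfigError(f"VcfDialect.{name} must be non-empty")
        if self.depth_mode not in ("AD", "DP4"):
            raise ConfigError(f"depth_mode must be 'AD' or 'DP4', got {self.depth_mode!r}")
        if self.chrom_normalization not in ("off", "strip-chr", "add-chr"):
            raise ConfigError(
                "chrom_normalization must be one of off/strip-chr/add-chr, "
                f"got {self.chrom_normalization!r}"
            )
        missing_codes = {1, 2, 3, 4} - set(self.status_codes)
        if missing_codes:
            raise ConfigError(f"status_codes must cover codes 1-4; missing {sorted(missing_codes)}")

    def normalize_chrom(self, chrom: str) -> str:
        if self.chrom_normalization == "strip-chr" and chrom.startswith("chr"):
            return chrom[3:]
        if self.chrom_normalization == "add-chr" and not chrom.startswith("chr"):
            return "chr" + chrom
        return chrom


def _check_header_fields(vcf: pysam.VariantFile, dialect: VcfDialect, path: str) -> set[str]:
    """Return the set of dialect FORMAT fields absent from the header.

    Strict dialects raise naming the first missing field; lenient dialects log
    one warning per field per file and carry the fields as missing.
    """
    wanted = {dialect.ssc_field, dialect.vaq_field, dialect.status_field, dialect.depth_field}
    if dialect.qual_source != "QUAL":
        wanted.add(dialect.qual_source)
    absent = {name for name in wanted if name not in vcf.header.formats}
    if absent:
        if dialect.strict:
            raise DataError(
                f"{path}: VCF header is missing declared FORMAT field "
                f"{sorted(absent)[0]!r} (strict dialect)"
            )
        for name in sorted(absent):
            logger.warning("%s: FORMAT field %r absent; carried as missing", path, name)
    return absent


def _scalar(value) -> Optional[float]:
    """Unwrap pysam's Number=1 values (may come back as a 1-tuple)."""
    if value is None:
        return None
    if isinstance(value, tuple):
        if not value or value[0] is None:
            return None
        value = value[0]
    return float(value)


def read_somatic_vcf(
    path: str | Path,
    dialect: Optional[VcfDialect] = None,
    sample_id: str = "",
    replicate: Replicate = Replicate.WGS,
) -> tuple[list[SnvCall], list[IndelRecord]]:
    """Parse one somatic VCF into SNV calls and indel spans.

    Every biallelic-SNV alt of a record becomes one :class:`SnvCall`
    (multi-allelic records are decomposed); any record whose ref or some alt
    is longer than one base contributes one :class:`IndelRecord` spanning
    ``[pos, pos + len(ref) - 1]``. Records are returned in file order.
    """
    dialect = dialect or VcfDialect()
    path = str(path)
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise DataError(f"cannot read VCF {path}: {exc}") from exc
    with vcf:
        absent = _check_header_fields(vcf, dialect, path)
        samples = list(vcf.header.samples)
        tumor = dialect.tumor_sample
        if tumor is None:
            tumor = samples[-1] if samples else None
        elif tumor not in samples:
            raise DataError(f"{path}: tumor sample {tumor!r} not in VCF samples {samples}")

        calls: list[SnvCall] = []
        indels: list[IndelRecord] = []
        seen: set[SnvKey] = set()
        for record in vcf:
            chrom = dialect.normalize_chrom(record.chrom)
            ref = record.ref or ""
            alts = record.alts or ()
            if len(ref) > 1 or any(len(alt) > 1 for alt in alts):
                indels.append(IndelRecord(chrom, record.pos, record.pos + len(ref) - 1))
            if len(ref) != 1 or ref not in VALID_BASES:
                continue
            fmt = record.samples[tumor] if tumor is not None else None

            def fetch(field_name: str) -> Optional[float]:
                if fmt is None or field_name in absent:
                    return None
                return _scalar(fmt.get(field_name))

            if dialect.qual_source == "QUAL":
                qual = record.qual if record.qual is not None else None
            else:
                qual = fetch(dialect.qual_source)
            ssc = fetch(dialect.ssc_field)
            vaq = fetch(dialect.vaq_field)
            status_code = fetch(dialect.status_field)
            status = (
                dialect.status_codes.get(int(status_code)) if status_code is not None else None
            )
            depth_raw = (
                fmt.get(dialect.depth_field)
                if fmt is not None and dialect.depth_field not in absent
                else None
            )

            for alt_index, alt in enumerate(alts):
                if len(alt) != 1 or alt not in VALID_BASES:
                    continue
                depth_total: Optional[int] = None
                depth_alt: Optional[int] = None
                if depth_raw is not None and not all(v is None for v in depth_raw):
                    values = [int(v) for v in depth_raw if v is not None]
                    depth_total = sum(values)
                    if dialect.depth_mode == "AD":
                        if alt_index + 1 < len(depth_raw) and depth_raw[alt_index + 1] is not None:
                            depth_alt = int(depth_raw[alt_index + 1])
                    else:  # DP4 quartet: ref fwd/rev then alt fwd/rev
                        if len(values) == 4:
                            depth_alt = values[2] + values[3]
                key = SnvKey(chrom, record.pos, ref, alt)
                if key in seen:
                    raise DuplicateKeyError(f"{path}: duplicate SNV key {key}")
                seen.add(key)
                calls.append(
                    SnvCall(
                        key=key,
                        qual=qual,
                        ssc=ssc,
                        vaq=vaq,
                        status=status,
                        depth_total=depth_total,
                        depth_alt=depth_alt,
                        sample_id=sample_id,
                        replicate=replicate,
                    )
                )
    return calls, indels


def read_site_list(path: str | Path) -> set[SiteKey]:
    """Read a site exclusion list from VCF (allele-aware) or BED3 (wildcard).

    BED intervals are 0-based half-open; each covered base becomes one
    1-based :class:`SiteKey` with the wildcard alt.
    """
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".vcf", ".vcf.gz")):
        sites: set[SiteKey] = set()
        with pysam.VariantFile(str(path)) as vcf:
            for record in vcf:
                for alt in record.alts or (WILDCARD_ALT,):
                    alt = alt if alt in VALID_BASES else WILDCARD_ALT
                    sites.add(SiteKey(record.chrom, record.pos, alt))
        return sites
    if name.endswith(".bed"):
        sites = set()
        with open(path) as handle:
            for line_no, line in enumerate(handle, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split()
                if len(parts) < 3:
                    raise DataError(f"{path}:{line_no}: BED line has fewer than 3 columns")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                # half-open [start, end) zero-based -> 1-based closed positions
                for pos in range(start + 1, end + 1):
                    sites.add(SiteKey(chrom, pos, WILDCARD_ALT))
        return sites
    raise DataError(
        f"unrecognized site-list format for {path}; accepted: .vcf, .vcf.gz, .bed"
    )


def read_indel_list(path: str | Path) -> list[IndelRecord]:
    """Read indel spans from BED3 (spans as-is) or VCF (indel records only)."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith(".bed"):
        indels: list[IndelRecord] = []
        with open(path) as handle:
            for line_no, line in enumerate(handle, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split()
                if len(parts) < 3:
                    raise DataError(f"{path}:{line_no}: BED line has fewer than 3 columns")
                indels.append(IndelRecord(parts[0], int(parts[1]) + 1, int(parts[2])))
        return indels
    if name.endswith((".vcf", ".vcf.gz")):
        lenient = VcfDialect(strict=False)
        _, indels = read_somatic_vcf(path, lenient)
        return indels
    raise DataError(
        f"unrecognized indel-list format for {path}; accepted: .vcf, .vcf.gz, .bed"
    )


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the per-replicate covariate table (TSV).

    Required columns: sample_id, replicate; optional: coverage, pct_mapped.
    """
    table = pd.read_csv(path, sep="\t")
    missing = {"sample_id", "replicate"} - set(table.columns)
    if missing:
        raise DataError(f"{path}: metadata table missing column(s) {sorted(missing)}")
    return table


# ---------------------------------------------------------------------------
# writing


def _build_header(
    calls: Sequence[SnvCall],
    contigs: Optional[Mapping[str, int]],
    filter_names: Iterable[str],
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    if contigs is None:
        contigs = {}
        for call in calls:
            contigs[call.key.chrom] = max(contigs.get(call.key.chrom, 0), call.key.pos)
        contigs = {chrom: pos + 1000 for chrom, pos in sorted(contigs.items())}
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    for name in filter_names:
        if name != "PASS":
            header.filters.add(name, None, None, f"Removed by the {name} filter")
    header.formats.add("SS", 1, "Integer", "Somatic status (1=germline,2=somatic,3=LOH,4=unknown)")
    header.formats.add("SSC", 1, "Float", "Somatic score")
    header.formats.add("VAQ", 1, "Float", "Variant allele quality")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.add_sample("NORMAL")
    header.add_sample("TUMOR")
    return header


def write_filtered_vcf(
    calls: Sequence[SnvCall],
    removed_keys: set[SnvKey],
    path: str | Path,
    mode: str = "flag",
    filter_name: str = "FAIL",
    labels: Optional[Mapping[SnvKey, Sequence[str]]] = None,
    contigs: Optional[Mapping[str, int]] = None,
) -> None:
    """Write calls to a VCF, dropping or FILTER-flagging the removed keys.

    ``drop`` mode omits removed calls; ``flag`` mode writes every call, with
    removed calls carrying the removing filter's name in the FILTER column
    (``labels`` supplies per-key filter names for multi-filter runs) and
    ``PASS`` otherwise. Output is plain-text VCF 4.2, one record per call,
    sorted by (chrom, pos, ref, alt) for reproducibility.
    """
    if mode not in ("drop", "flag"):
        raise ConfigError(f"mode must be 'drop' or 'flag', got {mode!r}")
    all_names: set[str] = {filter_name}
    if labels:
        for names in labels.values():
            all_names.update(names)
    header = _build_header(calls, contigs, sorted(all_names))
    ordered = sorted(calls, key=lambda c: c.key)
    try:
        out = pysam.VariantFile(str(path), "w", header=header)
    except (OSError, ValueError) as exc:
        raise DataError(f"cannot write VCF {path}: {exc}") from exc
    with out:
        for call in ordered:
            removed = call.key in removed_keys
            if removed and mode == "drop":
                continue
            record = out.new_record(
                contig=call.key.chrom,
                start=call.key.pos - 1,
                alleles=(call.key.ref, call.key.alt),
            )
            record.qual = call.qual
            if removed:
                names = labels.get(call.key, (filter_name,)) if labels else (filter_name,)
                for name in names:
                    record.filter.add(name)
            else:
                record.filter.add("PASS")
            tumor = record.samples["TUMOR"]
            if call.status is not None:
                tumor["SS"] = _STATUS_TO_CODE[call.status]
            if call.ssc is not None:
                tumor["SSC"] = call.ssc
            if call.vaq is not None:
                tumor["VAQ"] = call.vaq
            if call.depth_total is not None and call.depth_alt is not None:
                tumor["AD"] = (call.depth_total - call.depth_alt, call.depth_alt)
            out.write(record)


def write_somatic_vcf(
    calls: Sequence[SnvCall],
    path: str | Path,
    contigs: Optional[Mapping[str, int]] = None,
) -> None:
    """Write a call collection as an all-PASS somatic VCF."""
    write_filtered_vcf(calls, set(), path, mode="flag", contigs=contigs)


def write_site_vcf(
    sites: Sequence[SnvKey],
    path: str | Path,
    contigs: Optional[Mapping[str, int]] = None,
) -> None:
    """Write a site panel (e.g. a synthetic dbSNP stand-in) as a sites-only VCF."""
    header = pysam.VariantHeader()
    if contigs is None:
        lengths: dict[str, int] = {}
        for site in sites:
            lengths[site.chrom] = max(lengths.get(site.chrom, 0), site.pos)
        contigs = {chrom: pos + 1000 for chrom, pos in sorted(lengths.items())}
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for site in sorted(sites):
            record = out.new_record(
                contig=site.chrom, start=site.pos - 1, alleles=(site.ref, site.alt)
            )
            out.write(record)


def write_indel_bed(indels: Sequence[IndelRecord], path: str | Path) -> None:
    """Write indel spans as BED3 (1-based closed -> 0-based half-open)."""
    with open(path, "w") as handle:
        for indel in sorted(indels):
            handle.write(f"{indel.chrom}\t{indel.start - 1}\t{indel.end}\n")


def _frame_to_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT, na_rep="NA")


def write_report_tables(results, out_dir: str | Path) -> dict[str, Path]:
    """Write the tidy report tables for one cohort run.

    ``results`` is a :class:`~replicate_concord.pipeline.CohortResults`.
    Emits ``pair_overlap.tsv`` (one row per pair), ``filter_effects.tsv``
    (one row per pair x filter), ``cohort_summary.tsv`` and, when present,
    ``correlations.tsv`` — all tab-separated with a fixed float format so
    identical inputs reproduce byte-identical files.
    """
    if results.pair_table is None or results.pair_table.empty:
        raise DataError("no pairs analyzed")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, frame in (
        ("pair_overlap", results.pair_table),
        ("filter_effects", results.effect_table),
        ("cohort_summary", results.summary_table),
        ("correlations", results.correlations),
    ):
        if frame is None:
            continue
        path = out_dir / f"{name}.tsv"
        _frame_to_tsv(frame, path)
        written[name] = path
    return written


def write_run_manifest(
    path: str | Path,
    config: Mapping,
    input_paths: Iterable[str | Path] = (),
    seed: Optional[int] = None,
) -> None:
    """Write a JSON run manifest: config echo, input checksums, seed."""
    checksums = {}
    for input_path in input_paths:
        input_path = Path(input_path)
        checksums[input_path.name] = sha256(input_path.read_bytes()).hexdigest()
    manifest = {"config": config, "inputs_sha256": checksums, "seed": seed}
    with open(path, "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True, default=str)
        handle.write("\n")
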