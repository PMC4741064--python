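"""Synthetic paired technical-replicate call sets with ground truth.

The generator encodes the generative model the concordance analysis assumes:
a tumor carries a set of true fixed somatic SNVs, each of which is detected
in a replicate independently with probability ``detect_prob``; on top of
these, each replicate accrues its own false calls (sequencing, amplification
and alignment artifacts), with the amplified (WGA) replicate receiving more.
Per-tumor true-mutation counts vary over orders of magnitude (log-uniform),
matching the wide dispersion seen in real tumor cohorts.

False calls carry planted structure the filters can catch: a fraction sits on
known-polymorphism (dbSNP-like) sites, a fraction clusters near an indel or
near another false call. Loss-of-heterozygosity status is assigned at random
to calls regardless of truth, so the LOH filter is non-discriminating by
construction. Quality scores for true calls are drawn from a higher
distribution than for false calls, with overlap; read depths follow a
Poisson coverage model with Beta-distributed alt fractions.

Every emitted call has exactly one ground-truth row, which is what a real
controlled-access cohort cannot provide.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    DataError,
    IndelRecord,
    Replicate,
    ReplicatePair,
    SiteKey,
    SnvCall,
    SnvKey,
    SomaticStatus,
)
from . import vcf_io

__all__ = [
    "SimParams",
    "TRUTH_COLUMNS",
    "simulate_pair",
    "simulate_cohort",
    "expected_overlap_fraction",
    "generate_panels",
]

_BASES = np.array(list("ACGT"))

TRUTH_COLUMNS = (
    "sample_id",
    "replicate",
    "chrom",
    "pos",
    "ref",
    "alt",
    "truth",
    "error_class",
)


@dataclass
class SimParams:
    """Generator parameters; all randomness flows from the single ``seed``.

    ``n_true_range`` is sampled log-uniformly per patient, emulating
    order-of-magnitude variation in per-tumor mutation burden. ``n_err_wgs``
    and ``n_err_wga`` are Poisson means for replicate-specific false calls;
    the WGA replicate's excess models amplification error.
    """

    n_patients: int = 10
    n_true_range: tuple[int, int] = (100, 5000)
    detect_prob: float = 0.66
    n_err_wgs: float = 400.0
    n_err_wga: float = 1100.0
    frac_loh: float = 0.35
    frac_dbsnp_artifact: float = 0.05
    frac_clustered: float = 0.08
    proximity_window_bp: int = 10
    # quality-score model: true calls high, false calls lower, overlapping
    true_score_mean: float = 120.0
    true_score_sd: float = 25.0
    err_score_mean: float = 45.0
    err_score_sd: float = 20.0
    # depth model
    mean_coverage: float = 30.0
    true_alt_beta: tuple[float, float] = (9.0, 11.0)  # mean 0.45
    err_alt_beta: tuple[float, float] = (3.0, 17.0)  # mean 0.15
    # genome model
    n_chroms: int = 3
    chrom_length_bp: int = 10_000_000
    # shared site/indel panels
    n_dbsnp_sites: int = 5000
    n_indels: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.n_true_range
        if not (0 < lo <= hi):
            raise DataError("n_true_range must satisfy 0 < lo <= hi")
        for name in ("detect_prob", "frac_loh", "frac_dbsnp_artifact", "frac_clustered"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise DataError(f"{name} must lie in [0, 1], got {value}")
        if self.frac_dbsnp_artifact + self.frac_clustered > 1.0:
            raise DataError("planted error fractions exceed 1")
        if self.n_chroms < 1 or self.chrom_length_bp < 1000:
            raise DataError("genome model too small")
        genome = self.n_chroms * self.chrom_length_bp
        if self.n_true_range[1] + self.n_err_wgs + self.n_err_wga > genome // 100:
            raise DataError("requested call counts exceed genome capacity")

    @property
    def contigs(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length_bp for i in range(self.n_chroms)}

    @property
    def genome_size_mbp(self) -> float:
        return self.n_chroms * self.chrom_length_bp / 1e6


def expected_overlap_fraction(n_true: float, detect_prob: float, n_err: float) -> float:
    """Expected percent of one replicate's calls also found in the other.

    Under independent per-replicate detection with probability ``p`` and
    ``n_err`` expected replicate-private false calls, a replicate holds
    ``n_true*p + n_err`` calls of which ``n_true*p**2`` are expected to be
    shared, giving ``100 * n_true*p**2 / (n_true*p + n_err)``.
    """
    denominator = n_true * detect_prob + n_err
    if denominator <= 0:
        raise DataError("expected call count is zero; overlap fraction undefined")
    return 100.0 * n_true * detect_prob**2 / denominator


def _random_key(rng: np.random.Generator, params: SimParams) -> SnvKey:
    chrom = f"chr{int(rng.integers(params.n_chroms)) + 1}"
    pos = int(rng.integers(1, params.chrom_length_bp + 1))
    ref, alt = rng.choice(4, size=2, replace=False)
    return SnvKey(chrom, pos, str(_BASES[ref]), str(_BASES[alt]))


def generate_panels(
    params: SimParams, rng: np.random.Generator
) -> tuple[list[SnvKey], list[IndelRecord]]:
    """Generate the cohort-shared dbSNP-like site panel and indel panel."""
    site_keys: dict[tuple[str, int], SnvKey] = {}
    while len(site_keys) < params.n_dbsnp_sites:
        key = _random_key(rng, params)
        site_keys.setdefault((key.chrom, key.pos), key)
    indels: list[IndelRecord] = []
    for _ in range(params.n_indels):
        chrom = f"chr{int(rng.integers(params.n_chroms)) + 1}"
        start = int(rng.integers(1, params.chrom_length_bp - 50))
        length = int(rng.integers(1, 6))  # affected span of 1-5 bases
        indels.append(IndelRecord(chrom, start, start + length - 1))
    return sorted(site_keys.values()), sorted(indels)


def _scores(rng: np.random.Generator, mean: float, sd: float) -> float:
    """One integer quality score, normal with floor at 0."""
    return float(max(0, round(rng.normal(mean, sd))))


def _depths(
    rng: np.random.Generator, params: SimParams, beta: tuple[float, float]
) -> tuple[int, int]:
    depth_total = int(rng.poisson(params.mean_coverage))
    fraction = rng.beta(*beta)
    depth_alt = int(rng.binomial(depth_total, fraction)) if depth_total else 0
    return depth_total, depth_alt


def _make_call(
    rng: np.random.Generator,
    params: SimParams,
    key: SnvKey,
    sample_id: str,
    replicate: Replicate,
    is_true: bool,
) -> SnvCall:
    mean, sd = (
        (params.true_score_mean, params.true_score_sd)
        if is_true
        else (params.err_score_mean, params.err_score_sd)
    )
    beta = params.true_alt_beta if is_true else params.err_alt_beta
    depth_total, depth_alt = _depths(rng, params, beta)
    status = SomaticStatus.LOH if rng.random() < params.frac_loh else SomaticStatus.SOMATIC
    return SnvCall(
        key=key,
        qual=_scores(rng, mean, sd),
        ssc=_scores(rng, mean, sd),
        vaq=_scores(rng, mean, sd),
        status=status,
        depth_total=depth_total,
        depth_alt=depth_alt,
        sample_id=sample_id,
        replicate=replicate,
    )


def _clip_pos(pos: int, params: SimParams) -> int:
    return min(max(pos, 1), params.chrom_length_bp)


def simulate_pair(
    params: SimParams,
    sample_id: str,
    rng: np.random.Generator,
    sites: Optional[Sequence[SnvKey]] = None,
    indels: Optional[Sequence[IndelRecord]] = None,
) -> tuple[ReplicatePair, pd.DataFrame, list[SnvKey], list[IndelRecord]]:
    """Simulate one patient's WGS/WGA replicate pair with ground truth.

    True mutations are sampled once per patient at distinct keys, then
    detected in each replicate independently with ``detect_prob``; false
    calls are drawn per replicate (Poisson counts, WGA mean higher), with the
    planted dbSNP / near-indel / clustered fractions. Returns the pair, its
    truth table, and the site and indel panels used (generated here unless
    supplied, so cohorts can share panels).
    """
    if sites is None or indels is None:
        panel_sites, panel_indels = generate_panels(params, rng)
        sites = sites if sites is not None else panel_sites
        indels = indels if indels is not None else panel_indels
    sites = list(sites)
    indels = list(indels)

    lo, hi = params.n_true_range
    n_true = int(round(float(np.exp(rng.uniform(np.log(lo), np.log(hi))))))
    true_keys: set[SnvKey] = set()
    while len(true_keys) < n_true:
        true_keys.add(_random_key(rng, params))
    true_list = sorted(true_keys)

    calls: dict[Replicate, list[SnvCall]] = {Replicate.WGS: [], Replicate.WGA: []}
    truth_rows: list[tuple] = []

    detected = {
        rep: rng.random(n_true) < params.detect_prob
        for rep in (Replicate.WGS, Replicate.WGA)
    }
    for rep in (Replicate.WGS, Replicate.WGA):
        for key, hit in zip(true_list, detected[rep]):
            if not hit:
                continue
            call = _make_call(rng, params, key, sample_id, rep, is_true=True)
            calls[rep].append(call)
            truth_rows.append(
                (sample_id, rep.value, key.chrom, key.pos, key.ref, key.alt, "TRUE_FIXED", "")
            )

    p_dbsnp = params.frac_dbsnp_artifact
    p_cluster = params.frac_clustered / 2.0  # near another false call
    p_indel = params.frac_clustered / 2.0  # near an indel
    class_probs = np.array([p_dbsnp, p_indel, p_cluster, 1.0 - p_dbsnp - p_indel - p_cluster])

    for rep, err_mean in ((Replicate.WGS, params.n_err_wgs), (Replicate.WGA, params.n_err_wga)):
        n_err = int(rng.poisson(err_mean))
        used = {c.key for c in calls[rep]} | true_keys
        placed: list[SnvCall] = []
        classes = rng.choice(4, size=n_err, p=class_probs)
        # generate non-clustered errors first so clustered ones have anchors
        for error_class_id in sorted(range(n_err), key=lambda i: classes[i] == 2):
            class_id = int(classes[error_class_id])
            key: Optional[SnvKey] = None
            label = "GENERIC"
            for _attempt in range(50):
                if class_id == 0 and sites:  # planted on a dbSNP-like site
                    key = sites[int(rng.integers(len(sites)))]
                    label = "DBSNP_SITE"
                elif class_id == 1 and indels:  # within the window of an indel
                    indel = indels[int(rng.integers(len(indels)))]
                    offset = int(rng.integers(0, params.proximity_window_bp + 1))
                    pos = indel.start - offset if rng.random() < 0.5 else indel.end + offset
                    template = _random_key(rng, params)
                    key = SnvKey(
                        indel.chrom, _clip_pos(pos, params), template.ref, template.alt
                    )
                    label = "NEAR_INDEL"
                elif class_id == 2 and placed:  # clustered near another false call
                    anchor = placed[int(rng.integers(len(placed)))]
                    offset = int(rng.integers(1, params.proximity_window_bp + 1))
                    pos = anchor.key.pos + (offset if rng.random() < 0.5 else -offset)
                    template = _random_key(rng, params)
                    key = SnvKey(
                        anchor.key.chrom, _clip_pos(pos, params), template.ref, template.alt
                    )
                    label = "CLUSTERED"
                else:
                    key = _random_key(rng, params)
                    label = "GENERIC"
                if key not in used:
                    break
                key = None
            if key is None:  # pathological collision streak; place anywhere free
                while True:
                    key = _random_key(rng, params)
                    label = "GENERIC"
                    if key not in used:
                        break
            used.add(key)
            call = _make_call(rng, params, key, sample_id, rep, is_true=False)
            if label == "GENERIC" and call.status is SomaticStatus.LOH:
                label = "LOH_ARTIFACT"
            placed.append(call)
            truth_rows.append(
                (sample_id, rep.value, key.chrom, key.pos, key.ref, key.alt, "ERROR", label)
            )
        calls[rep].extend(placed)

    pair = ReplicatePair(
        sample_id=sample_id,
        wgs_calls=calls[Replicate.WGS],
        wga_calls=calls[Replicate.WGA],
    )
    truth = pd.DataFrame(truth_rows, columns=list(TRUTH_COLUMNS))
    truth = truth.sort_values(["replicate", "chrom", "pos", "alt"], kind="stable").reset_index(
        drop=True
    )
    return pair, truth, list(sites), indels


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    """Derive an independent per-patient stream from the single cohort seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def simulate_cohort_pairs(
    params: SimParams,
) -> tuple[list[ReplicatePair], pd.DataFrame, list[SnvKey], list[IndelRecord]]:
    """Simulate all patients in memory; shared site/indel panels."""
    panel_rng = _patient_rng(params.seed, 0)
    sites, indels = generate_panels(params, panel_rng)
    pairs: list[ReplicatePair] = []
    truths: list[pd.DataFrame] = []
    for index in range(params.n_patients):
        sample_id = f"P{index + 1:03d}"
        rng = _patient_rng(params.seed, index + 1)
        pair, truth, _, _ = simulate_pair(params, sample_id, rng, sites=sites, indels=indels)
        pairs.append(pair)
        truths.append(truth)
    truth = pd.concat(truths, ignore_index=True) if truths else pd.DataFrame(columns=TRUTH_COLUMNS)
    return pairs, truth, sites, indels


def simulate_cohort(params: SimParams, out_dir: str | Path) -> Path:
    """Simulate a cohort and write it to disk; returns the manifest path.

    Writes per-patient ``{sid}_WGS.vcf`` / ``{sid}_WGA.vcf``, the shared
    ``dbsnp.vcf`` site panel and ``indels.bed``, a combined ``truth.tsv``,
    the pairs ``manifest.tsv`` (paths relative to the manifest), and a JSON
    run manifest echoing parameters, seed and file checksums.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs, truth, sites, indels = simulate_cohort_pairs(params)
    contigs = params.contigs
    manifest_rows = []
    written: list[Path] = []
    for pair in pairs:
        wgs_path = out_dir / f"{pair.sample_id}_WGS.vcf"
        wga_path = out_dir / f"{pair.sample_id}_WGA.vcf"
        vcf_io.write_somatic_vcf(pair.wgs_calls, wgs_path, contigs=contigs)
        vcf_io.write_somatic_vcf(pair.wga_calls, wga_path, contigs=contigs)
        manifest_rows.append((pair.sample_id, wgs_path.name, wga_path.name))
        written.extend([wgs_path, wga_path])

    dbsnp_path = out_dir / "dbsnp.vcf"
    vcf_io.write_site_vcf(sites, dbsnp_path, contigs=contigs)
    indel_path = out_dir / "indels.bed"
    vcf_io.write_indel_bed(indels, indel_path)
    truth_path = out_dir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)

    manifest_path = out_dir / "manifest.tsv"
    pd.DataFrame(manifest_rows, columns=["sample_id", "wgs_vcf", "wga_vcf"]).to_csv(
        manifest_path, sep="\t", index=False
    )
    vcf_io.write_run_manifest(
        out_dir / "run_manifest.json",
        config=dataclasses.asdict(params),
        input_paths=written + [dbsnp_path, indel_path, truth_path, manifest_path],
        seed=params.seed,
    )
    return manifest_path
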