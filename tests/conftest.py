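from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from replicate_concord.model import Replicate, ReplicatePair, SnvCall, SnvKey
from replicate_concord.synthetic import SimParams, simulate_cohort_pairs

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

BASES = "ACGT"


def make_key(pos: int, chrom: str = "chr1", ref: str = "A", alt: str = "G") -> SnvKey:
    return SnvKey(chrom, pos, ref, alt)


def make_call(
    pos: int,
    chrom: str = "chr1",
    ref: str = "A",
    alt: str = "G",
    sample_id: str = "S1",
    replicate: Replicate = Replicate.WGS,
    **fields,
) -> SnvCall:
    return SnvCall(
        key=SnvKey(chrom, pos, ref, alt),
        sample_id=sample_id,
        replicate=replicate,
        **fields,
    )


def calls_from_keys(keys, sample_id="S1", replicate=Replicate.WGS, **fields):
    return [
        SnvCall(key=key, sample_id=sample_id, replicate=replicate, **fields)
        for key in keys
    ]


def make_pair(wgs_keys, wga_keys, sample_id="S1") -> ReplicatePair:
    return ReplicatePair(
        sample_id=sample_id,
        wgs_calls=calls_from_keys(wgs_keys, sample_id, Replicate.WGS),
        wga_calls=calls_from_keys(wga_keys, sample_id, Replicate.WGA),
    )


def random_keys(rng: np.random.Generator, n: int, pos_range: int = 10_000) -> set[SnvKey]:
    """n distinct random SNV keys on a small two-chromosome genome."""
    keys: set[SnvKey] = set()
    while len(keys) < n:
        chrom = f"chr{int(rng.integers(1, 3))}"
        pos = int(rng.integers(1, pos_range + 1))
        ref, alt = rng.choice(4, size=2, replace=False)
        keys.add(SnvKey(chrom, pos, BASES[ref], BASES[alt]))
    return keys


def random_pair(rng: np.random.Generator, max_calls: int = 30, sample_id="S1") -> ReplicatePair:
    """Random replicate pair with a controllable amount of shared keys."""
    n_shared = int(rng.integers(0, max_calls // 2 + 1))
    n_wgs_only = int(rng.integers(0, max_calls // 2 + 1))
    n_wga_only = int(rng.integers(0, max_calls // 2 + 1))
    pool = list(random_keys(rng, n_shared + n_wgs_only + n_wga_only + 1))
    shared = pool[:n_shared]
    wgs = shared + pool[n_shared : n_shared + n_wgs_only]
    wga = shared + pool[n_shared + n_wgs_only : n_shared + n_wgs_only + n_wga_only]
    return make_pair(wgs, wga, sample_id)


#: Fixed seed for the shared default-parameter cohort used by the
#: parameter-recovery and filter-discrimination checks.
COHORT_SEED = 11


@pytest.fixture(scope="session")
def default_cohort():
    """A 20-patient cohort simulated with default generator parameters."""
    params = SimParams(n_patients=20, seed=COHORT_SEED)
    pairs, truth, sites, indels = simulate_cohort_pairs(params)
    return params, pairs, truth, sites, indels
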