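from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from replicate_concord.filters import (
    alt_fraction_filter,
    apply_filters,
    dbsnp_filter,
    indel_proximity_filter,
    loh_filter,
    snv_proximity_filter,
    threshold_filter,
)
from replicate_concord.model import (
    ConfigError,
    DataError,
    FilterConfig,
    IndelRecord,
    SiteKey,
    SomaticStatus,
)

from conftest import calls_from_keys, make_call, random_keys
from oracle_utils import brute_force_indel_proximity, brute_force_snv_proximity


def keys(result):
    return {k.pos for k in result.removed}


class TestThresholdFilters:
    @pytest.mark.parametrize(
        "field, name", [("qual", "GATK"), ("ssc", "SS"), ("vaq", "VAQ")]
    )
    def test_strictly_below_threshold_removes(self, field, name):
        """Scores {10, 39} fall, {40, 41, 100} survive a threshold of 40."""
        calls = [
            make_call(pos, **{field: value})
            for pos, value in zip((1, 2, 3, 4, 5), (10.0, 39.0, 40.0, 41.0, 100.0))
        ]
        result = threshold_filter(calls, field, 40.0)
        assert result.filter_name == name
        assert keys(result) == {1, 2}
        assert {k.pos for k in result.kept} == {3, 4, 5}

    def test_empty_and_noop(self):
        assert threshold_filter([], "vaq", 40.0).removed == set()
        calls = [make_call(p, vaq=50.0) for p in (1, 2)]
        assert threshold_filter(calls, "vaq", 40.0).removed == set()

    def test_missing_field_kept_and_counted(self):
        calls = [make_call(1, vaq=10.0), make_call(2)]
        result = threshold_filter(calls, "vaq", 40.0)
        assert keys(result) == {1}
        assert result.n_missing_field == 1
        assert {k.pos for k in result.kept} == {2}

    def test_strict_mode_raises_on_missing(self):
        with pytest.raises(DataError, match="vaq"):
            threshold_filter([make_call(1)], "vaq", 40.0, strict=True)

    def test_unknown_field_rejected(self):
        with pytest.raises(ConfigError):
            threshold_filter([], "depth_total", 40.0)


class TestLohFilter:
    def test_targets_only_loh_status(self):
        calls = (
            [make_call(p, status=SomaticStatus.SOMATIC) for p in range(1, 5)]
            + [make_call(p, status=SomaticStatus.LOH) for p in range(10, 13)]
            + [make_call(20, status=SomaticStatus.GERMLINE)]
            + [make_call(21)]  # missing status
        )
        result = loh_filter(calls)
        assert keys(result) == {10, 11, 12}
        assert result.n_missing_field == 1
        assert 20 in {k.pos for k in result.kept}

    def test_all_somatic_is_noop(self):
        calls = [make_call(p, status=SomaticStatus.SOMATIC) for p in (1, 2)]
        assert loh_filter(calls).removed == set()


class TestSnvProximity:
    def test_single_call_has_no_neighbor(self):
        assert snv_proximity_filter([make_call(100)], 10).removed == set()

    def test_window_boundary_is_inclusive(self):
        both = snv_proximity_filter([make_call(100), make_call(110)], 10)
        assert keys(both) == {100, 110}
        neither = snv_proximity_filter([make_call(100), make_call(111)], 10)
        assert neither.removed == set()

    def test_chain_removes_all_without_transitivity(self):
        calls = [make_call(p) for p in (100, 108, 116)]
        assert keys(snv_proximity_filter(calls, 10)) == {100, 108, 116}

    def test_chromosomes_do_not_neighbor(self):
        calls = [make_call(100, chrom="chr1"), make_call(100, chrom="chr2", ref="C", alt="T")]
        assert snv_proximity_filter(calls, 10).removed == set()

    def test_same_position_different_alt_are_neighbors(self):
        calls = [make_call(100, alt="G"), make_call(100, alt="T")]
        assert len(snv_proximity_filter(calls, 0).removed) == 2

    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_all_pairs(self, seed):
        rng = np.random.default_rng(seed)
        calls = calls_from_keys(random_keys(rng, int(rng.integers(2, 60)), pos_range=400))
        window = int(rng.integers(0, 25))
        assert snv_proximity_filter(calls, window).removed == brute_force_snv_proximity(
            calls, window
        )

    def test_single_pass_judged_on_original_set(self):
        """Re-applying to the kept set removes nothing: survivors had no close
        neighbor in the original superset, hence none in any subset."""
        rng = np.random.default_rng(0)
        calls = calls_from_keys(random_keys(rng, 50, pos_range=300))
        first = snv_proximity_filter(calls, 10)
        kept_calls = [c for c in calls if c.key in first.kept]
        assert snv_proximity_filter(kept_calls, 10).removed == set()


class TestIndelProximity:
    def test_empty_indel_list_is_noop(self):
        assert indel_proximity_filter([make_call(100)], [], 10).removed == set()

    def test_gap_distance_to_span(self):
        span = [IndelRecord("chr1", 110, 112)]
        assert keys(indel_proximity_filter([make_call(105)], span, 10)) == {105}  # gap 5
        assert keys(indel_proximity_filter([make_call(111)], span, 10)) == {111}  # inside
        assert indel_proximity_filter([make_call(99)], span, 10).removed == set()  # gap 11
        assert keys(indel_proximity_filter([make_call(122)], span, 10)) == {122}  # gap 10

    @pytest.mark.parametrize("ref_len", [2, 3, 5])
    def test_span_arithmetic_matches_per_base_expansion(self, ref_len):
        """[p, p+L-1] spans: brute-force every position near the span edge."""
        indel = IndelRecord("chr1", 500, 500 + ref_len - 1)
        for pos in range(480, 530):
            expected = (
                min(abs(pos - indel.start), abs(pos - indel.end)) <= 10
                or indel.start <= pos <= indel.end
            )
            removed = indel_proximity_filter([make_call(pos)], [indel], 10).removed
            assert bool(removed) is expected, pos

    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        calls = calls_from_keys(random_keys(rng, 40, pos_range=500))
        indels = [
            IndelRecord(f"chr{int(rng.integers(1, 3))}", start, start + int(rng.integers(0, 5)))
            for start in rng.integers(1, 500, size=8)
        ]
        window = int(rng.integers(0, 20))
        assert indel_proximity_filter(calls, indels, window).removed == (
            brute_force_indel_proximity(calls, indels, window)
        )


class TestDbsnpFilter:
    def test_empty_sites_is_noop(self):
        assert dbsnp_filter([make_call(100)], set()).removed == set()

    def test_exact_match_removed_in_both_modes(self):
        calls = [make_call(100, alt="G")]
        sites = {SiteKey("chr1", 100, "G")}
        for mode in ("position-only", "position+alt"):
            assert keys(dbsnp_filter(calls, sites, mode)) == {100}

    def test_alt_mismatch_split_by_mode(self):
        calls = [make_call(100, alt="T")]
        sites = {SiteKey("chr1", 100, "G")}
        assert keys(dbsnp_filter(calls, sites, "position-only")) == {100}
        assert dbsnp_filter(calls, sites, "position+alt").removed == set()

    def test_wildcard_site_matches_any_alt(self):
        calls = [make_call(100, alt="T")]
        sites = {SiteKey("chr1", 100)}
        assert keys(dbsnp_filter(calls, sites, "position+alt")) == {100}


class TestAltFractionFilter:
    def test_strictly_below_removes(self):
        low = make_call(1, depth_total=20, depth_alt=1)  # 5%
        boundary = make_call(2, depth_total=20, depth_alt=2)  # exactly 10%
        result = alt_fraction_filter([low, boundary], 0.10)
        assert keys(result) == {1}

    def test_zero_or_missing_depth_kept_and_counted(self):
        calls = [make_call(1, depth_total=0, depth_alt=0), make_call(2)]
        result = alt_fraction_filter(calls, 0.10)
        assert result.removed == set()
        assert result.n_missing_field == 2


class TestApplyFilters:
    def test_single_filter_equals_combined(self):
        calls = [make_call(p, status=SomaticStatus.LOH) for p in (1, 2)]
        config = FilterConfig(enabled_filters=["LOH"])
        results, combined = apply_filters(calls, config)
        assert len(results) == 1
        assert combined == results[0].removed

    def test_disjoint_removals_union(self):
        loh = [make_call(p, status=SomaticStatus.LOH, vaq=99.0) for p in (1, 2, 3)]
        low_vaq = [
            make_call(p, status=SomaticStatus.SOMATIC, vaq=5.0) for p in (100, 200, 300, 400)
        ]
        config = FilterConfig(enabled_filters=["LOH", "VAQ"], proximity_window_bp=10)
        results, combined = apply_filters(loh + low_vaq, config)
        assert len(combined) == 7

    def test_noop_filter_removes_nothing(self):
        calls = [make_call(p, status=SomaticStatus.SOMATIC) for p in (1, 200)]
        config = FilterConfig(enabled_filters=["LOH"])
        _, combined = apply_filters(calls, config)
        assert combined == set()

    def test_order_independence(self):
        rng = np.random.default_rng(1)
        calls = [
            make_call(
                int(pos),
                status=SomaticStatus.LOH if rng.random() < 0.3 else SomaticStatus.SOMATIC,
                vaq=float(rng.integers(0, 100)),
                depth_total=30,
                depth_alt=int(rng.integers(0, 10)),
            )
            for pos in rng.choice(2000, size=80, replace=False) + 1
        ]
        sites = {SiteKey("chr1", c.key.pos) for c in calls[:10]}
        indels = [IndelRecord("chr1", 500, 502)]
        forward = FilterConfig()
        backward = FilterConfig(enabled_filters=list(reversed(forward.enabled_filters)))
        res_f, comb_f = apply_filters(calls, forward, sites, indels)
        res_b, comb_b = apply_filters(calls, backward, sites, indels)
        assert comb_f == comb_b
        assert {r.filter_name: r.removed for r in res_f} == {
            r.filter_name: r.removed for r in res_b
        }

    @given(st.integers(0, 2**31 - 1))
    def test_every_filter_partitions_its_input(self, seed):
        rng = np.random.default_rng(seed)
        calls = [
            make_call(
                int(pos),
                status=SomaticStatus.LOH if rng.random() < 0.3 else SomaticStatus.SOMATIC,
                vaq=float(rng.integers(0, 120)),
                qual=float(rng.integers(0, 120)),
                ssc=float(rng.integers(0, 120)),
                depth_total=int(rng.integers(0, 40)),
                depth_alt=0,
            )
            for pos in rng.choice(3000, size=40, replace=False) + 1
        ]
        all_keys = {c.key for c in calls}
        sites = {SiteKey("chr1", c.key.pos) for c in calls[:5]}
        indels = [IndelRecord("chr1", 100, 104)]
        results, combined = apply_filters(calls, FilterConfig(), sites, indels)
        union_of_removed = set()
        for result in results:
            assert result.removed | result.kept == all_keys
            assert result.removed & result.kept == set()
            union_of_removed |= result.removed
        assert combined == union_of_removed

    def test_idempotent_on_kept_set(self):
        rng = np.random.default_rng(2)
        calls = [
            make_call(
                int(pos),
                status=SomaticStatus.LOH if rng.random() < 0.4 else SomaticStatus.SOMATIC,
                vaq=float(rng.integers(0, 100)),
            )
            for pos in rng.choice(1000, size=60, replace=False) + 1
        ]
        for run in (
            lambda c: loh_filter(c),
            lambda c: threshold_filter(c, "vaq", 40.0),
            lambda c: snv_proximity_filter(c, 10),
        ):
            first = run(calls)
            kept_calls = [c for c in calls if c.key in first.kept]
            assert run(kept_calls).removed == set()


def test_threshold_monotonicity_over_grid():
    """Raising a threshold never shrinks the removed set."""
    rng = np.random.default_rng(3)
    calls = [make_call(int(p), vaq=float(v)) for p, v in enumerate(rng.integers(0, 100, 50), 1)]
    previous: set = set()
    for threshold in (0, 10, 20, 40, 60, 80, 101):
        removed = threshold_filter(calls, "vaq", float(threshold)).removed
        assert previous <= removed
        previous = removed
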