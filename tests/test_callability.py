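import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crossvar.callability import (
    CallabilityThresholds, CallabilityTrack, State, build_track,
    callability_fraction, classify_base, export_regions, merge_tracks,
    noncallable_base_composition, rle_decode, rle_encode,
)
from crossvar.io_formats import DepthMQTrack, read_bed, write_bed

T = CallabilityThresholds()


def track(depth, mq=None, contig="c"):
    depth = np.asarray(depth, dtype=float)
    mq = np.full(len(depth), 60.0) if mq is None else np.asarray(mq, dtype=float)
    return DepthMQTrack({contig: depth}), DepthMQTrack({contig: mq})


class TestClassifyBase:
    @pytest.mark.parametrize("depth, mq, expected", [
        (0, 0, State.NO_COVERAGE),
        (3, 60, State.LOW_COVERAGE),
        (10, 5, State.POOR_MQ),
        (10, 60, State.CALLABLE),
        (4, 10, State.CALLABLE),      # both thresholds inclusive
        (4, 9.99, State.POOR_MQ),
        (2, 0, State.LOW_COVERAGE),   # coverage precedence over MQ
    ])
    def test_states(self, depth, mq, expected):
        assert classify_base(depth, mq, T) is expected

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            classify_base(-1, 60, T)

    def test_threshold_invariants(self):
        with pytest.raises(ValueError):
            CallabilityThresholds(min_depth=0)
        with pytest.raises(ValueError):
            CallabilityThresholds(min_mq=-1)


class TestBuildTrack:
    def test_uniform_single_run(self):
        d, m = track([10] * 100)
        t = build_track(d, m, T)
        assert t.runs["c"] == [(State.CALLABLE, 100)]

    def test_hand_rle(self):
        d, m = track([5, 5, 0, 0, 5])
        t = build_track(d, m, T)
        assert t.runs["c"] == [
            (State.CALLABLE, 2), (State.NO_COVERAGE, 2), (State.CALLABLE, 1),
        ]

    def test_span_mismatch_rejected(self):
        d, _ = track([5, 5])
        _, m = track([60, 60, 60])
        with pytest.raises(ValueError, match="spans differ"):
            build_track(d, m, T)

    @given(st.lists(st.integers(0, 3), min_size=0, max_size=300))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_rle_round_trip(self, states):
        vec = np.array(states, dtype=np.int8)
        assert np.array_equal(rle_decode(rle_encode(vec)), vec)

    def test_adjacent_runs_differ(self, sim_world):
        _, depth, mq, _ = sim_world["platforms"]["p1"]
        t = build_track(depth, mq, T)
        for runs in t.runs.values():
            states = [s for s, _ in runs]
            assert all(a != b for a, b in zip(states, states[1:]))


class TestCallabilityFraction:
    def test_all_callable(self):
        d, m = track([10] * 50)
        assert callability_fraction(build_track(d, m, T)) == 100.00

    def test_arithmetic(self):
        depth = np.full(10_000, 10.0)
        depth[:70] = 0
        d, m = track(depth)
        assert callability_fraction(build_track(d, m, T)) == 99.30

    def test_state_fractions_sum_to_100(self, sim_world):
        _, depth, mq, _ = sim_world["platforms"]["p1"]
        t = build_track(depth, mq, T)
        counts = t.state_counts()
        assert sum(counts.values()) == t.total_bases()
        total = sum(
            callability_fraction(t, [s]) or 0 for s in State
        )
        assert total == pytest.approx(100.0, abs=0.02)  # rounding only


class TestMergeTracks:
    def test_low_coverage_platforms_merge_callable(self):
        d1, m1 = track([2] * 10)
        d2, m2 = track([3] * 10)
        merged = merge_tracks(d1, m1, d2, m2, T)
        assert merged.runs["c"] == [(State.CALLABLE, 10)]

    def test_identity_under_zero_coverage(self):
        rng = np.random.default_rng(0)
        depth = rng.integers(0, 12, size=200)
        d1, m1 = track(depth)
        d2, m2 = track(np.zeros(200), np.zeros(200))
        merged = merge_tracks(d1, m1, d2, m2, T)
        assert merged.runs == build_track(d1, m1, T).runs

    def test_both_zero_no_coverage(self):
        d, m = track([0, 0])
        assert merge_tracks(d, m, d, m, T).runs["c"] == [(State.NO_COVERAGE, 2)]

    def test_merged_mq_is_depth_weighted(self):
        # one platform deep at MQ 60, the other shallow at MQ 0:
        # weighted mean stays above the threshold
        d1, m1 = track([9] * 5, [60] * 5)
        d2, m2 = track([1] * 5, [0] * 5)
        merged = merge_tracks(d1, m1, d2, m2, T)
        assert merged.runs["c"] == [(State.CALLABLE, 5)]

    def test_merged_callable_superset_on_simulated_data(self, sim_world):
        (_, d1, m1, _) = sim_world["platforms"]["p1"]
        (_, d2, m2, _) = sim_world["platforms"]["p2"]
        merged = merge_tracks(d1, m1, d2, m2, T)
        dec_m = merged.decode()
        for name in ("p1", "p2"):
            _, dd, mm, _ = sim_world["platforms"][name]
            single = build_track(dd, mm, T).decode()
            for contig in dec_m:
                callable_single = single[contig] == int(State.CALLABLE)
                callable_merged = dec_m[contig] == int(State.CALLABLE)
                assert np.all(callable_merged[callable_single])

    def test_merged_fraction_at_least_max_of_platforms(self, sim_world):
        (_, d1, m1, _) = sim_world["platforms"]["p1"]
        (_, d2, m2, _) = sim_world["platforms"]["p2"]
        f1 = callability_fraction(build_track(d1, m1, T))
        f2 = callability_fraction(build_track(d2, m2, T))
        fm = callability_fraction(merge_tracks(d1, m1, d2, m2, T))
        assert fm >= max(f1, f2)


class TestBaseComposition:
    def test_all_a_noncallable(self):
        d, m = track([0] * 10)
        comp = noncallable_base_composition(build_track(d, m, T), {"c": "A" * 10})
        assert comp["A"] == 1.0 and comp["C"] == 0.0

    def test_no_noncallable_is_na(self):
        d, m = track([10] * 10)
        assert noncallable_base_composition(
            build_track(d, m, T), {"c": "ACGT" * 3}
        ) is None

    def test_at_biased_dropout_enriches_at(self, sim_world):
        reference = sim_world["reference"]
        _, depth, mq, _ = sim_world["platforms"]["p1"]  # AT-biased platform
        comp = noncallable_base_composition(build_track(depth, mq, T), reference)
        genome = "".join(reference.values())
        genome_at = (genome.count("A") + genome.count("T")) / len(genome)
        assert comp["A"] + comp["T"] > genome_at


class TestExportRegions:
    def test_single_run_single_interval(self):
        d, m = track([10] * 100)
        regions = export_regions(build_track(d, m, T), State.CALLABLE)
        assert regions.intervals == [("c", 0, 100)]

    def test_interval_count_matches_run_count(self):
        d, m = track([5, 0, 5, 0, 5])
        t = build_track(d, m, T)
        regions = export_regions(t, State.CALLABLE)
        assert len(regions) == 3
        assert regions.total_length() == t.state_counts()[State.CALLABLE]

    def test_bed_round_trip_reproduces_fraction(self, tmp_path, sim_world):
        _, depth, mq, _ = sim_world["platforms"]["p2"]
        t = build_track(depth, mq, T)
        regions = export_regions(t, State.CALLABLE)
        path = tmp_path / "callable.bed"
        write_bed(regions, path)
        reread = read_bed(path)
        from crossvar.rounding import percentage
        assert percentage(reread.total_length(), t.total_bases()) \
            == callability_fraction(t)
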