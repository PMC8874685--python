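import numpy as np
import pytest

from oracles import best_subsequence, best_subsequence_naive
from sdatw.descriptors import DescriptorConfig, describe, distance_matrix
from sdatw.engine import (
    DetectedStride,
    _column_loop,
    _column_scan,
    flush,
    init_state,
    run_stream,
    star_pad,
    step,
    time_filter,
)
from sdatw.errors import ParameterError

ALL_KINDS = [
    "raw", "paa", "dwt", "slope", "derivative", "hog1d",
    "hog1d+raw", "hog1d+dwt", "hog1d+paa",
]


def small_config(kind: str) -> DescriptorConfig:
    return DescriptorConfig.from_name(
        kind, l=5, intervals=2, dwt_levels=2, hog_intervals=2, hog_bins=4
    )


class TestState:
    def test_init_boundary_column(self):
        st = init_state(200)
        assert st.D_col.shape == (201,)
        assert st.D_col[0] == 0.0
        assert np.all(np.isinf(st.D_col[1:]))
        assert np.all(st.s_col == 0)
        assert np.isinf(st.d_min)
        assert st.confirmed == []

    def test_star_pad_restores_init_column(self):
        st = init_state(10)
        rng = np.random.default_rng(0)
        for _ in range(7):
            step(st, rng.uniform(0.1, 1.0, 10))
        star_pad(st)
        fresh = init_state(10)
        np.testing.assert_array_equal(st.D_col, fresh.D_col)
        np.testing.assert_array_equal(st.s_col, fresh.s_col)
        assert np.isinf(st.d_min)

    def test_negative_distance_rejected(self):
        st = init_state(3)
        with pytest.raises(ParameterError):
            step(st, np.array([0.1, -0.2, 0.3]))

    def test_all_inf_column_leaves_candidate_untouched(self):
        st = init_state(4)
        rng = np.random.default_rng(1)
        for _ in range(6):
            step(st, rng.uniform(0.5, 1.0, 4))
        before = (st.d_min, st.cand_start, st.cand_end)
        step(st, np.full(4, np.inf))
        assert (st.d_min, st.cand_start, st.cand_end) == before or np.isinf(st.d_min)


class TestColumnUpdate:
    def test_scan_equals_loop_on_random_and_tied_costs(self):
        rng = np.random.default_rng(2)
        for trial in range(30):
            n = int(rng.integers(2, 12))
            D_prev = np.where(rng.random(n + 1) < 0.3, np.inf, rng.integers(0, 4, n + 1).astype(float))
            D_prev[0] = 0.0
            s_prev = rng.integers(0, 50, n + 1)
            dist = rng.integers(0, 3, n).astype(float)  # integer costs force ties
            t = int(rng.integers(0, 100))
            D1, s1 = _column_scan(dist, D_prev.copy(), s_prev.copy(), t)
            D2, s2 = _column_loop(dist, D_prev.copy(), s_prev.copy(), t)
            np.testing.assert_array_equal(D1, D2, err_msg=f"trial {trial}")
            np.testing.assert_array_equal(s1, s2, err_msg=f"trial {trial}")


class TestMatching:
    def test_perfect_template_occurrence_distance_zero(self):
        rng = np.random.default_rng(3)
        template = rng.normal(size=15)
        quiet = np.full(30, 50.0)
        stream = np.concatenate([quiet, template, quiet])
        cost = np.abs(stream[:, None] - template[None, :])
        strides, _ = run_stream(cost)
        best = min(strides, key=lambda s: s.distance)
        assert best.distance == pytest.approx(0.0, abs=1e-12)
        assert best.interval == (30, 45)

    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_streaming_equals_bruteforce_per_descriptor(self, kind):
        cfg = small_config(kind)
        rng = np.random.default_rng(hash(kind) % 2**31)
        q = np.cumsum(rng.normal(size=80))
        t = np.cumsum(rng.normal(size=20))
        cost = distance_matrix(describe(q, cfg), describe(t, cfg))
        strides, _ = run_stream(cost)
        best = min(strides, key=lambda s: s.distance)
        p, e, d = best_subsequence(cost)
        assert (best.start, best.end - 1) == (p, e)
        assert best.distance == pytest.approx(d, abs=1e-9)

    def test_vectorized_oracle_matches_naive(self):
        rng = np.random.default_rng(4)
        for _ in range(8):
            cost = rng.uniform(0.05, 2.0, size=(rng.integers(5, 13), rng.integers(2, 5)))
            assert best_subsequence(cost) == best_subsequence_naive(cost)

    def test_confirmed_strides_disjoint_and_ordered(self):
        rng = np.random.default_rng(5)
        for seed in range(5):
            cost = rng.uniform(0.0, 1.0, size=(400, 12))
            strides, _ = run_stream(cost)
            for a, b in zip(strides, strides[1:]):
                assert a.end <= b.start

    def test_flush_emits_pending_candidate(self):
        template = np.arange(10.0)
        stream = template.copy()  # ends exactly at the match end
        cost = np.abs(stream[:, None] - template[None, :])
        strides, _ = run_stream(cost)
        assert strides[-1].interval == (0, 10)
        assert strides[-1].distance == pytest.approx(0.0, abs=1e-12)

    def test_cell_update_counter_linear_in_stream_length(self):
        rng = np.random.default_rng(6)
        n = 50
        counts = []
        for m in (1000, 2000, 4000):
            _, state = run_stream(rng.uniform(0.1, 1.0, size=(m, n)))
            counts.append(state.cell_updates)
        assert counts[1] / counts[0] == pytest.approx(2.0)
        assert counts[2] / counts[1] == pytest.approx(2.0)


class TestTimeFilter:
    def test_duration_window(self):
        strides = [
            DetectedStride(0, 20, 1.0),  # 0.2 s
            DetectedStride(30, 130, 1.0),  # 1.0 s
            DetectedStride(200, 450, 1.0),  # 2.5 s
        ]
        kept = time_filter(strides, 100.0)
        assert [s.interval for s in kept] == [(30, 130)]

    def test_empty_input(self):
        assert time_filter([], 100.0) == []

    def test_boundary_durations_inclusive(self):
        strides = [DetectedStride(0, 25, 1.0), DetectedStride(100, 300, 1.0)]
        assert len(time_filter(strides, 100.0)) == 2


class TestSegmentPipeline:
    def test_five_template_copies_found_at_joins(self, stride_template, gyro_z_scheme):
        import sdatw

        spec = sdatw.WalkSpec(n_strides=5, seed=21, duration_sd_frac=0.0, stomps=1)
        rec, truth = sdatw.simulate_walk(spec)
        det = sdatw.segment(
            rec, stride_template, DescriptorConfig.from_name("dwt"), gyro_z_scheme
        )
        fs = rec.sample_rate
        hits = 0
        for a, b in truth.stride_intervals:
            if any(abs(d.start - a) <= 10 and abs(d.end - b) <= 10 for d in det):
                hits += 1
        assert hits == len(truth.stride_intervals)

    def test_pure_noise_stream_reports_without_crashing(self, stride_template, gyro_z_scheme):
        import sdatw
        from sdatw.imu_io import ImuRecording

        rng = np.random.default_rng(22)
        n = 2000
        rec = ImuRecording(
            acc=rng.normal(0, 1.0, (n, 3)) + [0, 9.81, 0],
            gyro=rng.normal(0, 1.0, (n, 3)),
            mag=np.full((n, 3), 0.3),
        )
        det = sdatw.segment(
            rec, stride_template, DescriptorConfig.from_name("dwt"), gyro_z_scheme
        )
        assert isinstance(det, list)
        for d in det:
            assert 0.25 <= d.duration <= 2.0
            assert np.isfinite(d.distance)

    def test_count_invariant_to_flat_prefix(self, stride_template, gyro_z_scheme):
        import sdatw
        from sdatw.imu_io import ImuRecording

        rec, _ = sdatw.simulate_walk(sdatw.WalkSpec(n_strides=12, seed=23))
        pad = 20  # 0.2 s of quiet standing
        rec2 = ImuRecording(
            acc=np.vstack([np.tile([0, 9.81, 0], (pad, 1)), rec.acc]),
            gyro=np.vstack([np.zeros((pad, 3)), rec.gyro]),
            mag=np.vstack([np.tile([0.42, 0.12, 0.21], (pad, 1)), rec.mag]),
        )
        cfg = DescriptorConfig.from_name("dwt")
        n1 = len(sdatw.segment(rec, stride_template, cfg, gyro_z_scheme))
        n2 = len(sdatw.segment(rec2, stride_template, cfg, gyro_z_scheme))
        assert n1 == n2
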