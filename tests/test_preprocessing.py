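"""Transform contracts: normalization, smoothing, differentiation,
projection, windowing, train-frozen scaling."""

import numpy as np
import pytest

from gaitlab.preprocessing import (
    WindowSpec,
    apply_scaler,
    differentiate,
    fit_scaler,
    height_normalize,
    project_coronal,
    smooth_moving_average,
    window_split,
)
from gaitlab.skeleton import JOINT_INDEX, N_JOINTS, SkeletonSequence
from gaitlab.synthetic_gait import GaitModelParams, generate_walk


def make_seq(positions, fps=24.0):
    n = positions.shape[0]
    return SkeletonSequence(timestamps=np.arange(n) / fps, positions=positions)


def walker_of_height(h, seed=1):
    p = GaitModelParams(subject_id=f"h{h}", gender="M", height=h, noise_sd=0.0,
                        stride_length=min(1.2, 0.6 * h))
    return generate_walk(p, 5.0, 24.0, seed=seed)


def extent(seq):
    head = seq.joint("head")[:, 1]
    feet = np.minimum(seq.joint("foot_l")[:, 1], seq.joint("foot_r")[:, 1])
    return float(np.median(head - feet))


class TestHeightNormalize:
    def test_unit_extent_and_centered_pelvis(self):
        seq = height_normalize(walker_of_height(2.0))
        assert extent(seq) == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(seq.joint("pelvis").mean(axis=0), 0.0, atol=1e-9)

    def test_removes_height_cue_between_walkers(self):
        tall = height_normalize(walker_of_height(2.0))
        short = height_normalize(walker_of_height(1.3))
        assert extent(tall) == pytest.approx(extent(short), abs=1e-9)

    def test_idempotent(self):
        once = height_normalize(walker_of_height(1.8))
        twice = height_normalize(once)
        assert np.allclose(once.positions, twice.positions, atol=1e-9)

    def test_preserves_sway_ratio(self):
        p = GaitModelParams(subject_id="r", gender="M", noise_sd=0.0,
                            shoulder_sway_amp=0.06, hip_sway_amp=0.03)
        raw = generate_walk(p, 8.0, 24.0, seed=2)
        norm = height_normalize(raw)

        def ratio(s):
            return np.std(s.joint("neck")[:, 0]) / np.std(s.joint("pelvis")[:, 0])

        assert ratio(norm) == pytest.approx(ratio(raw), rel=1e-9)

    def test_degenerate_skeleton_rejected(self):
        pos = np.zeros((10, N_JOINTS, 3))
        with pytest.raises(ValueError, match="degenerate"):
            height_normalize(make_seq(pos))


class TestSmoothing:
    def test_constant_signal_unchanged(self):
        pos = np.full((20, N_JOINTS, 3), 3.7)
        out = smooth_moving_average(make_seq(pos))
        assert np.allclose(out.positions, 3.7, atol=1e-12)

    def test_linear_ramp_unchanged_on_interior(self):
        ramp = np.arange(30, dtype=float)
        pos = np.tile(ramp[:, None, None], (1, N_JOINTS, 3))
        out = smooth_moving_average(make_seq(pos), window=5)
        assert np.allclose(out.positions[2:-2], pos[2:-2], atol=1e-9)

    def test_impulse_spreads_to_one_fifth(self):
        pos = np.zeros((21, N_JOINTS, 3))
        pos[10] = 1.0
        out = smooth_moving_average(make_seq(pos), window=5)
        assert np.allclose(out.positions[8:13, 0, 0], 0.2, atol=1e-12)
        assert np.allclose(out.positions[:8, 0, 0], 0.0, atol=1e-12)

    def test_bad_window(self):
        pos = np.zeros((10, N_JOINTS, 3))
        with pytest.raises(ValueError):
            smooth_moving_average(make_seq(pos), window=0)
        with pytest.raises(ValueError):
            smooth_moving_average(make_seq(pos[:3]), window=5)


class TestDifferentiate:
    def test_constant_positions_zero_velocity(self):
        out = differentiate(make_seq(np.full((10, N_JOINTS, 3), 2.0)))
        assert np.allclose(out.positions, 0.0, atol=1e-12)

    def test_linear_motion_constant_velocity(self):
        fps, v = 24.0, 0.37
        t = np.arange(48) / fps
        pos = np.zeros((48, N_JOINTS, 3))
        pos[..., 2] = (v * t)[:, None]
        out = differentiate(make_seq(pos, fps), fps)
        assert out.positions.shape == pos.shape  # length-preserving
        assert np.allclose(out.positions[..., 2], v, atol=1e-9)

    def test_sinusoid_amplitude_within_discretization_bound(self):
        fps, f, A = 24.0, 1.0, 0.05
        t = np.arange(240) / fps
        pos = np.zeros((240, N_JOINTS, 3))
        pos[..., 0] = (A * np.sin(2 * np.pi * f * t))[:, None]
        out = differentiate(make_seq(pos, fps), fps)
        vmax = np.max(np.abs(out.positions[..., 0]))
        expected = 2 * np.pi * f * A
        bound = expected * (2 * np.pi * f / fps) ** 2 / 6 + 1e-9
        assert abs(vmax - expected) <= bound + 0.02 * expected

    def test_differentiate_inverts_cumulative_sum(self):
        rng = np.random.default_rng(0)
        fps = 24.0
        v = rng.normal(size=(50, N_JOINTS, 3))
        pos = np.cumsum(v, axis=0) / fps
        out = differentiate(make_seq(pos, fps), fps)
        assert np.allclose(out.positions[1:-1], v[2:], atol=1e-9)

    def test_too_short(self):
        with pytest.raises(ValueError):
            differentiate(make_seq(np.zeros((1, N_JOINTS, 3))))


class TestProjection:
    def test_cardinality_40(self):
        arr = np.zeros((7, N_JOINTS, 3))
        out = project_coronal(arr)
        assert out.shape == (7, N_JOINTS, 2)
        assert out.reshape(7, -1).shape[1] == 40

    def test_idempotent_and_preserves_xy(self):
        rng = np.random.default_rng(1)
        arr = rng.normal(size=(5, N_JOINTS, 3))
        once = project_coronal(arr)
        assert np.array_equal(project_coronal(once), once)
        assert np.array_equal(once, arr[..., :2])


class TestWindowSplit:
    @pytest.mark.parametrize("k,expected", [(1, 144), (10, 14), (5, 28)])
    def test_nonoverlapping_counts(self, k, expected):
        arr = np.zeros((1440, N_JOINTS, 3))
        wins = window_split(arr, WindowSpec(k))
        assert len(wins) == expected
        assert all(w.shape[0] == 10 * k for w in wins)

    def test_short_sequence_yields_empty_with_warning(self):
        with pytest.warns(UserWarning, match="no windows"):
            wins = window_split(np.zeros((9, N_JOINTS, 3)), WindowSpec(1))
        assert wins == []

    def test_window_spec_bounds(self):
        with pytest.raises(ValueError):
            WindowSpec(0)
        with pytest.raises(ValueError):
            WindowSpec(11)
        assert WindowSpec(10).n_frames == 100
        assert WindowSpec(1).nominal_duration == pytest.approx(0.4)


class TestScaler:
    def test_fit_apply_postconditions(self):
        rng = np.random.default_rng(2)
        X = rng.normal(3.0, 2.0, size=(50, 6))
        stats = fit_scaler(X)
        out = apply_scaler(stats, X)
        assert np.allclose(out.min(axis=0), -1.0, atol=1e-12)
        assert np.allclose(out.max(axis=0), 1.0, atol=1e-12)
        # pre-minmax z-scores have mean 0 / sd 1 per column
        z = (X - stats.mean) / stats.sd
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(z.std(axis=0), 1.0, atol=1e-10)

    def test_constant_column_maps_to_zero(self):
        X = np.column_stack([np.arange(10.0), np.full(10, 4.2)])
        with pytest.warns(UserWarning, match="zero-variance"):
            stats = fit_scaler(X)
        out = apply_scaler(stats, X)
        assert np.allclose(out[:, 1], 0.0)

    def test_test_point_at_train_max_is_plus_one(self):
        X = np.arange(20.0)[:, None]
        stats = fit_scaler(X)
        assert apply_scaler(stats, np.array([[19.0]]))[0, 0] == pytest.approx(1.0)
        # out-of-range test values are not clipped
        assert apply_scaler(stats, np.array([[40.0]]))[0, 0] > 1.0

    def test_zscore_only_mode(self):
        rng = np.random.default_rng(3)
        X = rng.normal(5, 3, size=(40, 4))
        stats = fit_scaler(X, minmax=False)
        out = apply_scaler(stats, X)
        assert np.allclose(out.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(out.std(axis=0), 1.0, atol=1e-10)

    def test_scaled_training_data_always_within_unit_box(self):
        import warnings

        from hypothesis import given, settings
        from hypothesis import strategies as st
        from hypothesis.extra import numpy as hnp

        @settings(deadline=None, derandomize=True, max_examples=30)
        @given(
            hnp.arrays(
                np.float64,
                st.tuples(st.integers(2, 15), st.integers(1, 6)),
                elements=st.floats(-1e6, 1e6, allow_nan=False),
            )
        )
        def check(X):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out = apply_scaler(fit_scaler(X), X)
            assert np.all(out >= -1.0 - 1e-9) and np.all(out <= 1.0 + 1e-9)

        check()

    def test_stats_frozen_from_training_split_only(self):
        rng = np.random.default_rng(4)
        train, test_a, test_b = (rng.normal(size=(30, 5)) for _ in range(3))
        stats = fit_scaler(train)
        out_a = apply_scaler(stats, test_a)
        stats2 = fit_scaler(train)  # refit; test data can never influence it
        assert np.array_equal(stats.mean, stats2.mean)
        assert np.array_equal(apply_scaler(stats2, test_a), out_a)
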