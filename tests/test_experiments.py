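"""Sweep harness: subject-wise folds, dataset assembly, stimulus clips."""

import numpy as np
import pytest

from gaitlab.experiments import (
    DisplayConfig,
    build_dataset,
    duration_sweep,
    make_stimulus_clip,
    run_experiment,
    subject_kfold,
)
from gaitlab.models import LstmHyperParams
from gaitlab.preprocessing import WindowSpec, height_normalize


def subject_pairs(n_m, n_f):
    return [(f"S{i:02d}", "M" if i < n_m else "F") for i in range(n_m + n_f)]


class TestSubjectKfold:
    def test_study_cohort_fold_sizes(self):
        folds = subject_kfold(subject_pairs(26, 15), k=10, seed=0)
        sizes = sorted(len(test) for _, test in folds)
        assert sizes == [4] * 9 + [5]

    def test_partition_properties(self):
        folds = subject_kfold(subject_pairs(26, 15), k=10, seed=1)
        all_test = [s for _, test in folds for s in test]
        assert len(all_test) == len(set(all_test)) == 41
        for train, test in folds:
            assert set(train).isdisjoint(test)
            assert set(train) | set(test) == set(s for s, _ in subject_pairs(26, 15))

    def test_gender_stratified(self):
        pairs = dict(subject_pairs(26, 15))
        folds = subject_kfold(list(pairs.items()), k=10, seed=2)
        for _, test in folds:
            genders = {pairs[s] for s in test}
            assert genders == {"M", "F"}

    def test_deterministic_given_seed(self):
        a = subject_kfold(subject_pairs(8, 8), k=4, seed=5)
        b = subject_kfold(subject_pairs(8, 8), k=4, seed=5)
        assert a == b

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            subject_kfold(subject_pairs(2, 2), k=10)


class TestBuildDataset:
    def test_representation_cardinalities(self, dyn_sessions):
        sessions = dyn_sessions[:2]
        spec = WindowSpec(2)
        X3, y, _ = build_dataset(sessions, "position3d", spec)
        assert X3.shape[1:] == (20, 60)
        X2, _, _ = build_dataset(sessions, "position2d", spec)
        assert X2.shape[1:] == (20, 40)
        Xs, _, _ = build_dataset(sessions, "static4", spec)
        assert Xs.shape[1] == 240
        Xv, _, _ = build_dataset(sessions, "static4_velocity", spec)
        assert Xv.shape[1] == 240
        Xc, yc, _ = build_dataset(sessions, "clinical")
        assert Xc.shape == (2, 12)

    def test_labels_follow_session_gender(self, dyn_sessions):
        sessions = dyn_sessions[:4]
        _, y, sids = build_dataset(sessions, "static4", WindowSpec(5))
        by_sid = {s: g for _, g, s in sessions}
        for label, sid in zip(y, sids):
            assert label == (1 if by_sid[sid] == "M" else 0)

    def test_features_independent_of_labels(self, dyn_sessions):
        # permuting gender labels must not change the feature matrix
        sessions = dyn_sessions[:4]
        flipped = [(seq, "F" if g == "M" else "M", sid) for seq, g, sid in sessions]
        Xa, _, _ = build_dataset(sessions, "static4", WindowSpec(3))
        Xb, _, _ = build_dataset(flipped, "static4", WindowSpec(3))
        assert np.array_equal(Xa, Xb)

    def test_unknown_representation(self, dyn_sessions):
        with pytest.raises(ValueError):
            build_dataset(dyn_sessions[:1], "wavelet")


class TestSweepHarness:
    def test_sweep_result_schema_and_accuracy_arithmetic(self, dyn_sessions):
        df = duration_sweep(
            dyn_sessions, "svm_linear", "static4", ks=[1, 5],
            n_replicates=2, n_folds=3, seed=3,
        )
        assert set(df["window_k"]) == {1, 5}
        assert set(df["replicate"]) == {0, 1}
        assert np.allclose(df["accuracy"], df["n_correct"] / df["n_test"])
        assert (df["n_test"] > 0).all()

    def test_2d_experiment_records_cardinality_40(self, dyn_sessions):
        hp = LstmHyperParams(hidden_size=4, epochs=1, seed=0)
        mixed = dyn_sessions[:9] + dyn_sessions[30:39]  # 3 M + 3 F subjects
        df = run_experiment(
            5, mixed, ks=[1], n_replicates=1, n_folds=2, seed=1, lstm_hp=hp,
        )
        assert set(df["representation"]) == {"position2d", "velocity2d"}
        X, _, _ = build_dataset(dyn_sessions[:2], "position2d", WindowSpec(1))
        assert X.shape[2] == 40

    def test_unknown_experiment_id(self, dyn_sessions):
        with pytest.raises(ValueError):
            run_experiment(7, dyn_sessions)

    def test_deterministic_given_master_seed(self, dyn_sessions):
        kw = dict(ks=[2], n_replicates=1, n_folds=2, seed=9)
        a = duration_sweep(dyn_sessions, "rdf", "static4", **kw)
        b = duration_sweep(dyn_sessions, "rdf", "static4", **kw)
        assert a.equals(b)


class TestStimulusClip:
    def test_dot_count_and_radius(self, walk_10s):
        clip = make_stimulus_clip(height_normalize(walk_10s))
        assert clip.dots.shape[1:] == (20, 2)
        assert clip.dot_radius_px == 5
        assert clip.canvas == (1920, 1080)

    def test_exposure_duration_frame_count(self, walk_10s):
        clip = make_stimulus_clip(walk_10s, duration=3.8)
        assert clip.n_frames == 91  # round(3.8 × 24)

    def test_dots_within_canvas(self, walk_10s):
        clip = make_stimulus_clip(walk_10s)
        assert (clip.dots[..., 0] >= 0).all() and (clip.dots[..., 0] < 1920).all()
        assert (clip.dots[..., 1] >= 0).all() and (clip.dots[..., 1] < 1080).all()

    def test_psychophysics_mode_restricts_durations(self, walk_10s):
        for d in (0.4, 1.5, 2.5, 3.8):
            clip = make_stimulus_clip(walk_10s, duration=d, psychophysics_mode=True)
            assert clip.n_frames == round(d * 24)
        with pytest.raises(ValueError):
            make_stimulus_clip(walk_10s, duration=2.0, psychophysics_mode=True)

    def test_clip_table_export(self, walk_10s):
        clip = make_stimulus_clip(walk_10s, duration=0.4)
        table = clip.to_table()
        assert len(table) == clip.n_frames * 20
        assert list(table.columns) == ["frame", "joint", "x_px", "y_px"]
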