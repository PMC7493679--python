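"""Classifier contracts: LSTM gate arithmetic, determinism, persistence,
order sensitivity, and the static-model kernel behaviors."""

import numpy as np
import pytest

from gaitlab.features import static_summary
from gaitlab.models import (
    LSTMClassifier,
    LstmHyperParams,
    StaticModelSpec,
    TrainedModel,
    train_lstm,
    train_static,
)


def separable_sequences(n_per_class=20, t=10, d=6, seed=0):
    rng = np.random.default_rng(seed)
    X = np.concatenate(
        [np.full((n_per_class, t, d), -1.0), np.full((n_per_class, t, d), 1.0)]
    )
    X += rng.normal(0, 0.1, X.shape)
    y = np.array([0] * n_per_class + [1] * n_per_class)
    return X, y


class TestLstm:
    def test_gate_parameter_count_closed_form(self):
        # 4 gates × (H×(D+H) weights + H biases), head 2H + 2
        clf = LSTMClassifier(60, LstmHyperParams(hidden_size=128))
        assert clf.n_recurrent_params == 4 * (128 * (60 + 128) + 128) == 96768
        assert clf.n_head_params == 2 * 128 + 2

    def test_default_hyperparameters(self):
        hp = LstmHyperParams()
        assert hp.hidden_size == 128
        assert hp.learning_rate == pytest.approx(1e-3)
        assert hp.batch_size == 50
        assert hp.epochs == 100

    def test_learns_separable_classes_and_loss_decreases(self):
        X, y = separable_sequences()
        m = train_lstm(X, y, LstmHyperParams(hidden_size=16, epochs=40, seed=1))
        labels, probs = m.predict(X)
        assert (labels == y).mean() == 1.0
        assert m.model.loss_history[-1] < m.model.loss_history[0]

    def test_probabilities_sum_to_one_and_argmax(self):
        X, y = separable_sequences(seed=2)
        m = train_lstm(X, y, LstmHyperParams(hidden_size=8, epochs=5, seed=2))
        labels, probs = m.predict(X)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.array_equal(labels, np.argmax(probs, axis=1))

    def test_seed_determinism(self):
        X, y = separable_sequences(seed=3)
        hp = LstmHyperParams(hidden_size=8, epochs=5, seed=7)
        a = train_lstm(X, y, hp)
        b = train_lstm(X, y, hp)
        _, pa = a.predict(X)
        _, pb = b.predict(X)
        assert np.array_equal(pa, pb)

    def test_save_load_round_trip_bit_exact(self, tmp_path):
        X, y = separable_sequences(seed=4)
        m = train_lstm(X, y, LstmHyperParams(hidden_size=8, epochs=3, seed=4))
        _, before = m.predict(X)
        m.save(tmp_path / "model")
        back = TrainedModel.load(tmp_path / "model")
        _, after = back.predict(X)
        assert np.array_equal(before, after)

    def test_shape_mismatch_contract_error(self):
        X, y = separable_sequences(t=10, d=6, seed=5)
        m = train_lstm(X, y, LstmHyperParams(hidden_size=8, epochs=2, seed=5))
        with pytest.raises(ValueError, match="manifest"):
            m.predict(np.zeros((2, 12, 6)))
        with pytest.raises(ValueError):
            m.predict(np.zeros((2, 10, 7)))

    def test_ragged_windows_rejected(self):
        ragged = [np.zeros((10, 6)), np.zeros((12, 6))]
        with pytest.raises(ValueError, match="ragged|rectangular"):
            train_lstm(ragged, [0, 1])

    def test_frame_order_sensitivity_contrast(self):
        # shuffling frames changes LSTM logits but never the 4-stat features
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 20, 6)).cumsum(axis=1)  # temporally structured
        y = rng.integers(0, 2, 30)
        m = train_lstm(X, y, LstmHyperParams(hidden_size=8, epochs=3, seed=6))
        changed = 0
        for w in X:
            perm = rng.permutation(len(w))
            if np.any(perm != np.arange(len(w))):
                _, p0 = m.predict(w)
                _, p1 = m.predict(w[perm])
                changed += not np.allclose(p0, p1, atol=1e-12)
                assert np.allclose(
                    static_summary(w), static_summary(w[perm]), atol=1e-12
                )
        assert changed >= 28  # order matters for essentially every window


class TestStaticModels:
    def test_linear_svm_separates_blobs(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-2, 0.3, (30, 2)), rng.normal(2, 0.3, (30, 2))])
        y = np.array([0] * 30 + [1] * 30)
        m = train_static(X, y, StaticModelSpec(family="svm_linear"))
        labels, _ = m.predict(X)
        assert (labels == y).mean() == 1.0

    def test_xor_kernel_contrast(self):
        rng = np.random.default_rng(1)
        centers = np.array([[-2, -2], [2, 2], [-2, 2], [2, -2]], dtype=float)
        Xtr = np.vstack([rng.normal(c, 0.3, (40, 2)) for c in centers])
        ytr = np.array([0] * 80 + [1] * 80)
        Xte = np.vstack([rng.normal(c, 0.3, (20, 2)) for c in centers])
        yte = np.array([0] * 40 + [1] * 40)
        lin = train_static(Xtr, ytr, StaticModelSpec(family="svm_linear"))
        rbf = train_static(Xtr, ytr, StaticModelSpec(family="svm_rbf"))
        acc_lin = (lin.predict(Xte)[0] == yte).mean()
        acc_rbf = (rbf.predict(Xte)[0] == yte).mean()
        assert acc_lin <= 0.8  # near chance; a line cannot solve XOR
        assert acc_rbf > 0.9
        assert acc_rbf > acc_lin

    def test_rdf_is_majority_vote_of_ten_trees(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 5))
        y = (X[:, 0] + 0.3 * rng.normal(size=60) > 0).astype(int)
        m = train_static(X, y, StaticModelSpec(family="rdf", seed=3))
        forest = m.model
        assert len(forest.estimators_) == 10
        from gaitlab.preprocessing import apply_scaler

        Xs = apply_scaler(m.scaler, X)
        votes = np.stack([t.predict(Xs) for t in forest.estimators_])
        majority = (votes.mean(axis=0) > 0.5).astype(int)
        labels, _ = m.predict(X)
        ties = votes.mean(axis=0) == 0.5
        assert np.array_equal(labels[~ties], majority[~ties])

    def test_default_static_specs(self):
        spec = StaticModelSpec(family="svm_rbf")
        assert spec.svm_rbf_gamma == pytest.approx(0.99)
        spec = StaticModelSpec(family="rdf")
        assert (spec.rdf_n_trees, spec.rdf_min_samples_split,
                spec.rdf_max_features) == (10, 2, 3)
        with pytest.raises(ValueError):
            StaticModelSpec(family="mlp")

    def test_single_class_labels_rejected(self):
        X = np.random.default_rng(3).normal(size=(10, 3))
        with pytest.raises(ValueError, match="single class"):
            train_static(X, np.zeros(10, dtype=int))

    def test_static_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 4))
        y = (X[:, 0] > 0).astype(int)
        m = train_static(X, y, StaticModelSpec(family="svm_rbf"))
        _, before = m.predict(X)
        m.save(tmp_path / "svm")
        back = TrainedModel.load(tmp_path / "svm")
        _, after = back.predict(X)
        assert np.array_equal(before, after)
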