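"""Classifier families: a biomimetic LSTM sequence classifier and the
non-biomimetic static learners (SVM kernels, random decision forest).

The LSTM is implemented directly in numpy — a standard single-layer gated
cell (input/forget/output gates, tanh candidate), trained by backpropagation
through time with Adam on a softmax cross-entropy head. The final hidden
state is ReLU-activated and fed to an affine layer producing two logits.
Defaults follow the reference training regime: 128 hidden units, learning
rate 1e-3, mini-batches of 50, 100 epochs, zero-mean Gaussian weight
initialization (SD 0.1), forget-gate bias initialized to +1.

The static models wrap scikit-learn: SVMs with linear / RBF (gamma 0.99) /
sigmoid kernels, and a 10-tree entropy-criterion forest with
``min_samples_split=2`` and at most 3 features considered per split,
majority-vote prediction.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

__all__ = [
    "LstmHyperParams",
    "StaticModelSpec",
    "LSTMClassifier",
    "TrainedModel",
    "train_lstm",
    "train_static",
    "predict",
    "STATIC_FAMILIES",
]

STATIC_FAMILIES = ("svm_linear", "svm_rbf", "svm_sigmoid", "rdf")


@dataclass
class LstmHyperParams:
    hidden_size: int = 128
    learning_rate: float = 1e-3
    batch_size: int = 50
    epochs: int = 100
    weight_init_sd: float = 0.1
    grad_clip: float = 5.0
    seed: int = 0


@dataclass
class StaticModelSpec:
    family: str = "svm_linear"
    svm_c: float = 1.0
    svm_rbf_gamma: float = 0.99
    rdf_n_trees: int = 10
    rdf_min_samples_split: int = 2
    rdf_max_features: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.family not in STATIC_FAMILIES:
            raise ValueError(f"unknown static family {self.family!r}")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class LSTMClassifier:
    """Single-layer LSTM → ReLU → affine → 2-logit softmax classifier."""

    def __init__(self, input_dim: int, hp: LstmHyperParams | None = None):
        self.hp = hp or LstmHyperParams()
        self.input_dim = int(input_dim)
        H, D = self.hp.hidden_size, self.input_dim
        rng = np.random.default_rng(self.hp.seed)
        sd = self.hp.weight_init_sd
        # gate order along the 4H axis: input, forget, candidate, output
        self.Wx = rng.normal(0, sd, (D, 4 * H)).astype(np.float32)
        self.Wh = rng.normal(0, sd, (H, 4 * H)).astype(np.float32)
        self.b = np.zeros(4 * H, dtype=np.float32)
        self.b[H : 2 * H] = 1.0  # forget-gate bias
        self.Wo = rng.normal(0, sd, (H, 2)).astype(np.float32)
        self.bo = np.zeros(2, dtype=np.float32)
        self._rng = rng
        self.loss_history: list[float] = []
        self._adam_state = None

    # -- parameter bookkeeping -------------------------------------------
    @property
    def n_recurrent_params(self) -> int:
        """Gate parameters: 4*(H*(D+H) + H)."""
        return self.Wx.size + self.Wh.size + self.b.size

    @property
    def n_head_params(self) -> int:
        return self.Wo.size + self.bo.size

    def _params(self):
        return [self.Wx, self.Wh, self.b, self.Wo, self.bo]

    # -- forward / backward ----------------------------------------------
    def _forward(self, X, keep_cache=False):
        B, T, D = X.shape
        H = self.hp.hidden_size
        h = np.zeros((B, H), dtype=np.float32)
        c = np.zeros((B, H), dtype=np.float32)
        cache = []
        for t in range(T):
            z = X[:, t] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            if keep_cache:
                cache.append((i, f, g, o, c_prev, tc, h_prev))
        r = np.maximum(h, 0.0)
        logits = r @ self.Wo + self.bo
        return logits, h, r, cache

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = self._check_input(X)
        logits, _, _, _ = self._forward(X)
        return _softmax(logits.astype(np.float64))

    def _check_input(self, X):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2:
            X = X[None]
        if X.ndim != 3 or X.shape[2] != self.input_dim:
            raise ValueError(
                f"expected windows of shape (n, T, {self.input_dim}), got {X.shape}"
            )
        return X

    def _backward(self, X, y, logits, h, r, cache):
        B, T, D = X.shape
        H = self.hp.hidden_size
        p = _softmax(logits)
        loss = -np.mean(np.log(p[np.arange(B), y] + 1e-12))
        dlogits = p.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        dWo = r.T @ dlogits
        dbo = dlogits.sum(axis=0)
        dh = ((dlogits @ self.Wo.T) * (h > 0)).astype(np.float32)
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dc = np.zeros_like(dh)
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, tc, h_prev = cache[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g * g),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            dWx += X[:, t].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dh = (dz @ self.Wh.T).astype(np.float32)
            dc = dc * f
        grads = [dWx, dWh, db, dWo.astype(np.float32), dbo.astype(np.float32)]
        norm = np.sqrt(sum(float((g * g).sum()) for g in grads))
        if norm > self.hp.grad_clip:
            grads = [g * (self.hp.grad_clip / norm) for g in grads]
        return loss, grads

    def _adam_step(self, grads):
        if self._adam_state is None:
            self._adam_state = {
                "m": [np.zeros_like(p) for p in self._params()],
                "v": [np.zeros_like(p) for p in self._params()],
                "t": 0,
            }
        st = self._adam_state
        st["t"] += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        lr = self.hp.learning_rate
        for p, g, m, v in zip(self._params(), grads, st["m"], st["v"]):
            m[:] = b1 * m + (1 - b1) * g
            v[:] = b2 * v + (1 - b2) * g * g
            mh = m / (1 - b1 ** st["t"])
            vh = v / (1 - b2 ** st["t"])
            p -= (lr * mh / (np.sqrt(vh) + eps)).astype(np.float32)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LSTMClassifier":
        X = self._check_input(X)
        y = np.asarray(y, dtype=int)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        n = len(X)
        for _ in range(self.hp.epochs):
            order = self._rng.permutation(n)
            losses = []
            for s in range(0, n, self.hp.batch_size):
                idx = order[s : s + self.hp.batch_size]
                logits, h, r, cache = self._forward(X[idx], keep_cache=True)
                loss, grads = self._backward(X[idx], y[idx], logits, h, r, cache)
                self._adam_step(grads)
                losses.append(loss)
            self.loss_history.append(float(np.mean(losses)))
        return self

    # -- persistence ------------------------------------------------------
    def state_dict(self) -> dict:
        return {
            "Wx": self.Wx, "Wh": self.Wh, "b": self.b,
            "Wo": self.Wo, "bo": self.bo,
        }

    def load_state_dict(self, state: dict) -> None:
        for k, v in state.items():
            setattr(self, k, np.asarray(v, dtype=np.float32))


@dataclass
class TrainedModel:
    """A fitted classifier plus the preprocessing state frozen at training.

    ``scaler`` is a :class:`gaitlab.preprocessing.ScalerStats` (or None);
    ``manifest`` records family, representation, window spec, fold and
    replicate ids, seed, and the expected input shape. Prediction is a
    deterministic function of (model, input).
    """

    family: str
    model: object
    scaler: object = None
    manifest: dict = field(default_factory=dict)

    def predict(self, x: np.ndarray):
        """Return ``(labels, probabilities)`` for one or more inputs."""
        from .preprocessing import apply_scaler

        x = np.asarray(x, dtype=float)
        if self.family == "lstm":
            expect = self.manifest.get("input_shape")
            if x.ndim == 2:
                x = x[None]
            if expect and tuple(x.shape[1:]) != tuple(expect):
                raise ValueError(
                    f"window shape {x.shape[1:]} does not match training "
                    f"manifest {tuple(expect)}"
                )
            if self.scaler is not None:
                flat = apply_scaler(self.scaler, x.reshape(-1, x.shape[-1]))
                x = flat.reshape(x.shape)
            probs = self.model.predict_proba(x)
        else:
            if x.ndim == 1:
                x = x[None]
            expect = self.manifest.get("input_shape")
            if expect and x.shape[1] != expect[0]:
                raise ValueError(
                    f"feature vector of length {x.shape[1]} does not match "
                    f"training manifest {expect[0]}"
                )
            if self.scaler is not None:
                x = apply_scaler(self.scaler, x)
            if hasattr(self.model, "predict_proba"):
                probs = self.model.predict_proba(x)
            else:
                # margin → pseudo-probability via the logistic link
                d = self.model.decision_function(x)
                p1 = _sigmoid(d)
                probs = np.column_stack([1 - p1, p1])
        labels = np.argmax(probs, axis=1)
        return labels, probs

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        (path / "manifest.json").write_text(
            json.dumps({"family": self.family, **self.manifest}, default=str)
        )
        if self.family == "lstm":
            np.savez(path / "params.npz", **self.model.state_dict())
            (path / "hp.json").write_text(json.dumps(asdict(self.model.hp)))
        else:
            (path / "params.pkl").write_bytes(pickle.dumps(self.model))
        if self.scaler is not None:
            np.savez(
                path / "scaler.npz",
                mean=self.scaler.mean, sd=self.scaler.sd,
                zmin=self.scaler.zmin, zmax=self.scaler.zmax,
                constant_mask=self.scaler.constant_mask,
            )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        from .preprocessing import ScalerStats

        path = Path(path)
        meta = json.loads((path / "manifest.json").read_text())
        family = meta.pop("family")
        scaler = None
        if (path / "scaler.npz").exists():
            z = np.load(path / "scaler.npz")
            scaler = ScalerStats(
                mean=z["mean"], sd=z["sd"], zmin=z["zmin"], zmax=z["zmax"],
                constant_mask=z["constant_mask"],
            )
        if family == "lstm":
            hp = LstmHyperParams(**json.loads((path / "hp.json").read_text()))
            model = LSTMClassifier(int(meta["input_shape"][1]), hp)
            model.load_state_dict(dict(np.load(path / "params.npz")))
        else:
            model = pickle.loads((path / "params.pkl").read_bytes())
        return cls(family=family, model=model, scaler=scaler, manifest=meta)


def train_lstm(
    windows: np.ndarray,
    labels: np.ndarray,
    hp: LstmHyperParams | None = None,
    *,
    standardize: bool = True,
    manifest: dict | None = None,
) -> TrainedModel:
    """Fit the LSTM on ``(n, T, D)`` windows with binary labels.

    Per-coordinate standardization statistics (z-score, no range
    compression for sequence inputs) are frozen from the training windows
    and stored with the model. Raises on ragged/malformed window stacks.
    """
    from .preprocessing import apply_scaler, fit_scaler

    try:
        X = np.asarray(windows, dtype=float)
    except ValueError as exc:
        raise ValueError(
            "ragged window lengths are not a valid dataset"
        ) from exc
    if X.ndim != 3:
        raise ValueError(
            "expected a rectangular (n_windows, n_frames, D) stack; "
            "ragged window lengths are not a valid dataset"
        )
    y = np.asarray(labels, dtype=int)
    hp = hp or LstmHyperParams()
    scaler = None
    if standardize:
        scaler = fit_scaler(X.reshape(-1, X.shape[-1]), minmax=False)
        X = apply_scaler(scaler, X.reshape(-1, X.shape[-1])).reshape(X.shape)
    clf = LSTMClassifier(input_dim=X.shape[-1], hp=hp)
    clf.fit(X, y)
    man = {"input_shape": list(X.shape[1:]), **(manifest or {})}
    return TrainedModel(family="lstm", model=clf, scaler=scaler, manifest=man)


def _build_static(spec: StaticModelSpec):
    if spec.family == "svm_linear":
        return SVC(kernel="linear", C=spec.svm_c)
    if spec.family == "svm_rbf":
        return SVC(kernel="rbf", C=spec.svm_c, gamma=spec.svm_rbf_gamma)
    if spec.family == "svm_sigmoid":
        return SVC(kernel="sigmoid", C=spec.svm_c)
    return RandomForestClassifier(
        n_estimators=spec.rdf_n_trees,
        criterion="entropy",
        min_samples_split=spec.rdf_min_samples_split,
        max_features=spec.rdf_max_features,
        random_state=spec.seed,
    )


def train_static(
    features: np.ndarray,
    labels: np.ndarray,
    spec: StaticModelSpec | None = None,
    *,
    standardize: bool = True,
    manifest: dict | None = None,
) -> TrainedModel:
    """Fit an SVM or random-forest model on an ``(n, F)`` feature table.

    Features are z-scored then min-max compressed to [-1, 1] with training
    statistics frozen into the returned model. Raises if the training
    labels contain a single class.
    """
    from .preprocessing import apply_scaler, fit_scaler

    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or not np.all(np.isfinite(X)):
        raise ValueError("features must be a finite (n_samples, n_features) table")
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    spec = spec or StaticModelSpec()
    scaler = None
    if standardize:
        scaler = fit_scaler(X)
        X = apply_scaler(scaler, X)
    model = _build_static(spec).fit(X, y)
    man = {"input_shape": [X.shape[1]], **(manifest or {})}
    return TrainedModel(family=spec.family, model=model, scaler=scaler, manifest=man)


def predict(model: TrainedModel, x: np.ndarray):
    """Functional alias for :meth:`TrainedModel.predict`."""
    return model.predict(x)
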