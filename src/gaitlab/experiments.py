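"""Sweep orchestration: subject-wise cross-validation, duration sweeps over
model families × representations, and point-light stimulus-clip export.

Representations
---------------
``position3d``
    Height-normalized joint positions, 60 numbers per frame.
``velocity3d``
    5-frame moving-average smoothing, then adjacent-frame differences.
``position2d`` / ``velocity2d``
    Same with the anterior-posterior axis dropped (40 per frame).
``static4`` / ``static4_velocity``
    Four first-order statistics per dimension of the position (or velocity)
    window — the order-free representation fed to the static models.
``clinical``
    The 12 spatiotemporal gait metrics, one vector per session (gait events
    need full sessions, so this representation does not window).

Cross-validation always partitions subjects, never sessions or windows, so
no walker's data appears on both sides of a split.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .features import clinical_metrics, detect_gait_events, metrics_vector, static_summary
from .models import (
    LstmHyperParams,
    StaticModelSpec,
    train_lstm,
    train_static,
)
from .preprocessing import (
    WindowSpec,
    differentiate,
    height_normalize,
    project_coronal,
    smooth_moving_average,
    window_split,
)
from .skeleton import SkeletonSequence

__all__ = [
    "REPRESENTATIONS",
    "LABELS",
    "subject_kfold",
    "build_dataset",
    "duration_sweep",
    "run_experiment",
    "make_stimulus_clip",
    "DisplayConfig",
    "StimulusClip",
]

REPRESENTATIONS = (
    "position3d",
    "velocity3d",
    "position2d",
    "velocity2d",
    "static4",
    "static4_velocity",
    "clinical",
)

#: Binary label coding used throughout: F → 0, M → 1.
LABELS = {"F": 0, "M": 1}


def _cell_seed(master: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % (2**31))


def subject_kfold(dataset, k: int = 10, seed: int = 0):
    """Gender-stratified k-fold partition of SUBJECTS.

    ``dataset`` is a list of ``(SkeletonSequence, gender, subject_id)``
    tuples (or ``(subject_id, gender)`` pairs). Returns a list of
    ``(train_subject_ids, test_subject_ids)``; test folds are pairwise
    disjoint and cover all subjects. Deterministic given ``seed``.
    """
    subj_gender: dict[str, str] = {}
    for item in dataset:
        if isinstance(item[0], SkeletonSequence):
            _, gender, sid = item
        else:
            sid, gender = item
        subj_gender[str(sid)] = str(gender)
    subjects = sorted(subj_gender)
    if len(subjects) < k:
        raise ValueError(f"{len(subjects)} subjects cannot fill {k} folds")
    y = [subj_gender[s] for s in subjects]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    folds = []
    subjects_arr = np.array(subjects)
    for train_idx, test_idx in skf.split(subjects_arr, y):
        folds.append((list(subjects_arr[train_idx]), list(subjects_arr[test_idx])))
    return folds


def _sequence_windows(seq: SkeletonSequence, representation: str,
                      spec: WindowSpec, stride: int | None = None):
    s = height_normalize(seq)
    if "velocity" in representation:
        s = differentiate(smooth_moving_average(s, 5))
    arr = s.positions
    if representation.endswith("2d"):
        arr = project_coronal(arr)
    wins = window_split(arr, spec, stride)
    return [w.reshape(w.shape[0], -1) for w in wins]


def build_dataset(sessions, representation: str, spec: WindowSpec | None = None,
                  stride: int | None = None, windows_per_session: int | None = None):
    """Assemble ``(X, y, subject_ids)`` for one representation.

    Sequence representations yield ``X`` of shape ``(n_windows, n_frames,
    D)``; ``static4`` variants a ``(n_windows, 4*D)`` table; ``clinical`` a
    ``(n_sessions, 12)`` table. ``subject_ids`` aligns rows to walkers for
    subject-wise splitting. ``windows_per_session`` caps the number of
    windows taken from each session (``1`` mirrors the study design of one
    prediction per session per duration, keeping sample size constant
    across durations); ``None`` keeps every non-overlapping window.
    """
    if representation not in REPRESENTATIONS:
        raise ValueError(f"unknown representation {representation!r}")
    X, y, sids = [], [], []
    for seq, gender, sid in sessions:
        label = LABELS[gender]
        if representation == "clinical":
            s = height_normalize(seq)
            vec = metrics_vector(clinical_metrics(s, detect_gait_events(s)))
            X.append(vec)
            y.append(label)
            sids.append(sid)
            continue
        base = representation.replace("static4_velocity", "velocity3d").replace(
            "static4", "position3d"
        )
        wins = _sequence_windows(seq, base, spec, stride)
        if windows_per_session is not None:
            wins = wins[:windows_per_session]
        for w in wins:
            X.append(static_summary(w) if representation.startswith("static4") else w)
            y.append(label)
            sids.append(sid)
    return np.asarray(X, dtype=float), np.asarray(y, dtype=int), np.asarray(sids)


def _fit_predict(family, Xtr, ytr, Xte, seed, lstm_hp, static_spec, manifest):
    if family == "lstm":
        hp = replace(lstm_hp or LstmHyperParams(), seed=seed)
        model = train_lstm(Xtr, ytr, hp, manifest=manifest)
    else:
        spec = replace(static_spec or StaticModelSpec(), family=family, seed=seed)
        model = train_static(Xtr, ytr, spec, manifest=manifest)
    labels, _ = model.predict(Xte)
    return labels, model


def duration_sweep(
    sessions,
    family: str,
    representation: str,
    ks=range(1, 11),
    *,
    n_replicates: int = 10,
    n_folds: int = 10,
    seed: int = 0,
    lstm_hp: LstmHyperParams | None = None,
    static_spec: StaticModelSpec | None = None,
    permute_labels: bool = False,
    windows_per_session: int | None = None,
    experiment_id: int = 0,
    archive_dir=None,
) -> pd.DataFrame:
    """Full (k × replicate × fold) sweep for one family/representation cell.

    Each replicate re-seeds the model initialization, the fold assignment
    and — under ``permute_labels=True`` — an independent subject-level
    permutation of the gender labels (the null calibration: any residual
    mean accuracy over replicates is leakage). Returns tidy rows with
    per-fold prediction counts.
    """
    sessions = list(sessions)
    subj_gender = {}
    for _, g, sid in sessions:
        subj_gender.setdefault(sid, g)
    subj_list = sorted(subj_gender)

    ks = list(ks) if representation != "clinical" else [0]
    cache = {}
    rows = []
    for k in ks:
        spec = WindowSpec(k) if k else None
        if k not in cache:
            cache[k] = build_dataset(
                sessions, representation, spec,
                windows_per_session=windows_per_session,
            )
        X, y, sids = cache[k]
        for rep in range(n_replicates):
            fold_on = sessions
            if permute_labels:
                rng = np.random.default_rng(_cell_seed(seed, 97, rep))
                permuted = dict(
                    zip(subj_list, rng.permutation([subj_gender[s] for s in subj_list]))
                )
                y = np.array([LABELS[permuted[s]] for s in sids], dtype=int)
                # folds must be stratified on the labels actually used, or
                # per-fold imbalance biases null accuracy below chance
                fold_on = [(s, permuted[s]) for s in subj_list]
            fold_seed = _cell_seed(seed, experiment_id, k, rep, 1)
            folds = subject_kfold(fold_on, n_folds, seed=fold_seed)
            for fold_id, (train_s, test_s) in enumerate(folds):
                tr = np.isin(sids, train_s)
                te = np.isin(sids, test_s)
                if tr.sum() == 0 or te.sum() == 0 or len(np.unique(y[tr])) < 2:
                    continue
                model_seed = _cell_seed(seed, experiment_id, k, rep, fold_id, 2)
                manifest = {
                    "representation": representation,
                    "window_k": k,
                    "replicate": rep,
                    "fold": fold_id,
                    "seed": model_seed,
                }
                pred, model = _fit_predict(
                    family, X[tr], y[tr], X[te], model_seed, lstm_hp,
                    static_spec, manifest,
                )
                if archive_dir is not None:
                    model.save(
                        f"{archive_dir}/{family}_{representation}_k{k}_r{rep}_f{fold_id}"
                    )
                n_correct = int((pred == y[te]).sum())
                rows.append(
                    {
                        "experiment_id": experiment_id,
                        "family": family,
                        "representation": representation,
                        "window_k": k,
                        "replicate": rep,
                        "fold": fold_id,
                        "n_test": int(te.sum()),
                        "n_correct": n_correct,
                        "accuracy": n_correct / int(te.sum()),
                    }
                )
    return pd.DataFrame(rows)


#: Model/representation cells run by each experiment id.
EXPERIMENT_PLANS = {
    2: [("lstm", "position3d")],
    3: [(f, "static4") for f in ("svm_linear", "svm_rbf", "svm_sigmoid", "rdf")]
    + [(f, "clinical") for f in ("svm_linear", "svm_rbf", "svm_sigmoid", "rdf")],
    4: [("lstm", "velocity3d")]
    + [(f, "static4_velocity") for f in ("svm_linear", "svm_rbf", "svm_sigmoid", "rdf")],
    5: [("lstm", "position2d"), ("lstm", "velocity2d")],
}


def run_experiment(
    exp_id: int,
    sessions,
    *,
    ks=range(1, 11),
    n_replicates: int = 10,
    n_folds: int = 10,
    seed: int = 0,
    lstm_hp: LstmHyperParams | None = None,
    static_spec: StaticModelSpec | None = None,
    archive_dir=None,
) -> pd.DataFrame:
    """Run one of the four computational experiments as a factorial sweep.

    2: LSTM on 3D positions; 3: static models on 4-stat and clinical
    representations; 4: all families on velocity cues; 5: LSTM on 2D
    (coronal) input. Deterministic given the master ``seed``.
    """
    if exp_id not in EXPERIMENT_PLANS:
        raise ValueError(f"unknown experiment id {exp_id}; expected one of 2-5")
    frames = []
    for family, representation in EXPERIMENT_PLANS[exp_id]:
        frames.append(
            duration_sweep(
                sessions,
                family,
                representation,
                ks,
                n_replicates=n_replicates,
                n_folds=n_folds,
                seed=seed,
                lstm_hp=lstm_hp,
                static_spec=static_spec,
                experiment_id=exp_id,
                archive_dir=archive_dir,
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Point-light stimulus clips
# ---------------------------------------------------------------------------

#: Exposure durations (s) used in psychophysics presentations.
PSYCHOPHYSICS_DURATIONS = (0.4, 1.5, 2.5, 3.8)


@dataclass(frozen=True)
class DisplayConfig:
    """Screen geometry for stimulus export.

    ``px_per_deg`` converts visual angle to pixels (≈40 px/° for a 1080p
    desktop monitor at arm's-length viewing).
    """

    canvas: tuple = (1920, 1080)  # (width, height) px
    dot_radius_px: int = 5
    field_deg: tuple = (6.0, 8.0)  # (width, height) degrees, incl. padding
    walker_deg: tuple = (2.5, 4.0)  # walker bounding box, degrees
    px_per_deg: float = 40.0
    fps: float = 24.0


@dataclass
class StimulusClip:
    """Per-frame dot centers in screen pixels for one walking clip."""

    dots: np.ndarray  # (frames, 20, 2), px, origin top-left, y down
    dot_radius_px: int
    canvas: tuple
    fps: float

    @property
    def n_frames(self) -> int:
        return self.dots.shape[0]

    def to_table(self) -> pd.DataFrame:
        """Long-format export: frame, joint index, x_px, y_px."""
        f, j, _ = self.dots.shape
        frames = np.repeat(np.arange(f), j)
        joints = np.tile(np.arange(j), f)
        flat = self.dots.reshape(-1, 2)
        return pd.DataFrame(
            {"frame": frames, "joint": joints, "x_px": flat[:, 0], "y_px": flat[:, 1]}
        )


def make_stimulus_clip(
    seq: SkeletonSequence,
    display: DisplayConfig | None = None,
    duration: float | None = None,
    psychophysics_mode: bool = False,
) -> StimulusClip:
    """Render a height-normalized walk into point-light dot coordinates.

    The coronal (x, y) projection is scaled so the walker's unit stature
    spans the walker box height and centered in the canvas; a single scalar
    scale preserves the aspect ratio. In ``psychophysics_mode`` the clip
    duration must be one of :data:`PSYCHOPHYSICS_DURATIONS`.
    """
    display = display or DisplayConfig()
    if duration is not None:
        if psychophysics_mode and not any(
            abs(duration - d) < 1e-9 for d in PSYCHOPHYSICS_DURATIONS
        ):
            raise ValueError(
                f"psychophysics exposure must be one of {PSYCHOPHYSICS_DURATIONS}"
            )
        n = int(round(duration * display.fps))
        if n > seq.n_frames:
            raise ValueError("sequence shorter than requested clip duration")
    else:
        n = seq.n_frames
    s = height_normalize(seq)
    xy = project_coronal(s.positions[:n])  # (n, 20, 2), stature ~ 1 unit
    scale = display.walker_deg[1] * display.px_per_deg  # px per stature
    cx, cy = display.canvas[0] / 2.0, display.canvas[1] / 2.0
    dots = np.empty_like(xy)
    dots[..., 0] = cx + xy[..., 0] * scale
    dots[..., 1] = cy - xy[..., 1] * scale  # screen y grows downward
    return StimulusClip(
        dots=dots,
        dot_radius_px=display.dot_radius_px,
        canvas=display.canvas,
        fps=display.fps,
    )
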