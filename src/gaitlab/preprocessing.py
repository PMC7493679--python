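"""Shared transforms: height normalization, smoothing, differentiation,
coronal projection, duration windowing, and train-frozen feature scaling.

Windows are defined in frames (``10*k`` for ``k = 1..10`` at 24 fps); the
nominal second labels used for reporting are carried alongside but never
drive the arithmetic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .skeleton import JOINT_INDEX, SkeletonSequence

__all__ = [
    "ScalerStats",
    "WindowSpec",
    "height_normalize",
    "smooth_moving_average",
    "differentiate",
    "project_coronal",
    "window_split",
    "fit_scaler",
    "apply_scaler",
]


@dataclass(frozen=True)
class WindowSpec:
    """One of the 10 exposure-duration conditions: ``n_frames = 10*k``."""

    k: int

    def __post_init__(self):
        if not 1 <= self.k <= 10:
            raise ValueError("window index k must be in 1..10")

    @property
    def n_frames(self) -> int:
        return 10 * self.k

    @property
    def nominal_duration(self) -> float:
        """Reporting label in seconds (0.4 s steps, as conventionally quoted)."""
        return 0.4 * self.k


def height_normalize(seq: SkeletonSequence) -> SkeletonSequence:
    """Scale the walker to unit stature and center the pelvis at the origin.

    A single scalar scale (the median per-frame head-to-foot vertical
    extent) preserves the aspect ratio while removing stature as a cue; the
    pelvis mean position becomes the origin. Idempotent. Raises on a
    degenerate (zero-extent) skeleton.
    """
    pos = seq.positions
    head_y = pos[:, JOINT_INDEX["head"], 1]
    feet_y = np.minimum(
        pos[:, JOINT_INDEX["foot_l"], 1], pos[:, JOINT_INDEX["foot_r"], 1]
    )
    extent = float(np.median(head_y - feet_y))
    if extent <= 1e-12:
        raise ValueError("degenerate skeleton: zero head-to-foot extent")
    center = pos[:, JOINT_INDEX["pelvis"], :].mean(axis=0)
    return seq.copy_with(positions=(pos - center) / extent)


def smooth_moving_average(seq: SkeletonSequence, window: int = 5) -> SkeletonSequence:
    """Centered moving average per coordinate, length-preserving.

    Edges use a shrinking (truncated) centered window, so constants and
    interior affine segments pass through unchanged.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = seq.n_frames
    if n < window:
        raise ValueError(f"sequence of {n} frames shorter than window {window}")
    half = window // 2
    flat = seq.to_frame_vectors()
    csum = np.cumsum(np.vstack([np.zeros((1, flat.shape[1])), flat]), axis=0)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1) + 1
    out = (csum[hi] - csum[lo]) / (hi - lo)[:, None]
    return seq.copy_with(positions=out.reshape(seq.positions.shape))


def differentiate(seq: SkeletonSequence, fps: float | None = None) -> SkeletonSequence:
    """Per-coordinate velocity by forward differences of adjacent frames.

    Length-preserving: the final difference is repeated so velocity and
    position windows align one-to-one for a given :class:`WindowSpec`.
    Units are m/s.
    """
    if seq.n_frames < 2:
        raise ValueError("need at least 2 frames to differentiate")
    fps = fps or seq.fps
    vel = np.diff(seq.positions, axis=0) * fps
    vel = np.concatenate([vel, vel[-1:]], axis=0)
    return seq.copy_with(positions=vel)


def project_coronal(arr: np.ndarray) -> np.ndarray:
    """Drop the anterior-posterior (z) axis, keeping (x, y) per joint.

    Accepts ``(frames, joints, 3)`` or already-projected ``(frames,
    joints, 2)`` arrays (idempotent); per-frame cardinality becomes 40.
    """
    if arr.shape[-1] == 2:
        return arr
    return arr[..., :2]


def window_split(
    seq_or_array, spec: WindowSpec, stride: int | None = None
) -> list[np.ndarray]:
    """Cut a session into fixed-length windows of ``spec.n_frames`` frames.

    Non-overlapping by default (``stride = n_frames``); each window is
    returned as a ``(n_frames, joints, dims)`` array. A session shorter
    than one window yields an empty list with a warning.
    """
    arr = (
        seq_or_array.positions
        if isinstance(seq_or_array, SkeletonSequence)
        else np.asarray(seq_or_array)
    )
    n = arr.shape[0]
    w = spec.n_frames
    stride = stride or w
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if n < w:
        warnings.warn(
            f"sequence of {n} frames shorter than window of {w}; no windows",
            stacklevel=2,
        )
        return []
    return [arr[s : s + w] for s in range(0, n - w + 1, stride)]


@dataclass
class ScalerStats:
    """Standardization statistics frozen from the training split only.

    Transform: per-feature z-score, then min-max into [-1, 1] using the
    training extrema of the z-scored values. Test values may fall outside
    [-1, 1]; they are not clipped. Zero-variance features are retained and
    mapped to 0 (flagged in ``constant_mask``).
    """

    mean: np.ndarray
    sd: np.ndarray
    zmin: np.ndarray
    zmax: np.ndarray
    constant_mask: np.ndarray

    @property
    def n_features(self) -> int:
        return self.mean.shape[0]


def fit_scaler(train: np.ndarray, minmax: bool = True) -> ScalerStats:
    """Fit :class:`ScalerStats` on a ``(n_samples, n_features)`` array.

    ``minmax=False`` fits the z-score stage only (used for sequence inputs,
    which are standardized but not range-compressed).
    """
    train = np.asarray(train, dtype=float)
    if train.ndim != 2 or train.shape[0] == 0:
        raise ValueError("fit_scaler expects a non-empty (n_samples, n_features) array")
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    # float summation noise on a constant column gives sd ~ 1e-16, not 0
    constant = sd <= 1e-12 * np.maximum(1.0, np.abs(mean))
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} zero-variance feature(s) retained as 0",
            stacklevel=2,
        )
    sd_safe = np.where(constant, 1.0, sd)
    z = (train - mean) / sd_safe
    if minmax:
        zmin, zmax = z.min(axis=0), z.max(axis=0)
    else:
        zmin = np.full_like(mean, -1.0)
        zmax = np.full_like(mean, 1.0)
    return ScalerStats(mean=mean, sd=sd_safe, zmin=zmin, zmax=zmax,
                       constant_mask=constant)


def apply_scaler(stats: ScalerStats, x: np.ndarray) -> np.ndarray:
    """Apply frozen scaling to ``(n_samples, n_features)`` data."""
    x = np.asarray(x, dtype=float)
    z = (x - stats.mean) / stats.sd
    span = stats.zmax - stats.zmin
    span_safe = np.where(span <= 0, 1.0, span)
    out = 2.0 * (z - stats.zmin) / span_safe - 1.0
    out = np.where(span <= 0, 0.0, out)
    out = np.where(stats.constant_mask, 0.0, out)
    return out
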