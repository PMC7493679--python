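"""Static representations of gait: four-statistic summaries and the
12 clinical spatiotemporal metrics (with the gait-event detection they need).

The four-statistic summary (min, max, mean, SD per dimension) deliberately
discards temporal order — it is invariant to any permutation of the frames
inside a window, which is the operational contrast with sequence models.

Clinical metrics are computed from heel-strike and toe-off events detected
on the foot's anterior excursion relative to the pelvis, the standard
kinematic event definition for treadmill data without force plates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .skeleton import JOINT_INDEX, SkeletonSequence

__all__ = [
    "METRIC_NAMES",
    "GaitEvents",
    "NoGaitDetectedError",
    "static_summary",
    "detect_gait_events",
    "clinical_metrics",
    "knee_flexion_angles",
]

#: Canonical order of the 12 clinical spatiotemporal metrics.
METRIC_NAMES: tuple[str, ...] = (
    "stride_length",
    "cadence",
    "speed",
    "stride_time",
    "single_support",
    "double_support",
    "stance_swing_ratio_l",
    "stance_swing_ratio_r",
    "knee_flexion_stance_l",
    "knee_flexion_stance_r",
    "knee_flexion_swing_l",
    "knee_flexion_swing_r",
)


class NoGaitDetectedError(ValueError):
    """No periodic gait pattern found in the sequence."""


def static_summary(window: np.ndarray) -> np.ndarray:
    """Four first-order statistics per dimension of a windowed signal.

    ``window`` is ``(frames, D)`` (or ``(frames, joints, dims)``, flattened
    internally). Returns a ``4*D`` vector ordered dimension-major:
    ``(min, max, mean, population SD)`` for each dimension.
    """
    arr = np.asarray(window, dtype=float)
    if arr.size == 0:
        raise ValueError("empty window")
    arr = arr.reshape(arr.shape[0], -1)
    stats = np.stack(
        [arr.min(axis=0), arr.max(axis=0), arr.mean(axis=0), arr.std(axis=0)],
        axis=1,
    )  # (D, 4) — population SD (ddof=0), fixed for reproducibility
    return stats.reshape(-1)


@dataclass
class GaitEvents:
    """Heel-strike and toe-off times (s) per foot, alternating HS→TO→HS."""

    heel_strikes: dict  # side -> np.ndarray of times
    toe_offs: dict  # side -> np.ndarray of times
    cycle_period: float  # s, estimated stride period

    def validate(self) -> None:
        for side in ("l", "r"):
            hs = self.heel_strikes[side]
            to = self.toe_offs[side]
            if len(hs) and (np.any(np.diff(hs) <= 0) or np.any(np.diff(to) <= 0)):
                raise ValueError("event times must be strictly increasing")
            # exactly one toe-off between consecutive ipsilateral heel strikes
            for a, b in zip(hs[:-1], hs[1:]):
                inside = (to > a) & (to < b)
                if inside.sum() != 1:
                    raise ValueError(
                        f"{side}: expected exactly one toe-off in ({a:.3f}, {b:.3f}),"
                        f" found {int(inside.sum())}"
                    )


def _estimate_period_frames(seq: SkeletonSequence) -> int:
    """Stride period in frames from the pelvis lateral-sway autocorrelation."""
    x = seq.joint("pelvis")[:, 0]
    x = x - x.mean()
    if np.std(x) < 1e-9:
        raise NoGaitDetectedError("pelvis lateral sway has no variance")
    ac = np.correlate(x, x, mode="full")[len(x) - 1 :]
    ac = ac / ac[0]
    lo = max(2, int(0.7 * seq.fps))  # shortest plausible stride ~0.7 s
    hi = min(len(ac) - 1, int(2.6 * seq.fps))
    if hi <= lo:
        raise NoGaitDetectedError("sequence too short to estimate gait period")
    band = ac[lo:hi]
    lag = lo + int(np.argmax(band))
    if band.max() < 0.2:
        raise NoGaitDetectedError("no periodic pelvis sway detected")
    return lag


def _smooth(x: np.ndarray, w: int = 5) -> np.ndarray:
    if len(x) < w:
        return x
    kernel = np.ones(w) / w
    pad = np.pad(x, (w // 2, w // 2), mode="edge")
    return np.convolve(pad, kernel, mode="valid")


def detect_gait_events(seq: SkeletonSequence) -> GaitEvents:
    """Detect heel strikes and toe-offs per foot.

    Heel strike: local maximum of the foot's anterior position relative to
    the pelvis; toe-off: the subsequent local minimum. Peaks are found on a
    5-frame-smoothed signal with a minimum separation of 0.4× the stride
    period (estimated from the pelvis lateral-sway autocorrelation).
    Raises :class:`NoGaitDetectedError` when no periodicity is present.
    """
    period = _estimate_period_frames(seq)
    min_dist = max(2, int(0.4 * period))
    pelvis_z = seq.joint("pelvis")[:, 2]
    heel_strikes, toe_offs = {}, {}
    for side in ("l", "r"):
        rel = _smooth(seq.joint(f"foot_{side}")[:, 2] - pelvis_z)
        if np.std(rel) < 1e-9:
            raise NoGaitDetectedError(f"foot_{side} shows no fore-aft excursion")
        hs_idx, _ = sps.find_peaks(rel, distance=min_dist)
        to_idx, _ = sps.find_peaks(-rel, distance=min_dist)
        if len(hs_idx) < 2:
            raise NoGaitDetectedError(f"fewer than two heel strikes on foot_{side}")
        # keep exactly one toe-off per HS→HS interval (drop inconsistent strides)
        hs_keep, to_keep = [hs_idx[0]], []
        for a, b in zip(hs_idx[:-1], hs_idx[1:]):
            inside = to_idx[(to_idx > a) & (to_idx < b)]
            if len(inside) >= 1:
                to_keep.append(int(inside[np.argmin(rel[inside])]))
                hs_keep.append(int(b))
        if len(to_keep) == 0:
            raise NoGaitDetectedError(f"no toe-offs between heel strikes on foot_{side}")
        t = seq.timestamps
        heel_strikes[side] = t[np.asarray(hs_keep)]
        toe_offs[side] = t[np.asarray(to_keep)]
    events = GaitEvents(
        heel_strikes=heel_strikes,
        toe_offs=toe_offs,
        cycle_period=period / seq.fps,
    )
    events.validate()
    return events


def knee_flexion_angles(seq: SkeletonSequence, side: str) -> np.ndarray:
    """Per-frame knee flexion (degrees): 180° minus the hip-knee-ankle angle."""
    hip = seq.joint(f"hip_{side}")
    knee = seq.joint(f"knee_{side}")
    ankle = seq.joint(f"ankle_{side}")
    v1 = hip - knee
    v2 = ankle - knee
    cos = np.sum(v1 * v2, axis=1) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1) + 1e-12
    )
    return 180.0 - np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))


def _stance_mask(t: np.ndarray, hs: np.ndarray, to: np.ndarray) -> np.ndarray:
    """Boolean per-frame stance from paired events (True between HS and its TO)."""
    mask = np.zeros(len(t), dtype=bool)
    for a in hs:
        later = to[to > a]
        if len(later):
            mask |= (t >= a) & (t < later[0])
    return mask


def clinical_metrics(seq: SkeletonSequence, events: GaitEvents) -> dict:
    """The 12 clinical spatiotemporal metrics for one session.

    Walking (belt) speed is estimated from the mean backward foot velocity
    during the interior of detected stance intervals; stride length is the
    residual ipsilateral HS-to-HS foot displacement plus belt travel per
    stride. Cadence counts both feet's steps; support fractions come from
    per-frame stance overlap. Returns a dict keyed by
    :data:`METRIC_NAMES`.
    """
    events.validate()
    t = seq.timestamps
    pelvis_z = seq.joint("pelvis")[:, 2]
    stride_times, belt_speeds, residuals = [], [], []
    stance_frac = {}
    knee_stance, knee_swing = {}, {}
    masks = {}
    for side in ("l", "r"):
        hs = events.heel_strikes[side]
        to = events.toe_offs[side]
        if len(hs) < 2:
            raise ValueError(f"need >= 2 heel strikes on foot_{side}")
        st = np.diff(hs)
        stride_times.extend(st)
        rel = seq.joint(f"foot_{side}")[:, 2] - pelvis_z
        # residual same-foot displacement over each stride (≈0 on a treadmill)
        hs_idx = np.searchsorted(t, hs)
        residuals.extend(np.abs(np.diff(rel[np.clip(hs_idx, 0, len(t) - 1)])))
        # belt speed from the interior 60% of each stance interval
        fracs = []
        for a in hs:
            later = to[to > a]
            if not len(later):
                continue
            b = later[0]
            nxt = hs[hs > a]
            if len(nxt):
                fracs.append((b - a) / (nxt[0] - a))
            sel = (t >= a + 0.2 * (b - a)) & (t <= b - 0.2 * (b - a))
            if sel.sum() >= 3:
                dz = np.gradient(rel[sel], t[sel])
                belt_speeds.append(-np.mean(dz))
        stance_frac[side] = float(np.mean(fracs)) if fracs else np.nan
        masks[side] = _stance_mask(t, hs, to)
        knee = knee_flexion_angles(seq, side)
        span = (t >= hs[0]) & (t <= hs[-1])
        st_m = masks[side] & span
        sw_m = ~masks[side] & span
        knee_stance[side] = float(knee[st_m].mean()) if st_m.any() else np.nan
        knee_swing[side] = float(knee[sw_m].mean()) if sw_m.any() else np.nan

    stride_time = float(np.mean(stride_times))
    cadence = 120.0 / stride_time  # two steps per stride
    belt = float(np.mean(belt_speeds)) if belt_speeds else 0.0
    stride_length = float(np.mean(residuals)) + belt * stride_time
    speed = cadence / 120.0 * stride_length

    # support fractions over the span where both feet have defined state
    span_lo = max(events.heel_strikes["l"][0], events.heel_strikes["r"][0])
    span_hi = min(events.heel_strikes["l"][-1], events.heel_strikes["r"][-1])
    span = (t >= span_lo) & (t <= span_hi)
    both = masks["l"] & masks["r"] & span
    one = (masks["l"] ^ masks["r"]) & span
    n_span = max(int(span.sum()), 1)
    double_support = float(both.sum()) / n_span
    single_support = float(one.sum()) / n_span

    def ratio(side):
        f = stance_frac[side]
        return f / (1.0 - f) if np.isfinite(f) and f < 1 else np.nan

    return {
        "stride_length": stride_length,
        "cadence": cadence,
        "speed": speed,
        "stride_time": stride_time,
        "single_support": single_support,
        "double_support": double_support,
        "stance_swing_ratio_l": ratio("l"),
        "stance_swing_ratio_r": ratio("r"),
        "knee_flexion_stance_l": knee_stance["l"],
        "knee_flexion_stance_r": knee_stance["r"],
        "knee_flexion_swing_l": knee_swing["l"],
        "knee_flexion_swing_r": knee_swing["r"],
    }


def metrics_vector(metrics: dict) -> np.ndarray:
    """The 12 metrics as a vector in canonical :data:`METRIC_NAMES` order."""
    return np.array([metrics[k] for k in METRIC_NAMES], dtype=float)
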