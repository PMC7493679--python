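"""Canonical skeleton definition and the in-memory sequence container.

Axis convention used throughout the package:

* ``x`` — lateral, positive to the walker's right
* ``y`` — vertical, positive up
* ``z`` — anterior–posterior, positive toward the viewer

Coordinates are in meters. Sequences are treadmill walks: the pelvis has no
progressive (z-trend) component, so the walker appears to walk in place
facing the viewer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical ordered 20-joint set. Upper body first, then left/right limbs.
JOINTS: tuple[str, ...] = (
    "head",
    "neck",
    "spine_mid",
    "pelvis",
    "shoulder_l",
    "shoulder_r",
    "elbow_l",
    "elbow_r",
    "wrist_l",
    "wrist_r",
    "hand_l",
    "hand_r",
    "hip_l",
    "hip_r",
    "knee_l",
    "knee_r",
    "ankle_l",
    "ankle_r",
    "foot_l",
    "foot_r",
)

N_JOINTS = len(JOINTS)
AXES: tuple[str, ...] = ("x", "y", "z")

#: Flat per-frame coordinate names in canonical order: ``<joint>_<axis>``.
COORD_NAMES: tuple[str, ...] = tuple(f"{j}_{a}" for j in JOINTS for a in AXES)

JOINT_INDEX: dict[str, int] = {name: i for i, name in enumerate(JOINTS)}


class SkeletonError(ValueError):
    """Invariant violation on a skeleton sequence."""


@dataclass
class SkeletonSequence:
    """Timestamped 3D trajectories of the 20 canonical joints for one session.

    Parameters
    ----------
    timestamps
        Seconds, strictly increasing, shape ``(n_frames,)``.
    positions
        Meters, shape ``(n_frames, 20, 3)`` in canonical joint order with
        axes ``(x, y, z)``.
    subject_id, session_id, gender, fps
        Session metadata. ``gender`` is ``"M"`` or ``"F"``.
    """

    timestamps: np.ndarray
    positions: np.ndarray
    subject_id: str = ""
    session_id: str = ""
    gender: str = ""
    fps: float = 24.0
    joints: tuple[str, ...] = field(default=JOINTS)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.validate()

    def validate(self) -> None:
        if tuple(self.joints) != JOINTS:
            raise SkeletonError(
                f"expected the canonical {N_JOINTS}-joint set, got {len(self.joints)} joints"
            )
        if self.positions.ndim != 3 or self.positions.shape[1:] != (N_JOINTS, 3):
            raise SkeletonError(
                f"positions must have shape (frames, {N_JOINTS}, 3), got {self.positions.shape}"
            )
        if self.timestamps.shape != (self.positions.shape[0],):
            raise SkeletonError("timestamps and positions disagree on frame count")
        if self.n_frames == 0:
            raise SkeletonError("empty sequence")
        if not np.all(np.isfinite(self.positions)):
            raise SkeletonError("positions contain non-finite values")
        if self.n_frames > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise SkeletonError("timestamps must be strictly increasing")
        if self.gender not in ("", "M", "F"):
            raise SkeletonError(f"gender must be 'M' or 'F', got {self.gender!r}")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    def joint(self, name: str) -> np.ndarray:
        """Trajectory of one joint, shape ``(n_frames, 3)``."""
        return self.positions[:, JOINT_INDEX[name], :]

    def to_frame_vectors(self) -> np.ndarray:
        """Flatten to frame vectors of cardinality 60, canonical order."""
        return self.positions.reshape(self.n_frames, N_JOINTS * 3)

    def copy_with(self, *, positions: np.ndarray | None = None,
                  timestamps: np.ndarray | None = None) -> "SkeletonSequence":
        return SkeletonSequence(
            timestamps=self.timestamps.copy() if timestamps is None else timestamps,
            positions=self.positions.copy() if positions is None else positions,
            subject_id=self.subject_id,
            session_id=self.session_id,
            gender=self.gender,
            fps=self.fps,
        )
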