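"""Parametric synthetic point-light walker cohorts.

The study population this package analyses (treadmill walkers recorded as
20-joint 3D trajectories at 24 fps) is emulated by a kinematic-chain walker
whose joint time courses are low-order periodic functions of the gait phase.
Gender information is planted through two separable channels:

* **dynamic cues** — the ratio of shoulder to hip lateral sway amplitude,
  higher on average for male walkers;
* **structural cues** — shoulder-to-hip width ratio and stature, which
  height normalization is designed to suppress.

Both channels are configurable (:class:`EffectConfig`), so experiments can
plant the cue purely in the dynamics, purely in the structure, or nowhere
(a null cohort).

The legs follow an explicit stance/swing profile rather than a single
sinusoid: during stance (a configurable duty factor, default 0.62 of the
cycle) the foot travels backward at constant velocity, emulating a treadmill
belt, and during swing it returns with a cosine ease and knee-flexion-driven
foot clearance. This makes the spatiotemporal gait metrics (cadence, speed,
stride length, support fractions) analytically known functions of the
generator parameters — the ground truth that metric-extraction code is
tested against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .skeleton import JOINTS, JOINT_INDEX, N_JOINTS, SkeletonSequence

__all__ = [
    "GaitModelParams",
    "EffectConfig",
    "CohortSpec",
    "sample_cohort",
    "generate_walk",
    "ground_truth_metrics",
    "InvalidCohortError",
]


class InvalidCohortError(ValueError):
    """Raised for unsatisfiable cohort requests."""


# Anthropometric segment lengths as fractions of stature (standard
# biomechanics segment tables).
SEGMENT_FRACTIONS = {
    "thigh": 0.245,
    "shank": 0.246,
    "foot": 0.152,
    "upper_arm": 0.186,
    "forearm": 0.146,
    "hand": 0.108,
    "ankle_height": 0.039,
    "hip_height": 0.530,
    "shoulder_height": 0.818,
    "neck": 0.035,
    "head": 0.112,
}


@dataclass
class GaitModelParams:
    """Ground-truth generative parameters for one synthetic walker.

    Lengths are meters, angles radians unless noted. Amplitudes may be zero
    (degenerate, motionless limits are valid); lengths, the height and the
    cycle period must be strictly positive.
    """

    subject_id: str
    gender: str  # "M" or "F"
    gait_cycle_period: float = 1.6  # s, full stride (two steps)
    stride_length: float = 1.25  # m
    shoulder_sway_amp: float = 0.045  # m lateral
    hip_sway_amp: float = 0.035  # m lateral
    vertical_bounce_amp: float = 0.025  # m
    arm_swing_amp: float = 0.26  # rad
    knee_flexion_max: float = 60.0  # degrees, swing peak
    shoulder_width: float = 0.36  # m
    hip_width: float = 0.32  # m
    height: float = 1.72  # m
    duty_factor: float = 0.62  # stance fraction of the cycle per leg
    noise_sd: float = 0.005  # m, i.i.d. per-coordinate jitter
    segment_lengths: dict = field(default_factory=dict)
    weight: float = 75.0  # kg, metadata only
    age: float = 25.0  # years, metadata only

    def __post_init__(self) -> None:
        if self.gender not in ("M", "F"):
            raise ValueError(f"gender must be 'M' or 'F', got {self.gender!r}")
        if not (0.8 <= self.gait_cycle_period <= 2.4):
            raise ValueError("gait_cycle_period must be within [0.8, 2.4] s")
        for name in ("height", "shoulder_width", "hip_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in (
            "stride_length",
            "shoulder_sway_amp",
            "hip_sway_amp",
            "vertical_bounce_amp",
            "arm_swing_amp",
            "knee_flexion_max",
            "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.5 < self.duty_factor < 0.9):
            raise ValueError("duty_factor must lie in (0.5, 0.9)")
        if not self.segment_lengths:
            self.segment_lengths = {
                k: v * self.height for k, v in SEGMENT_FRACTIONS.items()
            }
        # The fore-aft foot excursion must be reachable by the leg.
        leg = self.segment_lengths["thigh"] + self.segment_lengths["shank"]
        if self.stride_length * self.duty_factor / 2.0 > 0.95 * leg:
            raise ValueError("stride_length too large for leg length")


def _gauss_pair(m_mean, f_mean, sd, lo=None, hi=None):
    return {"M": (m_mean, sd, lo, hi), "F": (f_mean, sd, lo, hi)}


@dataclass
class EffectConfig:
    """Gender-conditional parameter distributions for cohort sampling.

    Each entry maps gender → (mean, sd, lower, upper) of a truncated
    Gaussian. The two planted cues are the shoulder/hip sway-amplitude ratio
    (dynamic) and the shoulder/hip width ratio plus stature (structural).
    """

    gait_cycle_period: dict = field(
        default_factory=lambda: _gauss_pair(1.6, 1.6, 0.10, 0.9, 2.3)
    )
    stride_length: dict = field(
        default_factory=lambda: _gauss_pair(1.25, 1.25, 0.10, 0.6, 1.8)
    )
    hip_sway_amp: dict = field(
        default_factory=lambda: _gauss_pair(0.035, 0.035, 0.006, 0.01, 0.08)
    )
    sway_ratio: dict = field(
        default_factory=lambda: _gauss_pair(1.3, 0.7, 0.25, 0.05, 3.0)
    )
    vertical_bounce_amp: dict = field(
        default_factory=lambda: _gauss_pair(0.025, 0.025, 0.005, 0.005, 0.06)
    )
    arm_swing_amp: dict = field(
        default_factory=lambda: _gauss_pair(0.26, 0.26, 0.06, 0.02, 0.6)
    )
    knee_flexion_max: dict = field(
        default_factory=lambda: _gauss_pair(60.0, 60.0, 6.0, 20.0, 80.0)
    )
    hip_width: dict = field(
        default_factory=lambda: _gauss_pair(0.31, 0.31, 0.02, 0.22, 0.42)
    )
    width_ratio: dict = field(
        default_factory=lambda: _gauss_pair(1.15, 0.95, 0.06, 0.6, 1.6)
    )
    height: dict = field(
        # Study-population stature means/SDs (cm → m), truncated to a
        # physically plausible adult range.
        default_factory=lambda: _gauss_pair(1.7623, 1.2856, 0.3243, 1.0, 2.2)
    )
    duty_factor: dict = field(
        default_factory=lambda: _gauss_pair(0.62, 0.62, 0.015, 0.54, 0.72)
    )
    weight: dict = field(
        default_factory=lambda: _gauss_pair(80.49, 73.3, 2.86, 40.0, 150.0)
    )
    age: dict = field(
        default_factory=lambda: _gauss_pair(26.06, 21.29, 6.42, 18.0, 50.0)
    )
    noise_sd: float = 0.005

    def __post_init__(self) -> None:
        # Gender-specific SDs where the study population reports them.
        self.height["F"] = (self.height["F"][0], 0.2351, 1.0, 2.2)
        self.weight["F"] = (self.weight["F"][0], 4.59, 40.0, 150.0)
        self.age["F"] = (self.age["F"][0], 1.23, 18.0, 50.0)

    @classmethod
    def default(cls) -> "EffectConfig":
        """Dynamic (sway-ratio) plus structural (width, stature) cues."""
        return cls()

    @classmethod
    def dynamics_only(cls) -> "EffectConfig":
        """Gender cue only in the sway dynamics; structure gender-neutral."""
        cfg = cls()
        cfg.width_ratio = _gauss_pair(1.05, 1.05, 0.06, 0.6, 1.6)
        cfg.height = _gauss_pair(1.70, 1.70, 0.10, 1.4, 2.1)
        cfg.weight = _gauss_pair(75.0, 75.0, 8.0, 40.0, 150.0)
        return cfg

    @classmethod
    def structure_only(cls) -> "EffectConfig":
        """Gender cue only in stature (which height normalization removes).

        Sway dynamics and the width ratio are gender-neutral, so after
        height normalization no gender information should remain.
        """
        cfg = cls()
        cfg.sway_ratio = _gauss_pair(1.0, 1.0, 0.25, 0.05, 3.0)
        cfg.width_ratio = _gauss_pair(1.05, 1.05, 0.06, 0.6, 1.6)
        return cfg

    @classmethod
    def null(cls) -> "EffectConfig":
        """No gender effect at all."""
        cfg = cls.dynamics_only()
        cfg.sway_ratio = _gauss_pair(1.0, 1.0, 0.25, 0.05, 3.0)
        return cfg


@dataclass
class CohortSpec:
    """A sampled cohort plus its recording protocol.

    Defaults mirror the study protocol: 6 one-minute treadmill sessions per
    subject at 24 fps.
    """

    subjects: list
    sessions_per_subject: int = 6
    session_duration: float = 60.0
    fps: float = 24.0
    seed: int = 0

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def counts(self) -> dict:
        out = {"M": 0, "F": 0}
        for s in self.subjects:
            out[s.gender] += 1
        return out


def _draw_trunc(rng: np.random.Generator, mean, sd, lo, hi) -> float:
    if sd == 0:
        return float(mean)
    lo = -np.inf if lo is None else lo
    hi = np.inf if hi is None else hi
    a, b = (lo - mean) / sd, (hi - mean) / sd
    u = rng.uniform(stats.norm.cdf(a), stats.norm.cdf(b))
    return float(mean + sd * stats.norm.ppf(u))


def sample_cohort(
    n_male: int,
    n_female: int,
    seed: int,
    effect: EffectConfig | None = None,
    *,
    sessions_per_subject: int = 6,
    session_duration: float = 60.0,
    fps: float = 24.0,
) -> CohortSpec:
    """Draw per-subject generator parameters from gender-conditional Gaussians.

    Parameters are truncated to their valid ranges; the draw is fully
    reproducible given ``seed``. Raises :class:`InvalidCohortError` when no
    subjects are requested or a count is negative.
    """
    if n_male < 0 or n_female < 0:
        raise InvalidCohortError("subject counts must be non-negative")
    if n_male + n_female == 0:
        raise InvalidCohortError("cohort must contain at least one subject")
    effect = effect or EffectConfig.default()
    rng = np.random.default_rng(seed)
    subjects = []
    genders = ["M"] * n_male + ["F"] * n_female
    for i, g in enumerate(genders):
        draw = lambda spec: _draw_trunc(rng, *spec[g])  # noqa: E731
        height = draw(effect.height)
        hip_sway = draw(effect.hip_sway_amp)
        ratio = draw(effect.sway_ratio)
        hip_width = draw(effect.hip_width)
        wratio = draw(effect.width_ratio)
        subjects.append(
            GaitModelParams(
                subject_id=f"S{i:03d}{g}",
                gender=g,
                gait_cycle_period=draw(effect.gait_cycle_period),
                stride_length=min(draw(effect.stride_length), 1.5 * height * 0.49),
                shoulder_sway_amp=hip_sway * ratio,
                hip_sway_amp=hip_sway,
                vertical_bounce_amp=draw(effect.vertical_bounce_amp),
                arm_swing_amp=draw(effect.arm_swing_amp),
                knee_flexion_max=draw(effect.knee_flexion_max),
                shoulder_width=hip_width * wratio,
                hip_width=hip_width,
                height=height,
                duty_factor=draw(effect.duty_factor),
                noise_sd=effect.noise_sd,
                weight=draw(effect.weight),
                age=draw(effect.age),
            )
        )
    return CohortSpec(
        subjects=subjects,
        sessions_per_subject=sessions_per_subject,
        session_duration=session_duration,
        fps=fps,
        seed=seed,
    )


def _leg_trajectory(u: np.ndarray, params: GaitModelParams):
    """Sagittal-plane ankle offset and knee flexion over cycle phase ``u``.

    Returns ``(z_rel, beta)``: fore-aft ankle offset from the hip (m) and
    knee flexion (rad). Stance occupies ``u in [0, d)`` with constant
    backward travel (treadmill belt); swing returns the foot with a cosine
    ease. The fore-aft peak-to-peak excursion in the treadmill frame is
    ``stride_length * duty_factor``.
    """
    d = params.duty_factor
    excursion = params.stride_length * d
    beta_max = math.radians(params.knee_flexion_max)
    z = np.empty_like(u)
    beta = np.empty_like(u)
    stance = u < d
    s_st = u[stance] / d
    z[stance] = excursion * (0.5 - s_st)
    beta[stance] = 0.25 * beta_max * np.sin(np.pi * s_st)
    s_sw = (u[~stance] - d) / (1.0 - d)
    z[~stance] = excursion * (-0.5 + (1.0 - np.cos(np.pi * s_sw)) / 2.0)
    beta[~stance] = beta_max * np.sin(np.pi * s_sw)
    return z, beta


def generate_walk(
    params: GaitModelParams,
    duration: float,
    fps: float,
    seed: int = 0,
    *,
    subject_id: str | None = None,
    session_id: str = "sess00",
) -> SkeletonSequence:
    """Synthesize one treadmill walking session for ``params``.

    The pelvis sways laterally at the stride frequency, bounces vertically
    at twice that frequency, and has no anterior-posterior trend (treadmill
    convention). The shoulder girdle counter-sways in antiphase; the legs
    are a half-cycle apart; each arm swings in antiphase to its ipsilateral
    leg. Additive i.i.d. Gaussian jitter of SD ``params.noise_sd`` is
    applied per coordinate. Deterministic given ``(params, seed)``.
    """
    if duration <= 0 or fps <= 0:
        raise ValueError("duration and fps must be strictly positive")
    n = int(round(duration * fps))
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fps
    seg = params.segment_lengths
    # Random initial phase so sessions start at unsynchronized gait phases.
    u0 = rng.uniform(0.0, 1.0)
    u = (t / params.gait_cycle_period + u0) % 1.0
    ph = 2 * np.pi * u

    P = np.zeros((n, N_JOINTS, 3))

    hip_y = seg["hip_height"]
    sho_y = seg["shoulder_height"]
    bounce = params.vertical_bounce_amp * np.sin(2 * ph)
    pelvis_x = params.hip_sway_amp * np.sin(ph)
    shoulder_x = params.shoulder_sway_amp * np.sin(ph + np.pi)

    def put(name, x, y, z):
        j = JOINT_INDEX[name]
        P[:, j, 0] = x
        P[:, j, 1] = y
        P[:, j, 2] = z

    zeros = np.zeros(n)
    put("pelvis", pelvis_x, hip_y + bounce, zeros)
    put("spine_mid", (pelvis_x + shoulder_x) / 2, (hip_y + sho_y) / 2 + bounce, zeros)
    put("neck", shoulder_x, sho_y + seg["neck"] + bounce, zeros)
    put("head", shoulder_x, sho_y + seg["head"] + bounce, zeros)

    for side, sgn, u_off in (("l", -1.0, 0.0), ("r", 1.0, 0.5)):
        us = (u + u_off) % 1.0
        phs = 2 * np.pi * us
        # --- leg ---
        hip = np.stack(
            [pelvis_x + sgn * params.hip_width / 2, hip_y + bounce, zeros], axis=1
        )
        z_rel, beta = _leg_trajectory(us, params)
        lt, ls = seg["thigh"], seg["shank"]
        # Two-link chain: hip→knee→ankle with flexion beta in the sagittal
        # plane; the effective hip-ankle length shortens as the knee bends,
        # which lifts the foot during swing.
        d_eff = np.sqrt(lt**2 + ls**2 + 2 * lt * ls * np.cos(beta))
        z_clip = np.clip(z_rel / d_eff, -0.99, 0.99)
        theta = np.arcsin(z_clip)  # hip-ankle line pitch from vertical
        gamma = np.arcsin(np.clip(ls * np.sin(beta) / d_eff, -1, 1))
        alpha_t = theta + gamma  # thigh pitch
        knee = hip + lt * np.stack(
            [zeros, -np.cos(alpha_t), np.sin(alpha_t)], axis=1
        )
        ankle = hip + d_eff[:, None] * np.stack(
            [zeros, -np.cos(theta), np.sin(theta)], axis=1
        )
        foot = ankle + np.stack(
            [zeros, zeros - 0.3 * seg["ankle_height"], zeros + seg["foot"]], axis=1
        )
        put(f"hip_{side}", *hip.T)
        put(f"knee_{side}", *knee.T)
        put(f"ankle_{side}", *ankle.T)
        put(f"foot_{side}", *foot.T)
        # --- arm (antiphase to the ipsilateral leg) ---
        sho = np.stack(
            [shoulder_x + sgn * params.shoulder_width / 2, sho_y + bounce, zeros],
            axis=1,
        )
        gam = -params.arm_swing_amp * np.cos(phs)
        elbow = sho + seg["upper_arm"] * np.stack(
            [zeros, -np.cos(gam), np.sin(gam)], axis=1
        )
        elbow_bend = 0.35  # rad, constant elbow flexion
        fa = np.stack(
            [zeros, -np.cos(gam + elbow_bend), np.sin(gam + elbow_bend)], axis=1
        )
        wrist = elbow + seg["forearm"] * fa
        hand = wrist + seg["hand"] * fa
        put(f"shoulder_{side}", *sho.T)
        put(f"elbow_{side}", *elbow.T)
        put(f"wrist_{side}", *wrist.T)
        put(f"hand_{side}", *hand.T)

    if params.noise_sd > 0:
        P = P + rng.normal(0.0, params.noise_sd, size=P.shape)

    return SkeletonSequence(
        timestamps=t,
        positions=P,
        subject_id=subject_id or params.subject_id,
        session_id=session_id,
        gender=params.gender,
        fps=fps,
    )


def ground_truth_metrics(params: GaitModelParams) -> dict:
    """Closed-form clinical gait metrics implied by the generator model.

    The oracle for metric-recovery tests: keys match
    :data:`gaitlab.features.METRIC_NAMES`.
    """
    d = params.duty_factor
    beta_max = params.knee_flexion_max
    mean_sin = 2.0 / np.pi  # mean of sin(pi*s) over s in [0,1]
    return {
        "stride_length": params.stride_length,
        "cadence": 120.0 / params.gait_cycle_period,
        "speed": params.stride_length / params.gait_cycle_period,
        "stride_time": params.gait_cycle_period,
        "single_support": 2.0 * (1.0 - d),
        "double_support": 2.0 * d - 1.0,
        "stance_swing_ratio_l": d / (1.0 - d),
        "stance_swing_ratio_r": d / (1.0 - d),
        "knee_flexion_stance_l": 0.25 * beta_max * mean_sin,
        "knee_flexion_stance_r": 0.25 * beta_max * mean_sin,
        "knee_flexion_swing_l": beta_max * mean_sin,
        "knee_flexion_swing_r": beta_max * mean_sin,
    }
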