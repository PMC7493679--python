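"""Shared fixtures: small synthetic cohorts generated once per session.

Reduced-scale study conditions (cohort sizes, session lengths, the 32-unit
LSTM variant) are chosen for single-CPU tractability; the package defaults
remain the full-scale ones.
"""

import numpy as np
import pytest

from gaitlab.models import LstmHyperParams
from gaitlab.synthetic_gait import EffectConfig, GaitModelParams, generate_walk, sample_cohort


def make_sessions(cohort, duration, fps=24.0, seed0=1000):
    sessions = []
    for i, subj in enumerate(cohort.subjects):
        for k in range(cohort.sessions_per_subject):
            seq = generate_walk(
                subj, duration, fps, seed=seed0 + 10 * i + k, session_id=f"sess{k:02d}"
            )
            sessions.append((seq, subj.gender, subj.subject_id))
    return sessions


@pytest.fixture(scope="session")
def dyn_sessions():
    """10M + 10F walkers, gender cue only in sway dynamics; 3 × 20 s sessions."""
    cohort = sample_cohort(
        10, 10, seed=11, effect=EffectConfig.dynamics_only(),
        sessions_per_subject=3, session_duration=20.0,
    )
    return make_sessions(cohort, 20.0)


@pytest.fixture(scope="session")
def small_sessions():
    """5M + 5F, 2 × 15 s sessions — the null-calibration cohort."""
    cohort = sample_cohort(
        5, 5, seed=23, effect=EffectConfig.dynamics_only(),
        sessions_per_subject=2, session_duration=15.0,
    )
    return make_sessions(cohort, 15.0, seed0=5000)


@pytest.fixture(scope="session")
def lstm_hp_small():
    """32-unit LSTM variant for reduced-scale training runs."""
    return LstmHyperParams(hidden_size=32, epochs=40, seed=0)


@pytest.fixture
def zero_noise_params():
    return GaitModelParams(
        subject_id="z0", gender="M", gait_cycle_period=1.6, stride_length=1.2,
        noise_sd=0.0,
    )


@pytest.fixture
def walk_10s(zero_noise_params):
    return generate_walk(zero_noise_params, 10.0, 24.0, seed=5)
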