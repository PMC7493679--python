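"""Shared helpers for the analysis drivers: demo-scale cohort construction.

Demo scale (15 walkers, 2 × 20 s sessions) keeps every driver in the
minutes range on a laptop; the generator defaults themselves mirror the
full study protocol (41 walkers, 6 × 60 s at 24 fps).
"""

from pathlib import Path

from gaitlab.synthetic_gait import EffectConfig, generate_walk, sample_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def demo_cohort(effect=None, n_male=8, n_female=7, seed=17):
    return sample_cohort(
        n_male, n_female, seed=seed,
        effect=effect or EffectConfig.default(),
        sessions_per_subject=2, session_duration=20.0,
    )


def in_memory_sessions(cohort, seed0=9000):
    sessions = []
    for i, subj in enumerate(cohort.subjects):
        for j in range(cohort.sessions_per_subject):
            seq = generate_walk(
                subj, cohort.session_duration, cohort.fps,
                seed=seed0 + 10 * i + j, session_id=f"sess{j:02d}",
            )
            sessions.append((seq, subj.gender, subj.subject_id))
    return sessions
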