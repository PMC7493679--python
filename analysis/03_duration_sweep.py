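#!/usr/bin/env python
"""Exposure-duration sweep: sequence vs static learners.

Runs the LSTM (3D positions) and the four static families (4-stat summary)
over window durations on a dynamics-cue cohort, with subject-wise CV.
Writes the tidy sweep to ``results/sweep_duration.csv``.
"""

import pandas as pd

from common import RESULTS, demo_cohort, in_memory_sessions
from gaitlab.experiments import duration_sweep
from gaitlab.models import LstmHyperParams
from gaitlab.synthetic_gait import EffectConfig

cohort = demo_cohort(effect=EffectConfig.dynamics_only(), n_male=8, n_female=8, seed=19)
sessions = in_memory_sessions(cohort)
hp = LstmHyperParams(hidden_size=32, epochs=40, seed=0)  # reduced-scale variant

frames = []
frames.append(
    duration_sweep(
        sessions, "lstm", "position3d", ks=[1, 4, 7, 10],
        n_replicates=3, n_folds=3, seed=51, lstm_hp=hp, experiment_id=2,
    )
)
for family in ("svm_linear", "svm_rbf", "svm_sigmoid", "rdf"):
    frames.append(
        duration_sweep(
            sessions, family, "static4", ks=range(1, 11),
            n_replicates=3, n_folds=3, seed=51, experiment_id=3,
        )
    )

df = pd.concat(frames, ignore_index=True)
RESULTS.mkdir(exist_ok=True)
df.to_csv(RESULTS / "sweep_duration.csv", index=False)

from gaitlab.stats_report import summarize

print(summarize(df).round(3).to_string(index=False))
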