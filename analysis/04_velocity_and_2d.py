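#!/usr/bin/env python
"""Velocity-cue and coronal-projection comparisons.

Trains the LSTM on position vs velocity input (3D and 2D) and the static
families on velocity summaries and clinical metrics, then runs the t/F
comparisons: each cohort against chance and velocity vs position.
Writes ``results/velocity_2d.csv`` and ``results/stats_tests.csv``.
"""

import pandas as pd

from common import RESULTS, demo_cohort, in_memory_sessions
from gaitlab.experiments import duration_sweep
from gaitlab.models import LstmHyperParams
from gaitlab.stats_report import ftest_between, replicate_accuracies, ttest_vs_chance
from gaitlab.synthetic_gait import EffectConfig

cohort = demo_cohort(effect=EffectConfig.dynamics_only(), n_male=8, n_female=8, seed=19)
sessions = in_memory_sessions(cohort)
hp = LstmHyperParams(hidden_size=32, epochs=40, seed=0)

cells = [
    ("lstm", "position3d"),
    ("lstm", "velocity3d"),
    ("lstm", "position2d"),
    ("lstm", "velocity2d"),
    ("svm_linear", "static4_velocity"),
    ("rdf", "static4_velocity"),
    ("svm_linear", "clinical"),
    ("rdf", "clinical"),
]
frames = {}
for family, representation in cells:
    frames[(family, representation)] = duration_sweep(
        sessions, family, representation, ks=[5],
        n_replicates=4, n_folds=3, seed=67, lstm_hp=hp, experiment_id=4,
    )

df = pd.concat(frames.values(), ignore_index=True)
RESULTS.mkdir(exist_ok=True)
df.to_csv(RESULTS / "velocity_2d.csv", index=False)

accs = {
    key: replicate_accuracies(frame, family=key[0], representation=key[1])
    for key, frame in frames.items()
}
tests = []
for key, a in accs.items():
    r = ttest_vs_chance(a)
    tests.append(
        {"comparison": f"{key[0]}/{key[1]} vs chance", "stat": "t",
         "value": round(r.statistic, 2), "df": r.df, "p": r.p_value,
         "mean_acc": round(a.mean(), 3)}
    )
for pair in [
    (("lstm", "velocity3d"), ("lstm", "position3d")),
    (("lstm", "velocity2d"), ("lstm", "velocity3d")),
    (("lstm", "position2d"), ("lstm", "position3d")),
]:
    r = ftest_between(accs[pair[0]], accs[pair[1]])
    tests.append(
        {"comparison": f"{pair[0][1]} vs {pair[1][1]}", "stat": "F",
         "value": round(r.statistic, 2), "df": r.df, "p": r.p_value,
         "mean_acc": round(accs[pair[0]].mean() - accs[pair[1]].mean(), 3)}
    )

tests_df = pd.DataFrame(tests)
tests_df.to_csv(RESULTS / "stats_tests.csv", index=False)
print(tests_df.to_string(index=False))
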