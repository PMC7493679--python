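#!/usr/bin/env python
"""Validate the clinical-metric extractor against generator ground truth.

For zero-noise walkers the 12 spatiotemporal metrics have closed-form
values; this driver reports the relative recovery error of the headline
metrics (cadence, speed, stride length) plus the default-noise robustness.
"""

import numpy as np
import pandas as pd

from common import RESULTS, demo_cohort
from gaitlab.features import clinical_metrics, detect_gait_events
from gaitlab.synthetic_gait import generate_walk, ground_truth_metrics

rows = []
cohort = demo_cohort(n_male=15, n_female=15, seed=31)
for noise, tag in [(0.0, "zero-noise"), (0.005, "5 mm jitter")]:
    for i, subj in enumerate(cohort.subjects):
        subj.noise_sd = noise
        seq = generate_walk(subj, 10.0, 24.0, seed=400 + i)
        m = clinical_metrics(seq, detect_gait_events(seq))
        gt = ground_truth_metrics(subj)
        for key in ("cadence", "speed", "stride_length"):
            rows.append(
                {
                    "condition": tag,
                    "subject_id": subj.subject_id,
                    "metric": key,
                    "estimate": m[key],
                    "truth": gt[key],
                    "rel_err": abs(m[key] - gt[key]) / gt[key],
                }
            )

df = pd.DataFrame(rows)
RESULTS.mkdir(exist_ok=True)
df.to_csv(RESULTS / "metric_recovery.csv", index=False)

table = (
    df.groupby(["condition", "metric"])["rel_err"]
    .agg(median_rel_err="median", p90_rel_err=lambda x: np.quantile(x, 0.9))
    .round(4)
)
print(table)
print("\nzero-noise median relative error stays below 5% for all three metrics"
      if table.loc["zero-noise"]["median_rel_err"].max() < 0.05
      else "\nWARNING: recovery above 5%")
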