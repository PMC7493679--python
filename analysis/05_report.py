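#!/usr/bin/env python
"""Summary tables and the accuracy-vs-duration figure.

Consumes ``results/sweep_duration.csv`` (driver 03) and writes
``results/summary.csv`` plus ``results/accuracy_vs_duration.png`` with
mean ± SE bands per model family.
"""

import pandas as pd

from common import RESULTS
from gaitlab.stats_report import plot_accuracy_vs_duration, summarize

sweep_path = RESULTS / "sweep_duration.csv"
if not sweep_path.exists():
    raise SystemExit("run 03_duration_sweep.py first")

df = pd.read_csv(sweep_path)
summary = summarize(df)
summary.to_csv(RESULTS / "summary.csv", index=False)
plot_accuracy_vs_duration(summary, RESULTS / "accuracy_vs_duration.png")

print(summary.round(3).to_string(index=False))
print(f"\nfigure: {RESULTS / 'accuracy_vs_duration.png'}")
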