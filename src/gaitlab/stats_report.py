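"""Statistical comparisons and summary reporting for sweep results.

Two test families are used when comparing classifier cohorts:

* a one-sample two-tailed t-test of per-replicate accuracies against
  chance (0.5 for binary gender), and
* a variance-ratio F-test between two cohorts of accuracies,
  ``F = s_A^2 / s_B^2`` with ``(n_A - 1, n_B - 1)`` degrees of freedom and
  a two-tailed p-value.

The F statistic here is the ratio-of-variances construction (the reading
consistent with cohort-sized degrees of freedom); a Welch mean-comparison
alternative is available behind ``mean_test=True`` without endorsement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["TestResult", "ttest_vs_chance", "ftest_between", "summarize",
           "plot_accuracy_vs_duration"]


@dataclass
class TestResult:
    statistic: float
    df: tuple  # (df,) for t, (df1, df2) for F
    p_value: float
    group_means: tuple
    group_sizes: tuple
    flag: str = ""

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def ttest_vs_chance(accuracies, chance: float = 0.5) -> TestResult:
    """One-sample two-tailed t-test of accuracies against chance level.

    ``t = (mean - chance) / (s / sqrt(n))`` with ``df = n - 1``. A
    zero-variance sample is flagged: p is 0 when the mean differs from
    chance and 1 otherwise (sign convention, not a computed tail).
    """
    a = np.asarray(accuracies, dtype=float)
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 accuracy values")
    mean = a.mean()
    s = a.std(ddof=1)
    if s <= 1e-12 * max(1.0, abs(mean)):
        return TestResult(
            statistic=np.inf if mean != chance else 0.0,
            df=(n - 1,),
            p_value=0.0 if mean != chance else 1.0,
            group_means=(mean,),
            group_sizes=(n,),
            flag="zero-variance sample",
        )
    t = (mean - chance) / (s / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return TestResult(
        statistic=float(t), df=(n - 1,), p_value=float(p),
        group_means=(float(mean),), group_sizes=(n,),
    )


def ftest_between(group_a, group_b, mean_test: bool = False) -> TestResult:
    """Two-tailed variance-ratio F-test between two accuracy cohorts.

    ``F = s_A^2 / s_B^2``, df ``(n_A - 1, n_B - 1)``; the two-tailed p is
    twice the smaller tail. With ``mean_test=True`` a Welch t-test of the
    means is returned instead (statistic is Welch t, df approximate).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 values")
    means = (float(a.mean()), float(b.mean()))
    sizes = (len(a), len(b))
    if mean_test:
        t, p = stats.ttest_ind(a, b, equal_var=False)
        # Welch-Satterthwaite df
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        df = (va + vb) ** 2 / (
            va**2 / (len(a) - 1) + vb**2 / (len(b) - 1)
        )
        return TestResult(float(t), (float(df),), float(p), means, sizes,
                          flag="welch mean comparison")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    df = (len(a) - 1, len(b) - 1)
    if vb == 0:
        return TestResult(np.inf, df, 0.0 if va > 0 else 1.0, means, sizes,
                          flag="zero denominator variance")
    F = va / vb
    cdf = stats.f.cdf(F, *df)
    p = float(min(1.0, 2.0 * min(cdf, 1.0 - cdf)))
    return TestResult(float(F), df, p, means, sizes)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Mean accuracy ± SE per (family, representation, window) cell.

    Replicate accuracies (predictions pooled over folds within a
    replicate) are the unit of analysis; SE is over replicates and is NaN
    (reported absent) for a single replicate.
    """
    if len(results) == 0:
        raise ValueError("empty results")
    per_rep = (
        results.groupby(["family", "representation", "window_k", "replicate"])
        .apply(
            lambda g: g["n_correct"].sum() / g["n_test"].sum(),
            include_groups=False,
        )
        .rename("accuracy")
        .reset_index()
    )
    def se(x):
        x = np.asarray(x, dtype=float)
        if len(x) < 2:
            return np.nan
        return x.std(ddof=1) / np.sqrt(len(x))

    out = (
        per_rep.groupby(["family", "representation", "window_k"])["accuracy"]
        .agg(mean_accuracy="mean", se_accuracy=se, n_replicates="count")
        .reset_index()
    )
    return out


def replicate_accuracies(results: pd.DataFrame, **filters) -> np.ndarray:
    """Pooled per-replicate accuracies for one sweep cell (helper)."""
    df = results
    for col, val in filters.items():
        df = df[df[col] == val]
    if len(df) == 0:
        raise ValueError(f"no rows match {filters}")
    per_rep = df.groupby("replicate").apply(
        lambda g: g["n_correct"].sum() / g["n_test"].sum(), include_groups=False
    )
    return per_rep.to_numpy(dtype=float)


def plot_accuracy_vs_duration(summary: pd.DataFrame, path) -> None:
    """Accuracy-vs-duration curves with a shaded ±SE band per model cell."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for (family, representation), g in summary.groupby(["family", "representation"]):
        g = g.sort_values("window_k")
        dur = 0.4 * g["window_k"].to_numpy(dtype=float)
        m = g["mean_accuracy"].to_numpy() * 100
        se = g["se_accuracy"].to_numpy() * 100
        label = f"{family} ({representation})"
        ax.plot(dur, m, marker="o", label=label)
        if np.all(np.isfinite(se)):
            ax.fill_between(dur, m - se, m + se, alpha=0.2)
    ax.axhline(50, color="gray", ls="--", lw=1, label="chance")
    ax.set_xlabel("exposure duration (s)")
    ax.set_ylabel("accuracy (%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fig.savefig(path, dpi=120)
    plt.close(fig)
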