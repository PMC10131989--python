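"""Optional figures: difference histograms and Bland-Altman panels."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .agreement import BlandAltmanResult


def plot_difference_hist(paired: pd.DataFrame, label: str = "", ax=None):
    """Histogram of keyboard-minus-diary differences for one metric pair.

    Negative values: keyboard earlier / shorter than self-report.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    diffs = (paired["keyboard"] - paired["diary"]).dropna()
    ax.hist(diffs, bins=40, color="#4878d0", edgecolor="white")
    ax.axvline(0.0, color="k", linestyle="--", linewidth=1)
    ax.set_xlabel("difference (h)")
    ax.set_ylabel("nights")
    ax.set_title(label)
    return ax


def plot_bland_altman(paired: pd.DataFrame, result: BlandAltmanResult,
                      label: str = "", ax=None):
    """Repeated-measures Bland-Altman: per-night differences vs pair means,
    with the model bias and limits of agreement."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    df = paired.dropna(subset=["keyboard", "diary"])
    mean_h = 0.5 * (df["keyboard"] + df["diary"])
    diff_h = df["keyboard"] - df["diary"]
    ax.scatter(mean_h, diff_h, s=6, alpha=0.3, color="#4878d0")
    for yv, style in ((result.bias, "-"), (result.loa_lower, "--"),
                      (result.loa_upper, "--")):
        ax.axhline(yv, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("mean of modalities (night-axis h)")
    ax.set_ylabel("keyboard - diary (h)")
    ax.set_title(label)
    return ax
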