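"""Prediction-probability plots.

One marker per held-out sample at its mean jackknife probability, a
vertical error bar spanning the per-sample 95% CI, samples grouped by
true class along the x-axis, and a horizontal reference line at the
classification threshold.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def render_prediction_probability_plot(
    records: pd.DataFrame,
    threshold: float = 0.5,
    path=None,
    class_names: tuple[str, str] = ("negative", "positive"),
):
    """Render the plot; returns the matplotlib figure (saved if ``path``)."""
    required = {"ci_low", "ci_high", "jackknife_mean"}
    if not required.issubset(records.columns):
        raise ValueError(
            "records lack jackknife summaries; run the conservative estimator "
            "(attach_jackknife) first"
        )
    rec = records.sort_values(["true_label", "sample_id"]).reset_index(drop=True)
    x = np.arange(len(rec))
    mean = rec["jackknife_mean"].to_numpy(float)
    lo = mean - rec["ci_low"].to_numpy(float)
    hi = rec["ci_high"].to_numpy(float) - mean
    colors = np.where(rec["true_label"] == 0, "tab:blue", "tab:red")
    fig, ax = plt.subplots(figsize=(max(6, len(rec) * 0.3), 4))
    ax.errorbar(x, mean, yerr=[lo, hi], fmt="none", ecolor="gray", capsize=2, lw=1)
    for lab, color, name in ((0, "tab:blue", class_names[0]), (1, "tab:red", class_names[1])):
        m = rec["true_label"] == lab
        ax.plot(x[m], mean[m], "o", color=color, label=name)
    ax.axhline(threshold, color="black", ls="--", lw=1)
    ax.set_xticks(x)
    ax.set_xticklabels(rec["sample_id"], rotation=90, fontsize=6)
    ax.set_ylabel("prediction probability")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(Path(path), dpi=150)
        plt.close(fig)
    return fig
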