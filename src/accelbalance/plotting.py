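"""Bland-Altman agreement plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .validity_stats import ValiditySummary


def bland_altman_plot(errors: pd.DataFrame, summary: ValiditySummary, ax=None):
    """Bias vs criterion scatter with mean-bias and limits-of-agreement
    lines, one panel per method (mirrors the standard repeated-measures
    agreement layout)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for _, grp in errors.groupby("participant"):
        ax.plot(grp["criterion"], grp["bias"], "o", ms=4, alpha=0.6)
    ax.axhline(summary.mean_bias, color="k", lw=1.2, label="mean bias")
    ax.axhline(summary.loa_low, color="k", lw=1, ls="--", label="95% LoA")
    ax.axhline(summary.loa_high, color="k", lw=1, ls="--")
    ax.set_xlabel("criterion EI (kcal/day)")
    ax.set_ylabel("bias, predicted − criterion (kcal/day)")
    ax.set_title(summary.method)
    ax.legend(loc="best", fontsize=8)
    return ax
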