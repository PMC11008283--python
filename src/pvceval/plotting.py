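"""Publication-style figures for the method evaluation."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from pvceval.lmem import MethodEvaluation, T_SIGNIFICANT

__all__ = ["plot_tradeoff", "plot_change_heatmap"]

_MARKERS = ["o", "s", "^", "D", "v", "P", "X", "*", "h"]


def plot_tradeoff(evaluation: MethodEvaluation, ax=None):
    """Scatter of contrast t-score vs residual %CV, one color per method,
    one marker per ROI; filled markers mark significant contrasts."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    table = evaluation.table
    rois = list(dict.fromkeys(table["roi"]))
    methods = list(dict.fromkeys(table["method"]))
    colors = plt.cm.tab10.colors
    for mi, method in enumerate(methods):
        for ri, roi in enumerate(rois):
            sel = table[(table["method"] == method) & (table["roi"] == roi)]
            if sel.empty:
                continue
            filled = sel["significant"].to_numpy()
            ax.scatter(
                sel.loc[filled, "residual_pct_cv"], sel.loc[filled, "t_score"],
                color=colors[mi % 10], marker=_MARKERS[ri % len(_MARKERS)], s=45,
                label=method if ri == 0 else None,
            )
            ax.scatter(
                sel.loc[~filled, "residual_pct_cv"], sel.loc[~filled, "t_score"],
                facecolors="none", edgecolors=colors[mi % 10],
                marker=_MARKERS[ri % len(_MARKERS)], s=45,
            )
    ax.axhline(T_SIGNIFICANT, color="gray", linestyle="--", linewidth=1)
    ax.set_xlabel("within-subject variability, residual %CV")
    ax.set_ylabel("group separation, t-score")
    ax.legend(fontsize=8, title="method")
    return ax.figure


def plot_change_heatmap(changes: pd.DataFrame, ax=None):
    """Heat map of annualized %change; expects a tidy frame with columns
    roi, group, pct_change."""
    pivot = changes.pivot(index="roi", columns="group", values="pct_change")
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(pivot.columns) + 3, 0.45 * len(pivot) + 2))
    im = ax.imshow(pivot.to_numpy(), cmap="RdBu_r", aspect="auto")
    ax.set_xticks(range(len(pivot.columns)), pivot.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(pivot.index)), pivot.index)
    for i in range(pivot.shape[0]):
        for j in range(pivot.shape[1]):
            ax.text(j, i, f"{pivot.iat[i, j]:.2f}", ha="center", va="center", fontsize=8)
    ax.figure.colorbar(im, ax=ax, label="%ΔSUVR / year")
    return ax.figure
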