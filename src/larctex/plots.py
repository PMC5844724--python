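"""Report figures: paired pre/early box plots and ROC curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .features import FEATURE_NAMES

__all__ = ["plot_paired_boxes", "plot_roc_curves"]


def plot_paired_boxes(
    cohort_avg: pd.DataFrame,
    path,
    parameters: tuple[str, ...] = FEATURE_NAMES,
) -> Path:
    """Box-and-whisker plots of each parameter at pre vs early nCRT."""
    n = len(parameters)
    fig, axes = plt.subplots(1, n, figsize=(2.2 * n, 3.2), squeeze=False)
    for ax, name in zip(axes[0], parameters):
        data = [
            cohort_avg.loc[cohort_avg.timepoint == tp, name].to_numpy()
            for tp in ("pre", "early")
        ]
        ax.boxplot(data, tick_labels=["pre", "early"])
        ax.set_title(name, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_roc_curves(curves: dict[str, pd.DataFrame], path, title: str = "") -> Path:
    """Overlayed empirical ROC curves (one per predictor)."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for name, pts in curves.items():
        ax.plot(pts["fpr"], pts["tpr"], label=name, lw=1.4)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    if title:
        ax.set_title(title, fontsize=10)
    ax.legend(fontsize=7, loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
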