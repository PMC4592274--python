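"""Optional figures: score histograms by risk group and overlaid ROC curves.

matplotlib is imported lazily so the analysis stack has no hard plotting
dependency.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def _plt():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def plot_score_histograms(scores, labels, path, score_name="corrected PSA risk score"):
    """Histograms of a score for high- vs low-risk subjects (Fig-1 style)."""
    plt = _plt()
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    fig, axes = plt.subplots(2, 1, figsize=(6, 6), sharex=True)
    bins = np.histogram_bin_edges(scores, bins=30)
    for ax, mask, title in ((axes[0], labels, "High risk"), (axes[1], ~labels, "Low risk")):
        ax.hist(scores[mask], bins=bins, color="steelblue", edgecolor="white")
        ax.set_title(f"{title} (n={int(mask.sum())})")
        ax.set_ylabel("Men")
    axes[1].set_xlabel(score_name)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_roc_overlay(curves: dict, path):
    """Overlay empirical ROC curves (Fig-2 style).

    ``curves`` maps a label to a :class:`~psacorrect.discrimination.ROCCurve`.
    """
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, 6))
    for label, curve in curves.items():
        ax.step(1 - curve.specificity, curve.sensitivity, where="post", label=label)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="chance")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("Sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
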