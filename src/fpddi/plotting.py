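"""ROC and PR curve plots for one or more metrics reports."""

from __future__ import annotations

from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .metrics import MetricsReport


def plot_roc(reports: Mapping[str, MetricsReport], path=None, ax=None):
    """Overlay ROC curves; legend shows each classifier's AUROC."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for name, report in reports.items():
        ax.plot(report.roc[:, 1], report.roc[:, 2],
                label=f"{name} (AUROC = {report.auroc:.4f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1.02)
    ax.legend(loc="lower right", fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_pr(reports: Mapping[str, MetricsReport], path=None, ax=None):
    """Overlay precision-recall curves; legend shows each classifier's AUPR."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for name, report in reports.items():
        ax.plot(report.pr[:, 1], report.pr[:, 2],
                label=f"{name} (AUPR = {report.aupr:.4f})")
    ax.set_xlabel("Recall")
    ax.set_ylabel("Precision")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1.02)
    ax.legend(loc="lower left", fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
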