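"""Plot helpers for entropy curves and classification score tables."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

__all__ = ["plot_entropy_curve", "plot_scores"]


def plot_entropy_curve(curve, cutoff_percent: float = 80.0, ax=None):
    """Mean and min-max band of subsample entropy vs sample size."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    ns = [n for n, *_ in curve]
    means = [m for _, m, _, _ in curve]
    los = [lo for *_, lo, _ in curve]
    his = [hi for *_, hi in curve]
    ax.fill_between(ns, los, his, alpha=0.3, label="range")
    ax.plot(ns, means, color="crimson", label="mean")
    ax.axhline(cutoff_percent, ls="--", color="grey", lw=0.8)
    ax.set_xlabel("sample size")
    ax.set_ylabel("% of full-set entropy")
    ax.legend(frameon=False)
    return ax


def plot_scores(reports, metric: str = "f1", ax=None):
    """Per-classifier score distributions (one box per classifier) for a
    list of evaluation reports, e.g. a hyperparameter sweep."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    by_clf: dict[str, list[float]] = {}
    for rep in reports:
        by_clf.setdefault(rep.classifier, []).append(getattr(rep, metric))
    names = sorted(by_clf)
    ax.boxplot([by_clf[n] for n in names], tick_labels=names)
    ax.set_ylabel(metric.replace("_", " "))
    ax.set_ylim(0, 1)
    return ax
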