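"""Diagnostic plots for the risk calculators (matplotlib)."""

from __future__ import annotations

import numpy as np


def plot_roc(scores, labels, ax=None, label=None):
    """Empirical ROC curve with the rank-statistic AUC in the legend."""
    import matplotlib.pyplot as plt

    from .riskmodel import roc_auc

    scores = np.asarray(scores, float)
    labels = np.asarray(labels, float)
    order = np.argsort(-scores, kind="mergesort")
    tp = np.cumsum(labels[order] == 1) / max((labels == 1).sum(), 1)
    fp = np.cumsum(labels[order] == 0) / max((labels == 0).sum(), 1)
    auc, _ = roc_auc(scores, labels)
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(np.r_[0, fp], np.r_[0, tp],
            label=f"{label + ', ' if label else ''}AUC = {auc:.3f}")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    return ax


def plot_calibration(probs, labels, groups: int = 10, ax=None):
    """Observed vs predicted event rate per risk decile."""
    import matplotlib.pyplot as plt

    probs = np.asarray(probs, float)
    labels = np.asarray(labels, float)
    order = np.argsort(probs, kind="mergesort")
    bins = np.array_split(order, groups)
    pred = [probs[b].mean() for b in bins if len(b)]
    obs = [labels[b].mean() for b in bins if len(b)]
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(pred, obs, "o-")
    ax.plot([0, max(pred + obs)], [0, max(pred + obs)], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("predicted probability")
    ax.set_ylabel("observed event rate")
    return ax
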