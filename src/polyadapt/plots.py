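"""Plotting helpers for the audit pipeline's standard figures."""

from __future__ import annotations

import numpy as np


def plot_tsds_curve(curve, ax=None):
    """Mean tSDS per significance-ordered bin (most significant at right)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(curve["mean_neglog10_p"], curve["mean_tsds"], s=10)
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel(r"mean $-\log_{10} p$ in bin")
    ax.set_ylabel("mean tSDS in bin")
    return ax


def plot_ldsc_bins(fit, bins, ax=None):
    """Binned means with the fitted LD Score regression line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(bins["mean_l2"], bins["mean_y"], s=14)
    xs = np.linspace(bins["mean_l2"].min(), bins["mean_l2"].max(), 50)
    ax.plot(xs, fit.intercept + fit.slope * xs, color="C1")
    ax.set_xlabel("LD Score")
    ax.set_ylabel("bin mean statistic")
    return ax


def plot_scores_vs_axis(scores, axis, axis_label="latitude", ax=None):
    """Population polygenic scores against a geographic axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(axis, scores.z)
    ax.axhline(scores.mu, color="grey", lw=0.8, ls="--")
    for x, y, name in zip(axis, scores.z, scores.populations):
        ax.annotate(name, (x, y), fontsize=7)
    ax.set_xlabel(axis_label)
    ax.set_ylabel("polygenic score")
    return ax
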