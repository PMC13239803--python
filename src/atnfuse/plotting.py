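"""Plots for fusion results: modality-weight stacks, prediction scatter,
component-correlation bars."""

from __future__ import annotations

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_modality_weights(results, ax=None):
    """Stacked bar of per-component normalized modality shares."""
    shares, degenerate = results.modality_weight_distribution()
    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, results.k * 0.25), 3.5))
    bottom = np.zeros(results.k)
    x = np.arange(results.k)
    for m, code in enumerate(results.model.dataset.modalities):
        h = np.where(degenerate, 0.0, shares[:, m])
        ax.bar(x, h, bottom=bottom, label=code)
        bottom += h
    ax.set_xlabel("component")
    ax.set_ylabel("modality share")
    ax.legend(fontsize=7, ncol=len(results.model.dataset.modalities))
    return ax


def plot_prediction(results, which="test", ax=None):
    """Predicted vs observed target on one split."""
    ds, sp = results.model.dataset, results.model.split
    idx = sp.indices(which)
    pred = results.predict(Z=results.loadings_for(which))
    obs = ds.target[idx]
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(obs, pred, s=12, alpha=0.7)
    lim = [min(obs.min(), pred.min()), max(obs.max(), pred.max())]
    ax.plot(lim, lim, ls="--", c="gray", lw=1)
    if obs.size >= 3 and obs.std() > 0:
        r = np.corrcoef(obs, pred)[0, 1]
        ax.set_title(f"{which}: r = {r:.2f}")
    ax.set_xlabel("observed target")
    ax.set_ylabel("predicted target")
    return ax


def plot_correlation_screen(screen, ax=None):
    """Per-component correlation bars, significant ones starred."""
    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, len(screen.r) * 0.2), 3))
    x = np.arange(len(screen.r))
    colors = np.where(screen.r >= 0, "tab:red", "tab:blue")
    ax.bar(x, screen.r, color=colors)
    for i in np.flatnonzero(screen.significant):
        ax.text(i, screen.r[i], "*", ha="center",
                va="bottom" if screen.r[i] >= 0 else "top")
    ax.axhline(0, c="k", lw=0.5)
    ax.set_xlabel("component")
    ax.set_ylabel("Pearson r")
    return ax
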