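"""Plots: clinical audiograms (inverted dB axis) and feature-array heatmaps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers may switch backends first

import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_arta", "plot_feature_array"]


def plot_arta(results, ax=None, clip_to_audiometer: bool = True):
    """ARTA in clinical orientation: threshold vs frequency, one line
    per prediction age, dB axis increasing downwards."""
    pred = results.predict(clip_to_audiometer=clip_to_audiometer)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    freqs = pred.columns.to_numpy(dtype=float)
    x = np.log2(freqs)
    for age, row in pred.iterrows():
        ax.plot(x, row.to_numpy(), marker="o", label=f"{age:g} y")
    ax.set_xticks(x)
    ax.set_xticklabels([f"{f:g}" for f in freqs])
    ax.set_xlabel("Frequency (kHz)")
    ax.set_ylabel("Threshold (dB HL)")
    ax.set_ylim(125, -15)  # inverted, worse hearing downwards
    ax.axhline(20, color="grey", lw=0.5, ls="--")
    ax.legend(title="Age", fontsize=8)
    ax.set_title("Age-related typical audiogram")
    return ax


def plot_feature_array(array, ax=None, title: str = "Threshold feature array"):
    """Heatmap of ARTA grid-point counts per (degree class, band)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    counts = array.counts
    im = ax.imshow(counts.to_numpy(), cmap="Blues")
    ax.set_xticks(range(len(counts.columns)), counts.columns)
    ax.set_yticks(range(len(counts.index)), counts.index)
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            ax.text(j, i, str(int(counts.iloc[i, j])), ha="center", va="center")
    ax.set_title(title)
    plt.colorbar(im, ax=ax, shrink=0.8)
    return ax
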