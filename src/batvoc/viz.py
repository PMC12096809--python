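"""Plotting hooks: FRA heat maps, confusion matrices, raster plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .patterns import ConfusionMatrix
from .tuning import FRA
from .units import SpikeTrainSet


def plot_fra(fra: FRA, ax=None):
    """Heat map of the frequency-response area (levels up, log frequency)."""
    ax = ax or plt.gca()
    im = ax.pcolormesh(fra.freqs_khz, fra.levels_db, fra.response, shading="nearest")
    ax.set_xscale("log")
    ax.set_xlabel("frequency (kHz)")
    ax.set_ylabel("level (dB SPL)")
    plt.colorbar(im, ax=ax, label="median driven spikes")
    return ax


def plot_confusion(cm: ConfusionMatrix, ax=None, title: str = ""):
    """Row-stochastic confusion matrix with probabilities annotated."""
    ax = ax or plt.gca()
    im = ax.imshow(cm.probs, vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(cm.labels)), cm.labels, rotation=45, ha="right")
    ax.set_yticks(range(len(cm.labels)), cm.labels)
    ax.set_xlabel("assigned")
    ax.set_ylabel("true")
    for i in range(len(cm.labels)):
        for j in range(len(cm.labels)):
            ax.text(j, i, f"{cm.probs[i, j]:.2f}", ha="center", va="center",
                    color="w" if cm.probs[i, j] < 0.6 else "k", fontsize=8)
    if title:
        ax.set_title(title)
    plt.colorbar(im, ax=ax, label="p(assigned)")
    return ax


def plot_raster(sts: SpikeTrainSet, ax=None, onset_ms: float | None = None):
    """Trial-by-trial spike raster for one stimulus."""
    ax = ax or plt.gca()
    for i, spikes in enumerate(sts.trials):
        ax.vlines(spikes, i + 0.6, i + 1.4, lw=0.8, color="k")
    if onset_ms is None:
        onset_ms = sts.protocol.pre_stimulus_ms
    ax.axvline(onset_ms, color="r", lw=0.8, ls="--")
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("trial")
    ax.set_ylim(0.5, sts.n_trials + 0.5)
    ax.set_title(sts.stimulus_id)
    return ax
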