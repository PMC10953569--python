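"""Figure rendering from already-computed tables (no recomputation here)."""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .io import SpikeTrainSet
from .metrics import BoxSummary, CorrelationMatrix

__all__ = ["plot_raster", "plot_heatmap", "plot_box", "plot_corr"]


def _save(fig, path) -> Path:
    path = Path(path)
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)
    return path


def plot_raster(spiketrains: SpikeTrainSet, path) -> Path:
    """Raster of spike times per channel; x-range spans the full duration."""
    fig, ax = plt.subplots(figsize=(8, 4))
    if spiketrains.n_spikes() == 0:
        warnings.warn("empty spike trains: rendering an empty raster", stacklevel=2)
    for y, (ch, ts) in enumerate(sorted(spiketrains.trains.items(), key=lambda kv: str(kv[0]))):
        if len(ts):
            ax.vlines(ts, y + 0.1, y + 0.9, lw=0.5, color="k")
    ax.set_xlim(0, spiketrains.duration)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("channel")
    return _save(fig, path)


def plot_heatmap(firing_map_df, path) -> Path:
    """Spatial firing map: one marker per electrode at its layout position."""
    fig, ax = plt.subplots(figsize=(5, 5))
    if len(firing_map_df) == 0:
        warnings.warn("empty firing map: rendering an empty figure", stacklevel=2)
    else:
        sc = ax.scatter(
            firing_map_df["x_um"], firing_map_df["y_um"],
            c=firing_map_df["value"], s=60, cmap="viridis",
        )
        fig.colorbar(sc, ax=ax, label="rate (Hz)")
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.set_aspect("equal")
    return _save(fig, path)


def plot_box(summaries: dict[str, BoxSummary], path) -> Path:
    """Box glyphs drawn directly from BoxSummary fields."""
    fig, ax = plt.subplots(figsize=(max(4, len(summaries)), 4))
    if not summaries:
        warnings.warn("no box summaries: rendering an empty figure", stacklevel=2)
    for i, (label, s) in enumerate(summaries.items()):
        ax.add_patch(
            plt.Rectangle((i - 0.3, s.q1), 0.6, s.iqr, fill=False, color="k")
        )
        ax.hlines(s.median, i - 0.3, i + 0.3, color="r")
        ax.vlines(i, s.whisker_low, s.q1, color="k")
        ax.vlines(i, s.q3, s.whisker_high, color="k")
        if len(s.outliers):
            ax.plot(np.full(len(s.outliers), i), s.outliers, "k.", ms=3)
    ax.set_xticks(range(len(summaries)), list(summaries.keys()))
    ax.relim()
    ax.autoscale_view()
    return _save(fig, path)


def plot_corr(matrix: CorrelationMatrix, path) -> Path:
    """Channel-wise correlation matrix image."""
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(matrix.values, vmin=-1, vmax=1, cmap="RdBu_r")
    fig.colorbar(im, ax=ax, label="correlation")
    ax.set_xlabel("channel")
    ax.set_ylabel("channel")
    return _save(fig, path)
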