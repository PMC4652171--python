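"""Rendering of projected maps, stroke overlays and histograms."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .projection import ProjectedMap
from .reference import TerritoryAtlas
from .segmentation import IntensityHistogram, SegmentationThresholds
from .territories import TERRITORIES


def plot_map(
    pmap: ProjectedMap,
    stroke_mask: Optional[np.ndarray] = None,
    ax: Optional[plt.Axes] = None,
    title: str = "",
):
    """Render a projected map (grayscale) with an optional red stroke overlay.

    Map-left is brain-left; top is superior.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 2.5))
    values = np.where(pmap.inside, pmap.values, np.nan)
    ax.imshow(values, cmap="gray", interpolation="nearest")
    if stroke_mask is not None:
        overlay = np.zeros((*pmap.values.shape, 4))
        overlay[stroke_mask.astype(bool)] = (1.0, 0.1, 0.1, 0.8)
        ax.imshow(overlay, interpolation="nearest")
    ax.set_title(title)
    ax.set_xticks([])
    ax.set_yticks([])
    return ax


def plot_atlas(atlas: TerritoryAtlas, ax: Optional[plt.Axes] = None):
    """Colour-coded territory reference map."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 2.5))
    shape = atlas.shape
    rgb = np.ones((*shape, 3))
    colors = plt.get_cmap("tab10")(np.linspace(0, 1, len(TERRITORIES)))[:, :3]
    for color, t in zip(colors, TERRITORIES):
        rgb[atlas.masks[t]] = color
    ax.imshow(rgb, interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    handles = [plt.Line2D([], [], marker="s", ls="", color=c, label=t)
               for c, t in zip(colors, TERRITORIES)]
    ax.legend(handles=handles, loc="lower center", ncol=5, fontsize=8)
    return ax


def plot_histogram(
    hist: IntensityHistogram,
    thresholds: Optional[SegmentationThresholds] = None,
    ax: Optional[plt.Axes] = None,
):
    """Intensity histogram with the two cut-off lines."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.bar(hist.centers, hist.counts, width=hist.bin_width, color="0.6")
    if thresholds is not None:
        ax.axvline(thresholds.background_cutoff, color="tab:blue",
                   label=f"background cut-off {thresholds.background_cutoff:.0f} a.u.")
        ax.axvline(thresholds.stroke_cutoff, color="tab:red",
                   label=f"stroke cut-off {thresholds.stroke_cutoff:.0f} a.u.")
        ax.legend(fontsize=8)
    ax.set_xlabel("diffusion level (a.u.)")
    ax.set_ylabel("voxel count")
    return ax


def save_figure(ax, path: str | Path) -> Path:
    path = Path(path)
    ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(ax.figure)
    return path
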