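"""Heatmaps of spatial response maps and max-achievable curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .response import SpatialResponseMap, VolumetricResponse, max_achievable_curve


def plot_spatial_map(srm: SpatialResponseMap, ax=None, cmap: str = "viridis"):
    """Color-coded (level × order) response matrix; missing cells blank."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(
        np.ma.masked_invalid(srm.values),
        origin="upper",
        cmap=cmap,
        aspect="auto",
        extent=(0.5, srm.values.shape[1] + 0.5, srm.values.shape[0] + 0.5, 0.5),
    )
    ax.set_xlabel("wavelet order n")
    ax.set_ylabel("decomposition level k")
    ax.set_xticks(srm.orders)
    ax.set_yticks(srm.levels)
    ax.set_title(f"{srm.metric} — {srm.family}, η={srm.eta:g}")
    plt.colorbar(im, ax=ax, label=srm.metric)
    return ax


def plot_max_achievable(vrs: dict[str, VolumetricResponse], ax=None):
    """Best-achievable metric value vs noise intensity η, one curve per family."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5.5, 4))
    for family, vr in vrs.items():
        ax.plot(vr.schedule.levels, max_achievable_curve(vr), marker="o", label=family)
    first = next(iter(vrs.values()))
    ax.set_xlabel("noise intensity η")
    ax.set_ylabel(f"best achievable {first.metric}")
    ax.legend(title="family")
    ax.grid(alpha=0.3)
    return ax
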