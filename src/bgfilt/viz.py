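"""Minimal barcode / dendrogram figures (requires matplotlib)."""

from __future__ import annotations

import numpy as np
from scipy.cluster import hierarchy

from .filtration import Barcode, MergeTree

__all__ = ["plot_barcode", "plot_dendrogram"]


def plot_barcode(bc: Barcode, ax=None, color="C0"):
    """Horizontal bars [0, death) per component, sorted by death."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    deaths = np.sort(bc.deaths)
    ax.barh(np.arange(bc.size), deaths, height=0.6, color=color)
    ax.set_xlim(0, 1)
    ax.set_xlabel("filtration value")
    ax.set_ylabel("component")
    ax.set_title(f"barcode ({bc.partition})")
    return ax


def plot_dendrogram(tree: MergeTree, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    hierarchy.dendrogram(tree.linkage, labels=list(tree.labels), ax=ax,
                         orientation="right", color_threshold=0.0)
    ax.set_xlabel("filtration value")
    return ax
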