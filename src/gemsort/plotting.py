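"""Raster and feature-space plots of sorting output."""
from __future__ import annotations

import numpy as np

from .core import SortResult
from .features import FeatureVector


def plot_raster(result: SortResult, sample_rate_hz: float = 30_000.0, ax=None):
    """Spike times per cluster, the standard readout of a sort."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    clusters = np.unique(result.cluster_ids)
    for row, cl in enumerate(clusters):
        t = result.peak_samples[result.cluster_ids == cl] / sample_rate_hz
        ax.vlines(t, row + 0.6, row + 1.4, lw=0.5)
    ax.set_yticks(np.arange(1, clusters.size + 1), [str(c) for c in clusters])
    ax.set_xlabel("time (s)")
    ax.set_ylabel("cluster")
    return ax


def plot_feature_space(features: list[FeatureVector], labels=None, ax=None):
    """Scatter of (channel feature, first PCA coefficient) per spike."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    pts = np.stack([f.vector for f in features])
    c = None if labels is None else np.asarray(labels)
    sc = ax.scatter(pts[:, 0], pts[:, 1], s=4, c=c, cmap="tab10")
    ax.set_xlabel("channel feature")
    ax.set_ylabel("$a_0$")
    return ax
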