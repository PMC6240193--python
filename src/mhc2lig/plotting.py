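"""Minimal matplotlib renderings: KL logo bars and length histograms.

These are diagnostic plots (per-position stacked letter heights and the
learned length preference), not publication-grade sequence logos.
"""
from __future__ import annotations

import numpy as np

from .alphabet import RESIDUES
from .footprint import LogoMatrix


def plot_logo(logo: LogoMatrix, ax=None, top_k: int = 4):
    """Bar rendering of a KL logo: per position, the ``top_k`` residues by
    absolute height are stacked (positive up, negative down) and labeled."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.0 + 0.6 * logo.n_positions, 3))
    for pos in range(logo.n_positions):
        heights = logo.heights[pos]
        order = np.argsort(-np.abs(heights))[:top_k]
        up = down = 0.0
        for idx in order:
            h = heights[idx]
            if h >= 0:
                ax.bar(pos, h, bottom=up, width=0.8)
                ax.text(pos, up + h / 2, RESIDUES[idx], ha="center",
                        va="center", fontsize=7)
                up += h
            else:
                ax.bar(pos, h, bottom=down, width=0.8)
                down += h
    ax.axhline(0.0, color="black", lw=0.5)
    ax.set_xlabel("position")
    ax.set_ylabel("bits")
    return ax


def plot_length_preference(lengths, ax=None, min_length: int = 11,
                           max_length: int = 19):
    """Histogram of peptide lengths (e.g. of the top-scoring predictions)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    lengths = np.asarray(lengths)
    bins = np.arange(min_length, max_length + 2) - 0.5
    ax.hist(lengths, bins=bins, rwidth=0.85)
    ax.set_xlabel("peptide length")
    ax.set_ylabel("count")
    return ax
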