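"""Plot rendering for the descriptive displays (optional outputs)."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .descriptives import ternary_coords  # noqa: E402

__all__ = ["plot_quintile_bars", "plot_ternary"]


def plot_quintile_bars(bars: pd.DataFrame, outcome: str, path=None):
    """Grouped bar chart of centred log-ratio heights per outcome quintile."""
    parts = list(bars.columns)
    q = np.arange(len(bars))
    width = 0.8 / len(parts)
    fig, ax = plt.subplots(figsize=(6, 3.2))
    for k, part in enumerate(parts):
        ax.bar(q + k * width, bars[part], width=width, label=part)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xticks(q + 0.4 - width / 2)
    ax.set_xticklabels([f"Q{i}" for i in bars.index])
    ax.set_ylabel("centred log-ratio")
    ax.set_title(outcome)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
    return fig


def plot_ternary(sample3, labels, path=None, max_points: int = 2000):
    """Scatter of 3-part compositions in barycentric coordinates."""
    xy = ternary_coords(np.atleast_2d(sample3)[:max_points])
    tri = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2], [0, 0]])
    fig, ax = plt.subplots(figsize=(4.5, 4.2))
    ax.plot(tri[:, 0], tri[:, 1], "k-", lw=1)
    ax.scatter(xy[:, 0], xy[:, 1], s=4, alpha=0.3)
    for (x, y), lab in zip([(0, 0), (1, 0), (0.5, np.sqrt(3) / 2)], labels):
        ax.annotate(lab, (x, y), ha="center",
                    va="top" if y == 0 else "bottom", fontsize=9)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
    return fig
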