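"""Presentation plots for grid summaries; nothing here is asserted against."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .catalysis import CatalystStrategy
from .experiment import GridSummary

__all__ = ["plot_mean_depths", "plot_separation_surface"]


def plot_mean_depths(summary: GridSummary, p_cat_values=None):
    """Line plots of mean depth vs word length, one panel per p_cat.

    Each panel overlays the four strategy x amplification combinations.
    """
    table = summary.table
    if p_cat_values is None:
        p_cat_values = sorted(table["p_cat"].unique())
    fig, axes = plt.subplots(
        1, len(p_cat_values), figsize=(4 * len(p_cat_values), 3.5),
        sharey=True, squeeze=False,
    )
    for ax, p in zip(axes[0], p_cat_values):
        for strategy in table["strategy"].unique():
            for amp in (False, True):
                sel = table[
                    np.isclose(table["p_cat"], p)
                    & (table["strategy"] == strategy)
                    & (table["amplification"] == amp)
                ].sort_values("length")
                if sel.empty:
                    continue
                label = f"{strategy}, {'amplified' if amp else 'baseline'}"
                ax.plot(sel["length"], sel["mean_depth"], marker="o",
                        markersize=3, label=label)
        ax.set_title(f"p_cat = {p}")
        ax.set_xlabel("word length")
    axes[0][0].set_ylabel("mean construction depth")
    axes[0][-1].legend(fontsize=7)
    fig.tight_layout()
    return fig


def plot_separation_surface(
    summary: GridSummary,
    strategy: CatalystStrategy | str = CatalystStrategy.UNIFORM_NO_REUSE,
    amplification: bool = True,
):
    """Surface of baseline-subtracted separation over p_cat x length."""
    strategy = CatalystStrategy(strategy).value
    table = summary.table
    sel = table[(table["strategy"] == strategy)
                & (table["amplification"] == amplification)]
    pivot = sel.pivot_table(index="p_cat", columns="length", values="separation")
    fig = plt.figure(figsize=(6, 4.5))
    ax = fig.add_subplot(111, projection="3d")
    L, P = np.meshgrid(pivot.columns.values, pivot.index.values)
    ax.plot_surface(P, L, pivot.values, cmap="viridis")
    ax.set_xlabel("p_cat")
    ax.set_ylabel("word length")
    ax.set_zlabel("separation from baseline")
    ax.set_title(f"{strategy}, {'amplified' if amplification else 'baseline'}")
    fig.tight_layout()
    return fig
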