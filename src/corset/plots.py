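"""Figure helpers: scatter with fit and confidence band, box plots, time profiles."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def scatter_with_fit(table, result, mode="2d", path=None, ax=None):
    """Fraction-vs-circularity scatter with the least-squares fit and 95% band."""
    col = f"cristae_frac_{mode}"
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3.2))
    x = table["circularity"].to_numpy()
    y = table[col].to_numpy()
    ax.scatter(x, y, s=12, alpha=0.6, color="#2c6fbb", edgecolors="none")
    if result.defined:
        grid = np.linspace(x.min(), x.max(), 100)
        fit, lo, hi = result.confidence_band(grid)
        ax.plot(grid, fit, color="k", lw=1.2)
        ax.fill_between(grid, lo, hi, color="k", alpha=0.15, lw=0)
        ax.set_title(
            f"r = {result.pearson_r:.2f}, p = {result.p_value:.2g}, "
            f"n = {result.n}", fontsize=9
        )
    ax.set_xlabel("circularity")
    ax.set_ylabel(f"[cristae/IMM]% ({mode})")
    if path:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax


def box_compare(comparison, values_by_group, path=None, ax=None):
    """Two-group box plot with Tukey whiskers (1.5×IQR)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(3, 3.2))
    ax.boxplot(
        list(values_by_group.values()),
        tick_labels=list(values_by_group.keys()),
        whis=1.5,
    )
    ax.set_ylabel(comparison.metric)
    ax.set_title(
        f"t = {comparison.t_statistic:.2f}, p = {comparison.p_value:.2g}",
        fontsize=9,
    )
    if path:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax


def time_profile(profile_table, path=None):
    """Fraction and circularity against time on twin axes."""
    fig, ax = plt.subplots(figsize=(4, 3))
    t = profile_table["timestamp"]
    ax.plot(t, profile_table["cristae_frac_2d"], "o-", color="#b3562c",
            label="[cristae/IMM]%")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("[cristae/IMM]%", color="#b3562c")
    ax2 = ax.twinx()
    ax2.plot(t, profile_table["circularity"], "s--", color="#2c6fbb",
             label="circularity")
    ax2.set_ylabel("circularity", color="#2c6fbb")
    if path:
        fig.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(fig)
    return fig
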