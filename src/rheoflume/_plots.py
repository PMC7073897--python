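"""Report figures: pool-type means with 95% CIs and temporal profiles."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .stats_pipeline import POOL_LEVELS, RESPONSE_TRANSFORMS

_RIVER_COLORS = {"Aripo": "tab:blue", "Turure": "tab:orange"}


def pool_means_figure(table: pd.DataFrame, path: Path) -> None:
    """Per-river pool means and 95% CIs for the four metrics, raw points in grey."""
    fig, axes = plt.subplots(2, 2, figsize=(9, 7), constrained_layout=True)
    for ax, resp in zip(axes.ravel(), RESPONSE_TRANSFORMS):
        for j, river in enumerate(sorted(table["river"].unique())):
            sub = table[table["river"] == river]
            xs, means, errs = [], [], []
            for i, pool in enumerate(POOL_LEVELS):
                y = sub.loc[sub["pool"] == pool, resp].to_numpy()
                if len(y) == 0:
                    continue
                x = i + (j - 0.5) * 0.25
                ax.plot(np.full(len(y), x), y, ".", color="0.7", ms=4, zorder=1)
                xs.append(x)
                means.append(y.mean())
                errs.append(1.96 * y.std(ddof=1) / np.sqrt(len(y)) if len(y) > 1 else 0)
            ax.errorbar(
                xs, means, yerr=errs, fmt="o", capsize=3,
                color=_RIVER_COLORS.get(river), label=river, zorder=2,
            )
        ax.set_xticks(range(len(POOL_LEVELS)), POOL_LEVELS)
        ax.set_title(resp)
    axes[0, 0].legend(frameon=False)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def profile_figure(profiles, smooths, path: Path) -> None:
    """Per-river temporal profiles (raw group means + fitted smooths with bands)."""
    fig, axes = plt.subplots(2, 1, figsize=(8, 7), sharex=True, constrained_layout=True)
    for ax, resp, label in zip(
        axes, ("zone", "alignment"), ("mean flow-zone score", "proportion aligned upstream")
    ):
        for p in profiles:
            series = p.mean_zone if resp == "zone" else p.mean_alignment
            color = _RIVER_COLORS.get(p.group)
            ax.plot(series, color=color, alpha=0.35, lw=0.8)
            if resp in smooths:
                frames, fitted, lo, hi = smooths[resp].curves[p.group]
                ax.plot(frames, fitted, color=color, lw=2, label=p.group)
                ax.fill_between(frames, lo, hi, color=color, alpha=0.2, lw=0)
        ax.set_ylabel(label)
    axes[0].legend(frameon=False)
    axes[1].set_xlabel("frame (1.5 per second)")
    fig.savefig(path, dpi=120)
    plt.close(fig)
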