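"""Minimal plots: a clustered correlation heatmap and an MR forest plot."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .correlate import cluster_correlation_matrix

__all__ = ["correlation_heatmap", "mr_forest_plot"]


def correlation_heatmap(assoc: pd.DataFrame, path: str | Path) -> None:
    """Clustered rho heatmap of an association table (row/column order from
    complete-linkage clustering)."""
    rows, cols = cluster_correlation_matrix(assoc)
    grid = assoc.pivot(index="feature_a", columns="feature_b", values="rho")
    grid = grid.loc[rows, cols].fillna(0.0)
    fig, ax = plt.subplots(figsize=(max(4, 0.25 * len(cols)),
                                    max(3, 0.25 * len(rows))))
    im = ax.imshow(grid.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks(range(len(cols)), cols, rotation=90, fontsize=6)
    ax.set_yticks(range(len(rows)), rows, fontsize=6)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def mr_forest_plot(instruments: pd.DataFrame, estimate: float,
                   path: str | Path) -> None:
    """Per-instrument Wald ratios with 95% CIs and the combined estimate."""
    fig, ax = plt.subplots(figsize=(5, 0.4 * len(instruments) + 1.5))
    y = np.arange(len(instruments))
    ax.errorbar(instruments["wald"], y, xerr=1.96 * instruments["wald_se"],
                fmt="o", color="k", capsize=2)
    ax.axvline(estimate, color="firebrick", ls="--", label="combined")
    ax.axvline(0.0, color="grey", lw=0.5)
    ax.set_yticks(y, instruments.index, fontsize=7)
    ax.set_xlabel("causal effect per exposure SD")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
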