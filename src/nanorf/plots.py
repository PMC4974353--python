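"""Static figure export: volcano plots, 2-D score scatters, heat maps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def volcano_figure(volcano: pd.DataFrame, path: str | Path, alpha: float = 0.05,
                   title: str = "") -> None:
    """Mean log2 ratio vs -log10 adjusted p, significant proteins highlighted."""
    fig, ax = plt.subplots(figsize=(5, 4))
    x = volcano["mean_log2_ratio"]
    y = -np.log10(volcano["p_adjusted"])
    sig = volcano["p_adjusted"] < alpha
    ax.scatter(x[~sig], y[~sig], s=6, c="0.6", lw=0)
    ax.scatter(x[sig], y[sig], s=8, c="crimson", lw=0)
    ax.axvline(0, color="0.3", lw=0.6)
    ax.set_xlabel("mean log2(knockout / wild-type)")
    ax.set_ylabel("-log10 adjusted p")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def scatter_figure(pairs: pd.DataFrame, path: str | Path,
                   name_a: str = "complex A", name_b: str = "complex B") -> None:
    """Two-dimensional RF-score scatter, training members coloured."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    unl = (pairs["label_a"] == "unlabeled") & (pairs["label_b"] == "unlabeled")
    ax.scatter(pairs.loc[unl, "score_a"], pairs.loc[unl, "score_b"],
               s=6, c="0.7", lw=0, label="unlabeled")
    for col, label, color in (("label_a", "positive", "crimson"),
                              ("label_b", "positive", "royalblue"),
                              ("label_a", "negative", "seagreen")):
        sel = pairs[col] == label
        if col == "label_b":
            sel &= pairs["label_a"] != "positive"
        ax.scatter(pairs.loc[sel, "score_a"], pairs.loc[sel, "score_b"],
                   s=14, c=color, lw=0)
    ax.set_xlabel(f"RF score: {name_a}")
    ax.set_ylabel(f"RF score: {name_b}")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def heatmap_figure(ordered_scores: pd.DataFrame, partition, path: str | Path) -> None:
    """Branch-ordered score heat map with branch boundaries marked."""
    fig, ax = plt.subplots(figsize=(4, 6))
    ax.pcolormesh(ordered_scores.to_numpy(float), cmap="viridis", vmin=0, vmax=1)
    branches = partition.assignment.loc[ordered_scores.index].to_numpy()
    bounds = np.flatnonzero(np.diff(branches)) + 1
    for b in bounds:
        ax.axhline(b, color="white", lw=0.5)
    ax.set_xticks(np.arange(len(ordered_scores.columns)) + 0.5)
    ax.set_xticklabels(ordered_scores.columns, rotation=90, fontsize=7)
    ax.set_yticks([])
    ax.set_ylabel(f"{len(ordered_scores)} proteins in {partition.n_branches} branches")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
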