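"""Small plotting helpers for the pipeline's standard figures."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_hit_scatter(hits: pd.DataFrame, ax=None, title: str | None = None):
    """Control-vs-mutant occupancy scatter with significant genes grayed,
    in the style of a PCA-regression hit plot."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ctrl = hits[[c for c in hits.columns if c.startswith("occ_ctrl_")]].mean(axis=1)
    mut = hits[[c for c in hits.columns if c.startswith("occ_mut_")]].mean(axis=1)
    sig = hits["significant"].to_numpy()
    ax.scatter(ctrl[~sig], mut[~sig], s=4, c="k", alpha=0.4, label="unchanged")
    ax.scatter(ctrl[sig], mut[sig], s=8, c="gray", edgecolors="red", linewidths=0.3,
               label="significant")
    lo = min(ctrl.min(), mut.min())
    hi = max(ctrl.max(), mut.max())
    ax.plot([lo, hi], [lo, hi], lw=0.8, c="steelblue")
    ax.set_xlabel("control occupancy (log2)")
    ax.set_ylabel("mutant occupancy (log2)")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=7)
    return ax


def plot_radial_profile(profiles: dict[str, np.ndarray], ax=None):
    """Periphery-to-center shell profiles, one line per labelled group."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    for label, prof in profiles.items():
        shells = np.arange(1, len(prof) + 1)
        ax.plot(shells, prof, marker="o", ms=3, label=label)
    ax.set_xlabel("radial shell (periphery → center)")
    ax.set_ylabel("normalized density / intensity")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_cluster_sizes(sizes_by_condition: dict[str, np.ndarray], ax=None):
    """Box plots of nucleoplasmic cluster sizes per tether strength."""
    if ax is None:
        _, ax = plt.subplots(figsize=(3, 3))
    labels = list(sizes_by_condition)
    ax.boxplot([sizes_by_condition[k] for k in labels], tick_labels=labels)
    ax.set_ylabel("nucleoplasmic H3K27me3 cluster size (beads)")
    return ax
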