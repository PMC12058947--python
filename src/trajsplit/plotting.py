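"""Publication-style figures: mean trajectories, sweep curve, velocity profiles."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .stepclass import SweepResult

__all__ = ["plot_mean_trajectories", "plot_sweep", "plot_velocity_profiles"]

_COND_COLORS = {"compatible": "tab:blue", "incompatible": "tab:red"}


def plot_mean_trajectories(ds, table: pd.DataFrame):
    """Condition-mean paths, all trials (left) vs. single-step only (right).

    Thin lines are participant averages of the time-normalized paths;
    thick lines the grand means across participants.
    """
    fig, axes = plt.subplots(1, 2, figsize=(10, 5), sharex=True, sharey=True)
    mask_all = ds.retained
    stages = [("all movements", mask_all), ("single-step only", mask_all & ~table["multistep"])]
    for ax, (title, mask) in zip(axes, stages):
        sub = table[mask]
        for cond, grp in sub.groupby("compatibility", sort=False, observed=True):
            color = _COND_COLORS.get(str(cond), "gray")
            per_part = []
            for _, pgrp in grp.groupby("participant", sort=False, observed=True):
                mean_path = np.nanmean(ds.points[pgrp.index.to_numpy()], axis=0)
                per_part.append(mean_path)
                ax.plot(mean_path[:, 0], mean_path[:, 1], color=color, alpha=0.15, lw=0.6)
            if per_part:
                grand = np.mean(per_part, axis=0)
                ax.plot(grand[:, 0], grand[:, 1], color=color, lw=2.5, label=str(cond))
        ax.set_title(title)
        ax.set_xlabel("x (px, flipped frame)")
    axes[0].set_ylabel("y (px)")
    axes[0].legend()
    fig.tight_layout()
    return fig


def plot_sweep(sweep: SweepResult):
    """Standardized compatibility effect size (dz) vs. cutoff fraction."""
    fig, ax = plt.subplots(figsize=(6, 4))
    f = sweep.frame
    ax.plot(f["fraction"] * 100, f["dz"], marker="o", ms=3)
    ax.axvline(sweep.default_fraction * 100, ls="--", color="gray",
               label="default cutoff (start-area edge)")
    ax.axhline(0, color="black", lw=0.5)
    ax.set_xlabel("allowed excursion toward wrong target (% of centre distance)")
    ax.set_ylabel(f"dz ({sweep.measure})")
    ax.legend()
    fig.tight_layout()
    return fig


def plot_velocity_profiles(profiles: dict):
    """Group-mean speed over normalized pre-MAD and post-MAD time."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    pct = None
    for group, (prof, n) in profiles.items():
        if pct is None or len(pct) != prof.m:
            pct = np.linspace(0, 100, prof.m)
        axes[0].plot(pct, prof.pre, label=f"{group} (n={n})")
        axes[1].plot(pct, prof.post, label=f"{group} (n={n})")
    axes[0].set_title("pre-MAD segment")
    axes[1].set_title("post-MAD segment")
    for ax in axes:
        ax.set_xlabel("normalized segment time (%)")
    axes[0].set_ylabel("speed (px/ms)")
    axes[0].legend()
    fig.tight_layout()
    return fig
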