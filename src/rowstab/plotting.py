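"""Optional matplotlib views of pipeline artifacts.

These reproduce the usual presentation of the analysis: per-trial overlays
of individual strokes around the mean curve, marker grids of the instability
index per participant/stage/grade, and group-level duration trends across
stages.  Plots are reporting aids, not analysis surfaces.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .stroke_stats import MeanStrokeProfile

_GRADE_STYLE = {1: ("o", "k"), 2: ("s", "tab:blue"), 3: ("D", "tab:red")}


def plot_stroke_overlay(
    profile: MeanStrokeProfile, windows: np.ndarray | None = None, ax=None
):
    """Mean stroke curve with a +/- SD band (and optional raw windows)."""
    if ax is None:
        _, ax = plt.subplots()
    if windows is not None:
        for w in windows:
            ax.plot(profile.grid, w, color="c", lw=0.5, alpha=0.5)
    ax.fill_between(
        profile.grid,
        profile.mean_curve - profile.std_curve,
        profile.mean_curve + profile.std_curve,
        color="c", alpha=0.3, label="+/- SD",
    )
    ax.plot(profile.grid, profile.mean_curve, "k", lw=1.5, label="mean stroke")
    ax.axhline(0.0, color="0.7", lw=0.5)
    ax.set_xlabel("time from stroke onset (s)")
    ax.set_ylabel(r"$\omega_x$ (rad/s)")
    ax.legend(frameon=False)
    return ax


def plot_stability_markers(stability: pd.DataFrame, ax=None):
    """Instability index (percent) per participant, marker-coded by grade."""
    if ax is None:
        _, ax = plt.subplots()
    participants = list(dict.fromkeys(stability["participant"]))
    xpos = {p: i for i, p in enumerate(participants)}
    for grade, cell in stability.groupby("grade"):
        marker, color = _GRADE_STYLE.get(grade, ("x", "0.4"))
        ax.plot(
            [xpos[p] for p in cell["participant"]], cell["index_percent"],
            marker, color=color, ls="none", label=f"grade {grade}",
        )
    ax.set_xticks(range(len(participants)), participants)
    ax.set_ylabel("STD/|mean| index (%)")
    ax.legend(frameon=False)
    return ax


def plot_group_trends(group: pd.DataFrame, stages=None, axes=None):
    """Group-mean durations with SD whiskers across stages, one panel per
    quantity, marker-coded by grade."""
    if axes is None:
        _, axes = plt.subplots(1, 3, figsize=(11, 3.2), sharex=True)
    if stages is None:
        stages = list(dict.fromkeys(group["stage"]))
    xs = {s: i for i, s in enumerate(stages)}
    for ax, q, title in zip(
        axes, ("full", "phase1", "phase2"),
        ("full stroke", "phase 1 (drive)", "phase 2 (recovery)"),
    ):
        for grade, cell in group.groupby("grade"):
            marker, color = _GRADE_STYLE.get(grade, ("x", "0.4"))
            x = [xs[s] for s in cell["stage"]]
            ax.errorbar(
                x, cell[f"{q}_mean"], yerr=cell[f"{q}_sd"],
                fmt=marker, color=color, ls=":", capsize=3,
                label=f"grade {grade}",
            )
        ax.set_title(title)
        ax.set_xticks(range(len(stages)), stages)
        ax.set_ylabel("duration (s)")
    axes[0].legend(frameon=False)
    return axes
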