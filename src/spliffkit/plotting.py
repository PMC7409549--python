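"""Figure rendering: population conversion curves and call matrices."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .config import PHASES


def plot_population_curve(curve, traces: pd.DataFrame | None = None, ax=None,
                          label: str | None = None):
    """Conversion-vs-time panel: pooled single-cell points, loess line,
    95% band."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    if traces is not None:
        ax.plot(traces["time_min"], traces["fd_percent"], ".",
                color="0.7", ms=2, alpha=0.5, zorder=1)
    ax.fill_between(curve.grid, curve.ci_lower, curve.ci_upper,
                    color="tab:blue", alpha=0.2, lw=0, zorder=2)
    ax.plot(curve.grid, curve.fd_fit, "--", color="tab:blue",
            label=label or f"loess (n={curve.n_cells})", zorder=3)
    ax.set_xlabel("time after fusion (min)")
    ax.set_ylabel("conversion FD (%)")
    ax.legend(frameon=False)
    return ax


def plot_profile_matrix(calls_by_prey: dict[str, pd.DataFrame],
                        phase_boundaries: dict[str, tuple[float, float]] | None = None,
                        ax=None):
    """Interaction-profile matrix: one row per prey, filled boxes over the
    called windows with their significance stars."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 0.6 * len(calls_by_prey) + 1.5))
    preys = list(calls_by_prey)
    for yi, prey in enumerate(preys):
        calls = calls_by_prey[prey]
        for _, w in calls.iterrows():
            if w["called"]:
                ax.fill_between([w["t_start"], w["t_end"]], yi - 0.35, yi + 0.35,
                                color="tab:blue", alpha=0.9, lw=0)
                ax.text(0.5 * (w["t_start"] + w["t_end"]), yi, w["stars"],
                        ha="center", va="center", color="white", fontsize=6)
    if phase_boundaries:
        for phase in PHASES:
            if phase in phase_boundaries:
                start, end = phase_boundaries[phase]
                ax.axvline(start, color="0.6", lw=0.8, ls=":")
                ax.text(0.5 * (start + end), len(preys) - 0.3, phase,
                        ha="center", fontsize=8, color="0.3")
    ax.set_yticks(range(len(preys)), preys)
    ax.set_ylim(-0.6, len(preys) - 0.2 + 0.6)
    ax.set_xlabel("time after fusion (min)")
    return ax


def plot_frap_fit(normalized: pd.DataFrame, fit, ax=None):
    """Normalized recovery points with the fitted one-phase association."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    post = normalized[~normalized["prebleach_flag"].astype(bool)]
    t = post["time_s"].to_numpy(dtype=float)
    t0 = t - t[0]
    ax.plot(t0, post["normalized"], "o", ms=3, color="0.4")
    tt = np.linspace(0, t0.max(), 200)
    ax.plot(tt, fit.plateau * (1 - np.exp(-fit.rate_k * tt)), "-",
            color="tab:red",
            label=f"t$_{{1/2}}$ = {fit.t_half:.2f} s, P = {fit.plateau:.2f}")
    ax.set_xlabel("time after bleach (s)")
    ax.set_ylabel("normalized intensity")
    ax.legend(frameon=False)
    return ax
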