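"""FRAP normalization, one-phase association fitting, and group statistics.

A FRAP trace holds ROI and reference intensities per frame with a known
number of pre-bleach frames. Double normalization first divides the ROI by
the reference at each frame (correcting acquisition bleaching), then
rescales so the pre-bleach mean is 1 and the first post-bleach frame is 0.
The normalized recovery is fitted to a one-phase association

    F(t) = P · (1 − e^(−k·t)),  t = 0 at the first post-bleach frame,

whose plateau P is the mobile fraction and whose half-time is
t_1/2 = ln 2 / k.

Group comparisons follow the normality-routed scheme: distributions are
checked with the D'Agostino-Pearson test; two normal groups are compared by
t test, otherwise Mann-Whitney U; more than two groups by one-way ANOVA if
all normal, otherwise Kruskal-Wallis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import ValidationError

logger = logging.getLogger(__name__)

FRAP_COLUMNS = ["cell_id", "group", "time_s", "roi", "reference", "prebleach_flag"]

#: minimum fractional drop at the bleach frame for a trace to count as bleached
MIN_BLEACH_DEPTH = 0.05


class TraceRejected(ValueError):
    """Raised when a FRAP trace cannot be normalized."""


def double_normalize(trace: pd.DataFrame,
                     min_bleach_depth: float = MIN_BLEACH_DEPTH) -> pd.DataFrame:
    """Double-normalize one FRAP trace.

    Returns a copy with columns ``ratio`` (ROI/reference), ``normalized``
    (pre-bleach mean -> 1, first post-bleach frame -> 0) and
    ``flag_overshoot`` marking post-bleach values above the pre-bleach mean.
    Rejects traces with a non-positive reference frame or with no detectable
    bleach step (relative drop < ``min_bleach_depth``).
    """
    missing = [c for c in ("time_s", "roi", "reference", "prebleach_flag")
               if c not in trace.columns]
    if missing:
        raise ValidationError(f"FRAP trace missing columns {missing}")
    df = trace.sort_values("time_s").reset_index(drop=True).copy()
    if not df["time_s"].is_monotonic_increasing or df["time_s"].duplicated().any():
        raise ValidationError("frame times must be strictly increasing")
    if (df["reference"] <= 0).any():
        raise TraceRejected("non-positive reference frame")
    pre = df["prebleach_flag"].astype(bool).to_numpy()
    if pre.sum() < 1 or (~pre).sum() < 1:
        raise TraceRejected("need at least one pre- and one post-bleach frame")
    ratio = df["roi"].to_numpy(dtype=float) / df["reference"].to_numpy(dtype=float)
    pre_mean = float(ratio[pre].mean())
    if pre_mean <= 0:
        raise TraceRejected("non-positive pre-bleach level")
    first_post = float(ratio[~pre][0])
    depth = (pre_mean - first_post) / pre_mean
    if depth < min_bleach_depth:
        raise TraceRejected(
            f"no bleach detected (relative drop {depth:.3f} < {min_bleach_depth})"
        )
    normalized = (ratio - first_post) / (pre_mean - first_post)
    df["ratio"] = ratio
    df["normalized"] = normalized
    df["flag_overshoot"] = (~pre) & (ratio > pre_mean)
    return df


@dataclass
class FrapFit:
    """One-phase association fit of a normalized recovery."""

    rate_k: float  # per s
    plateau: float  # mobile fraction, normalized units
    t_half: float  # s, = ln 2 / rate_k
    residual_rms: float
    converged: bool
    n_points: int = 0


class OnePhaseAssociation:
    """Estimator for the one-phase association recovery F(t) = P(1 − e^(−kt)).

    ``fit(t, f)`` expects post-bleach times (seconds, 0 at the first
    post-bleach frame) and double-normalized intensities. Nonlinear least
    squares with multistart over the rate constant avoids local minima.

    Fitted attributes: ``rate_k_``, ``plateau_``, ``t_half_``,
    ``residual_rms_``, ``converged_``.
    """

    def __init__(self, min_points: int = 6, n_starts: int = 6):
        self.min_points = min_points
        self.n_starts = n_starts

    def get_params(self, deep: bool = True) -> dict:
        return {"min_points": self.min_points, "n_starts": self.n_starts}

    def set_params(self, **params) -> "OnePhaseAssociation":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    @staticmethod
    def _model(t, p, k):
        return p * (1.0 - np.exp(-k * t))

    def fit(self, t, f) -> "OnePhaseAssociation":
        t = np.asarray(t, dtype=float).ravel()
        f = np.asarray(f, dtype=float).ravel()
        ok = np.isfinite(t) & np.isfinite(f)
        t, f = t[ok], f[ok]
        if t.size < self.min_points:
            raise ValidationError(
                f"one-phase fit needs >= {self.min_points} post-bleach frames, "
                f"got {t.size}"
            )
        span = t.max() - t.min()
        if span <= 0:
            raise ValidationError("degenerate time axis")
        p0_plateau = float(np.clip(np.median(f[t >= t.max() - 0.2 * span]), 0.05, 2.0))
        k_grid = np.geomspace(0.1 / span, 50.0 / span, self.n_starts)
        best = None
        for k0 in k_grid:
            try:
                popt, _ = optimize.curve_fit(
                    self._model, t, f, p0=(p0_plateau, k0),
                    bounds=([0.0, 1e-8], [5.0, np.inf]), maxfev=5000,
                )
            except (RuntimeError, optimize.OptimizeWarning):
                continue
            rss = float(np.sum((f - self._model(t, *popt)) ** 2))
            if best is None or rss < best[0]:
                best = (rss, popt)
        if best is None:
            self.converged_ = False
            self.rate_k_ = self.plateau_ = self.t_half_ = np.nan
            self.residual_rms_ = np.nan
            return self
        rss, (p, k) = best
        self.converged_ = bool(k > 0)
        self.plateau_ = float(p)
        self.rate_k_ = float(k)
        self.t_half_ = math.log(2.0) / float(k)
        self.residual_rms_ = float(np.sqrt(rss / t.size))
        self.n_points_ = int(t.size)
        return self

    def predict(self, t) -> np.ndarray:
        return self._model(np.asarray(t, dtype=float), self.plateau_, self.rate_k_)

    def result(self) -> FrapFit:
        return FrapFit(
            rate_k=self.rate_k_, plateau=self.plateau_, t_half=self.t_half_,
            residual_rms=self.residual_rms_, converged=self.converged_,
            n_points=getattr(self, "n_points_", 0),
        )


def fit_one_phase(normalized: pd.DataFrame, min_points: int = 6) -> FrapFit:
    """Fit the post-bleach portion of a double-normalized trace."""
    post = normalized[~normalized["prebleach_flag"].astype(bool)]
    t = post["time_s"].to_numpy(dtype=float)
    t = t - t[0]  # origin at first post-bleach frame
    return OnePhaseAssociation(min_points=min_points).fit(
        t, post["normalized"].to_numpy(dtype=float)
    ).result()


def fit_traces(traces: pd.DataFrame, min_points: int = 6) -> pd.DataFrame:
    """Normalize and fit every cell in a long-format FRAP table.

    Returns one row per cell (rate_k, t_half, plateau, residual_rms,
    converged); rejected or non-converged cells are logged and excluded.
    """
    missing = [c for c in FRAP_COLUMNS if c not in traces.columns]
    if missing:
        raise ValidationError(f"FRAP table missing columns {missing}")
    rows = []
    for (cell_id, group), cell in traces.groupby(["cell_id", "group"], sort=False):
        try:
            norm = double_normalize(cell)
            fit = fit_one_phase(norm, min_points=min_points)
        except (TraceRejected, ValidationError) as err:
            logger.warning("cell %s rejected: %s", cell_id, err)
            continue
        if not fit.converged:
            logger.warning("cell %s: fit did not converge; excluded", cell_id)
            continue
        rows.append(
            {
                "cell_id": cell_id, "group": group,
                "rate_k": fit.rate_k, "t_half": fit.t_half,
                "plateau": fit.plateau, "residual_rms": fit.residual_rms,
                "n_points": fit.n_points,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group statistics


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(fits: pd.DataFrame, value: str = "t_half",
                   alpha: float = 0.05) -> dict:
    """Normality-routed comparison of per-cell fit values across groups.

    Groups with n < 3 are excluded with a warning. Normality uses the
    D'Agostino-Pearson omnibus test (requires n >= 8; smaller groups are
    treated as non-normal since the test is undefined there). Two groups:
    t test if both normal else Mann-Whitney U. More than two: one-way ANOVA
    if all normal else Kruskal-Wallis. Returns a JSON-serializable report
    with per-group mean ± SEM and the star-coded P-value.
    """
    groups: dict[str, np.ndarray] = {}
    report: dict = {"value": value, "groups": {}, "normality": {}}
    for label, sub in fits.groupby("group", sort=True):
        vals = sub[value].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size < 3:
            logger.warning("group %s excluded (n=%d < 3)", label, vals.size)
            continue
        groups[str(label)] = vals
        report["groups"][str(label)] = {
            "n": int(vals.size),
            "mean": float(vals.mean()),
            "sem": float(vals.std(ddof=1) / np.sqrt(vals.size)),
        }
    for label, vals in groups.items():
        if vals.size >= 8:
            stat, p = stats.normaltest(vals)
            normal = bool(p >= alpha)
            report["normality"][label] = {"p": float(p), "normal": normal}
        else:
            report["normality"][label] = {"p": None, "normal": False}
    if len(groups) < 2:
        report["test"] = None
        return report
    all_normal = all(v["normal"] for v in report["normality"].values())
    samples = list(groups.values())
    if len(groups) == 2:
        if all_normal:
            stat, p = stats.ttest_ind(*samples)
            name = "t test"
        else:
            stat, p = stats.mannwhitneyu(*samples, alternative="two-sided")
            name = "Mann-Whitney U"
    else:
        if all_normal:
            stat, p = stats.f_oneway(*samples)
            name = "one-way ANOVA"
        else:
            stat, p = stats.kruskal(*samples)
            name = "Kruskal-Wallis"
    report["test"] = {
        "name": name,
        "statistic": float(stat),
        "p_value": float(p),
        "stars": _stars(float(p)),
    }
    return report
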