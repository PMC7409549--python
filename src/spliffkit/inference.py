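"""Population-level interaction inference from pooled conversion traces.

Single-cell FD(t) traces are pooled across biological replicates and fitted
with a locally weighted quadratic regression (loess, tricube weights) to give
the population conversion curve with a pointwise 95% band. Interaction
timing is then read off sliding windows of two sampling intervals (three
consecutive grid points, advancing one point at a time): a linear trend is
fitted to the pooled replicate values inside each window (at this window
size the additive-model smooth degenerates to a straight line), giving a
slope in %conversion/min and a two-sided P-value.

A window is called an interaction when

* mean conversion (from the loess curve) < 70%: slope ≥ 1 %/min and P < α;
* mean conversion ≥ 70%: slope > 0 and P < α (near exhaustion of the
  uncleaved reporter the attainable slope shrinks, so only positivity and
  significance are required);

and the same criterion is NOT met by the non-interacting control in that
window (negative-control veto). Stars encode P < 0.001 / 0.01 / 0.05.
Windows whose mean conversion is ≥ 80% keep their call but carry an
interpretability caveat flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import PHASES, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_SPAN = 0.25
DEFAULT_ALPHA = 0.05
DEFAULT_SLOPE_FLOOR = 1.0  # % conversion / min
DEFAULT_CONVERSION_THRESHOLD = 70.0  # % — above this the floor is waived
DEFAULT_CAVEAT_THRESHOLD = 80.0


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "none"


# ---------------------------------------------------------------------------
# loess


class LoessCurve:
    """Locally weighted polynomial regression (loess) with a pointwise band.

    At each evaluation point x0 the nearest ``ceil(span * n)`` observations
    get tricube weights w = (1 - (d/h)^3)^3 scaled by the span bandwidth h,
    and a degree-``degree`` polynomial is fitted by weighted least squares;
    the fitted value is the local intercept. The 95% band is the pointwise
    normal band fitted ± 1.96 · sigma · ||l(x0)||, where l(x0) is the
    equivalent-kernel (hat) vector and sigma^2 = RSS / (n − tr L) from the
    residuals at the observation points.

    Fitted attributes: ``x_``, ``y_`` (training data), ``sigma_``,
    ``effective_df_``.
    """

    def __init__(self, span: float = DEFAULT_SPAN, degree: int = 2):
        self.span = span
        self.degree = degree

    def get_params(self, deep: bool = True) -> dict:
        return {"span": self.span, "degree": self.degree}

    def set_params(self, **params) -> "LoessCurve":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, x, y) -> "LoessCurve":
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        n = x.size
        q = max(self.degree + 1, int(np.ceil(self.span * n)))
        if n < self.degree + 2 or n < q:
            raise ValidationError(
                f"loess needs at least {max(self.degree + 2, q)} points "
                f"(span {self.span}, degree {self.degree}); got {n}"
            )
        order = np.argsort(x, kind="stable")
        self.x_, self.y_ = x[order], y[order]
        self._q = q
        fitted, hat_diag = self._predict_with_hat(self.x_)
        resid = self.y_ - fitted
        trace_l = float(np.sum(hat_diag))
        dof = max(n - trace_l, 1.0)
        self.sigma_ = float(np.sqrt(np.sum(resid**2) / dof))
        self.effective_df_ = trace_l
        return self

    def _local_fit(self, x0: float) -> tuple[np.ndarray, np.ndarray]:
        """Return (hat vector l(x0), fitted-coefficient design) at x0."""
        d = np.abs(self.x_ - x0)
        h = np.partition(d, self._q - 1)[self._q - 1]
        if h <= 0:
            h = max(d.max(), 1.0)  # all points tied at x0: uniform weights
            w = np.ones_like(d)
        else:
            u = np.clip(d / h, 0.0, 1.0)
            w = (1.0 - u**3) ** 3
        dx = self.x_ - x0
        X = np.vander(dx, N=self.degree + 1, increasing=True)
        sw = np.sqrt(w)
        Xw = X * sw[:, None]
        # fitted value at x0 = first coefficient; solve via QR (lstsq)
        coef, *_ = np.linalg.lstsq(Xw, self.y_ * sw, rcond=None)
        # equivalent kernel: e0^T (Xw^T Xw)^+ Xw^T diag(sw)
        XtX = Xw.T @ Xw
        try:
            first_row = np.linalg.solve(XtX, np.eye(self.degree + 1)[:, 0])
        except np.linalg.LinAlgError:
            first_row = np.linalg.pinv(XtX)[:, 0]
        l_vec = (X @ first_row) * w
        return l_vec, coef

    def _predict_with_hat(self, xs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        fitted = np.empty(xs.size)
        hat_diag = np.empty(xs.size)
        for i, x0 in enumerate(xs):
            l_vec, coef = self._local_fit(float(x0))
            fitted[i] = coef[0]
            # hat diagonal only meaningful when xs are the training points
            hat_diag[i] = l_vec[i] if xs is self.x_ else np.nan
        return fitted, hat_diag

    def predict(self, xs) -> np.ndarray:
        xs = np.asarray(xs, dtype=float).ravel()
        return np.array([self._local_fit(float(x0))[1][0] for x0 in xs])

    def predict_band(self, xs, level: float = 0.95):
        """Fitted values with pointwise (lower, upper) confidence bounds."""
        xs = np.asarray(xs, dtype=float).ravel()
        z = stats.norm.ppf(0.5 + level / 2.0)
        fitted = np.empty(xs.size)
        se = np.empty(xs.size)
        for i, x0 in enumerate(xs):
            l_vec, coef = self._local_fit(float(x0))
            fitted[i] = coef[0]
            se[i] = self.sigma_ * np.linalg.norm(l_vec)
        return fitted, fitted - z * se, fitted + z * se


@dataclass
class PopulationCurve:
    """Loess-pooled population conversion curve on a common time grid."""

    grid: np.ndarray
    fd_fit: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_cells: int
    span: float


def pool_and_fit_loess(traces: pd.DataFrame, span: float = DEFAULT_SPAN,
                       grid_interval: float | None = None) -> PopulationCurve:
    """Pool all cells' (time, FD) points and fit the population loess curve.

    The common grid runs over the union of the cells' time ranges at the
    finest sampling interval present (or ``grid_interval`` if given).
    Requires ≥ 2 cells with ≥ 4 post-fusion timepoints each.
    """
    valid = traces[~traces["fd_percent"].isna()]
    counts = valid.groupby("cell_id")["time_min"].nunique()
    usable = counts[counts >= 4]
    if usable.size < 2:
        raise ValidationError(
            "population fit needs >= 2 cells with >= 4 timepoints each; "
            f"got {usable.size}"
        )
    pooled = valid[valid["cell_id"].isin(usable.index)]
    x = pooled["time_min"].to_numpy(dtype=float)
    y = pooled["fd_percent"].to_numpy(dtype=float)
    if grid_interval is None:
        diffs = (
            pooled.sort_values(["cell_id", "time_min"])
            .groupby("cell_id")["time_min"]
            .diff()
            .dropna()
        )
        grid_interval = float(diffs.min()) if diffs.size else 1.0
    grid = np.round(
        np.arange(x.min(), x.max() + grid_interval / 2.0, grid_interval), 9
    )
    model = LoessCurve(span=span, degree=2).fit(x, y)
    fitted, lo, hi = model.predict_band(grid)
    return PopulationCurve(
        grid=grid, fd_fit=fitted, ci_lower=lo, ci_upper=hi,
        n_cells=int(usable.size), span=span,
    )


# ---------------------------------------------------------------------------
# sliding-window slopes


def sliding_window_slopes(curve: PopulationCurve, traces: pd.DataFrame,
                          window_points: int = 3) -> pd.DataFrame:
    """Per-window linear trend of pooled replicate FD values.

    Windows span ``window_points`` consecutive grid points (default 3 =
    two sampling intervals) and advance one grid point at a time. Slope and
    two-sided P-value come from the ordinary least-squares trend over all
    replicate points whose time falls inside the window (inclusive
    endpoints); mean_conversion is the loess curve averaged over the
    window's grid points. Windows with < 2 distinct times are skipped.
    """
    if curve.grid.size < window_points:
        raise ValidationError(
            f"grid has {curve.grid.size} points; need >= {window_points}"
        )
    valid = traces[~traces["fd_percent"].isna()]
    t = valid["time_min"].to_numpy(dtype=float)
    fd = valid["fd_percent"].to_numpy(dtype=float)
    eps = 1e-9
    rows = []
    for i in range(curve.grid.size - window_points + 1):
        t0 = float(curve.grid[i])
        t2 = float(curve.grid[i + window_points - 1])
        mask = (t >= t0 - eps) & (t <= t2 + eps)
        tw, yw = t[mask], fd[mask]
        if np.unique(tw).size < 2:
            logger.warning("window (%.6g, %.6g) skipped: <2 distinct times", t0, t2)
            continue
        res = stats.linregress(tw, yw)
        mean_conv = float(np.mean(curve.fd_fit[i : i + window_points]))
        rows.append(
            {
                "t_start": t0,
                "t_end": t2,
                "slope": float(res.slope),
                "p_value": float(res.pvalue),
                "mean_conversion": mean_conv,
                "n_points": int(tw.size),
            }
        )
    return pd.DataFrame(rows)


def _meets_criterion(slope: float, p: float, mean_conv: float, alpha: float,
                     slope_floor: float, conversion_threshold: float) -> tuple[bool, str]:
    if not np.isfinite(p) or p >= alpha:
        return False, "not_significant"
    if mean_conv < conversion_threshold:
        if slope >= slope_floor:
            return True, "slope_floor_path"
        return False, "below_slope_floor"
    if slope > 0:
        return True, "high_conversion_path"
    return False, "non_positive_slope"


def call_interactions(slopes: pd.DataFrame,
                      control_slopes: pd.DataFrame | None = None,
                      alpha: float = DEFAULT_ALPHA,
                      slope_floor: float = DEFAULT_SLOPE_FLOOR,
                      conversion_threshold: float = DEFAULT_CONVERSION_THRESHOLD,
                      caveat_threshold: float = DEFAULT_CAVEAT_THRESHOLD) -> pd.DataFrame:
    """Apply the calling rules (and negative-control veto) per window."""
    if control_slopes is not None:
        merged = slopes.merge(
            control_slopes, on=["t_start", "t_end"], how="left",
            suffixes=("", "_ctrl"), indicator=True,
        )
        if (merged["_merge"] != "both").any():
            raise ValidationError("bait and control window grids do not match")
    else:
        logger.warning("no negative control supplied; control veto disabled")
        merged = slopes.copy()
    rows = []
    for _, w in merged.iterrows():
        ok, reason = _meets_criterion(
            w["slope"], w["p_value"], w["mean_conversion"],
            alpha, slope_floor, conversion_threshold,
        )
        called = ok
        if ok and control_slopes is not None and np.isfinite(w["p_value_ctrl"]):
            ctrl_ok, _ = _meets_criterion(
                w["slope_ctrl"], w["p_value_ctrl"], w["mean_conversion_ctrl"],
                alpha, slope_floor, conversion_threshold,
            )
            if ctrl_ok:
                called = False
                reason = "control_veto"
        rows.append(
            {
                "t_start": w["t_start"],
                "t_end": w["t_end"],
                "slope": w["slope"],
                "p_value": w["p_value"],
                "mean_conversion": w["mean_conversion"],
                "called": bool(called),
                "stars": significance_stars(w["p_value"]) if called else "none",
                "reason": reason,
                "flag_caveat": bool(w["mean_conversion"] >= caveat_threshold),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# profiles


def merge_called_windows(calls: pd.DataFrame) -> list[dict]:
    """Merge runs of adjacent called windows into interaction intervals."""
    intervals: list[dict] = []
    current = None
    for _, w in calls.sort_values("t_start").iterrows():
        if w["called"]:
            if current is not None and w["t_start"] <= current["end"] + 1e-9:
                current["end"] = max(current["end"], w["t_end"])
                current["windows"] += 1
                current["min_p"] = min(current["min_p"], w["p_value"])
            else:
                if current is not None:
                    intervals.append(current)
                current = {
                    "start": w["t_start"], "end": w["t_end"],
                    "windows": 1, "min_p": w["p_value"],
                }
        elif current is not None:
            intervals.append(current)
            current = None
    if current is not None:
        intervals.append(current)
    for iv in intervals:
        iv["stars"] = significance_stars(iv["min_p"])
    return intervals


def build_profile(calls_by_prey: dict[str, pd.DataFrame],
                  phase_boundaries: dict[str, tuple[float, float]]) -> dict:
    """Phase-partitioned interaction-profile matrix across bait-prey pairs.

    Returns a JSON-serializable dict: per prey, every window's call and the
    merged interaction intervals grouped by phase.
    """
    profile: dict = {"phases": {p: list(phase_boundaries[p])
                                for p in PHASES if p in phase_boundaries},
                     "preys": {}}
    for prey, calls in calls_by_prey.items():
        entry = {"windows": calls.to_dict(orient="records"), "intervals_by_phase": {}}
        intervals = merge_called_windows(calls)
        for phase in profile["phases"]:
            start, end = phase_boundaries[phase]
            in_phase = []
            for iv in intervals:
                lo = max(iv["start"], start)
                hi = min(iv["end"], end)
                if hi > lo:
                    in_phase.append({**iv, "start": lo, "end": hi})
            entry["intervals_by_phase"][phase] = in_phase
        profile["preys"][prey] = entry
    return profile


# ---------------------------------------------------------------------------
# recovery benchmark


@dataclass
class BenchmarkResult:
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int
    tn: int
    n_windows_scored: int
    n_windows_excluded: int


def recover_schedule_benchmark(calls: pd.DataFrame,
                               true_windows: list[tuple[float, float]],
                               sampling_interval: float,
                               boundary_tolerance_windows: int = 1) -> BenchmarkResult:
    """Score window calls against the true interaction windows.

    A window is labeled truly active when at least half of it overlaps the
    union of true windows. Windows overlapping a true boundary ± the
    tolerance (in sampling intervals) are excluded from scoring: at
    boundaries the truth is genuinely ambiguous (cell-to-cell timing jitter
    and the GFP-degradation lag both blur the transition by about one
    frame).
    """
    tol = boundary_tolerance_windows * sampling_interval
    tp = fp = fn = tn = excluded = 0
    for _, w in calls.iterrows():
        t0, t2 = w["t_start"], w["t_end"]
        near_boundary = any(
            (t0 - tol) < edge < (t2 + tol)
            for a, b in true_windows
            for edge in (a, b)
        )
        if near_boundary:
            excluded += 1
            continue
        overlap = sum(
            max(0.0, min(t2, b) - max(t0, a)) for a, b in true_windows
        )
        truth = overlap >= 0.5 * (t2 - t0)
        if truth and w["called"]:
            tp += 1
        elif truth:
            fn += 1
        elif w["called"]:
            fp += 1
        else:
            tn += 1
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return BenchmarkResult(
        precision=precision, recall=recall, f1=f1,
        tp=tp, fp=fp, fn=fn, tn=tn,
        n_windows_scored=tp + fp + fn + tn,
        n_windows_excluded=excluded,
    )


# ---------------------------------------------------------------------------
# estimator facade


class InteractionCaller:
    """End-to-end inference estimator: conversion traces -> calls + profile.

    ``fit(traces, control_traces)`` pools the traces, fits the loess
    population curve, estimates sliding-window slopes for bait (and
    control), and applies the calling rules.

    Fitted attributes: ``curve_``, ``slopes_``, ``control_slopes_``,
    ``calls_``.
    """

    def __init__(self, span: float = DEFAULT_SPAN, alpha: float = DEFAULT_ALPHA,
                 slope_floor: float = DEFAULT_SLOPE_FLOOR,
                 conversion_threshold: float = DEFAULT_CONVERSION_THRESHOLD,
                 caveat_threshold: float = DEFAULT_CAVEAT_THRESHOLD,
                 window_points: int = 3):
        self.span = span
        self.alpha = alpha
        self.slope_floor = slope_floor
        self.conversion_threshold = conversion_threshold
        self.caveat_threshold = caveat_threshold
        self.window_points = window_points

    def get_params(self, deep: bool = True) -> dict:
        return {
            "span": self.span,
            "alpha": self.alpha,
            "slope_floor": self.slope_floor,
            "conversion_threshold": self.conversion_threshold,
            "caveat_threshold": self.caveat_threshold,
            "window_points": self.window_points,
        }

    def set_params(self, **params) -> "InteractionCaller":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, traces: pd.DataFrame,
            control_traces: pd.DataFrame | None = None) -> "InteractionCaller":
        self.curve_ = pool_and_fit_loess(traces, span=self.span)
        self.slopes_ = sliding_window_slopes(self.curve_, traces, self.window_points)
        if control_traces is not None:
            ctrl_curve = pool_and_fit_loess(control_traces, span=self.span)
            self.control_slopes_ = sliding_window_slopes(
                # evaluate control on the bait's grid so windows align
                PopulationCurve(
                    grid=self.curve_.grid,
                    fd_fit=LoessCurve(span=self.span, degree=2)
                    .fit(
                        control_traces["time_min"].to_numpy(dtype=float),
                        control_traces["fd_percent"].to_numpy(dtype=float),
                    )
                    .predict(self.curve_.grid),
                    ci_lower=np.nan * self.curve_.grid,
                    ci_upper=np.nan * self.curve_.grid,
                    n_cells=ctrl_curve.n_cells,
                    span=self.span,
                ),
                control_traces,
                self.window_points,
            )
        else:
            self.control_slopes_ = None
        self.calls_ = call_interactions(
            self.slopes_, self.control_slopes_,
            alpha=self.alpha, slope_floor=self.slope_floor,
            conversion_threshold=self.conversion_threshold,
            caveat_threshold=self.caveat_threshold,
        )
        return self

    def profile(self, phase_boundaries: dict[str, tuple[float, float]],
                prey: str = "prey") -> dict:
        return build_profile({prey: self.calls_}, phase_boundaries)
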