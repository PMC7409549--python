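"""Independent reference implementations used only to check the package.

These deliberately take different computational routes from the library:
the reporter-kinetics oracle uses the closed-form solution of the
constant-coefficient linear system (matrix exponential of the augmented
system), the loess oracle solves the weighted normal equations explicitly
per grid point, and the slope oracle uses the textbook OLS formulas with
the t distribution.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm
from scipy.stats import t as t_dist


def analytic_reporter_trajectory(config, schedule, times):
    """Closed-form U, R_c, G_c at ``times`` (minutes, >= 0) by propagating
    the augmented linear system [U, R, G, 1]' = M [U, R, G, 1] with
    exp(M dt) across the piecewise-constant segments."""
    times = np.asarray(times, dtype=float)
    boundaries = sorted(
        {0.0, float(schedule.total_duration)}
        | {float(x) for w in schedule.windows for x in w[:2]}
    )
    s = config.synthesis_rate
    d_r = config.reporter_degradation_rate
    d_g = config.gfp_degradation_rate

    def segment_matrix(k_cl):
        return np.array(
            [
                [-(k_cl + d_r), 0.0, 0.0, s],
                [k_cl, -d_r, 0.0, 0.0],
                [k_cl, 0.0, -d_g, 0.0],
                [0.0, 0.0, 0.0, 0.0],
            ]
        )

    state = np.array([config.initial_reporter, 0.0, 0.0, 1.0])
    out = np.empty((times.size, 3))
    out[times <= 0] = state[:3]
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        k_cl = (
            config.cleavage_rate_on
            if schedule.cleavage_active(0.5 * (a + b))
            else config.cleavage_rate_off
        )
        M = segment_matrix(k_cl)
        inside = (times > a) & (times <= b)
        for idx in np.nonzero(inside)[0]:
            out[idx] = (expm(M * (times[idx] - a)) @ state)[:3]
        state = expm(M * (b - a)) @ state
    return out[:, 0], out[:, 1], out[:, 2]


def brute_force_loess(x, y, x0, span, degree=2):
    """Loess fitted value at x0 via explicit weighted normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    q = max(degree + 1, int(np.ceil(span * n)))
    d = np.abs(x - x0)
    h = np.sort(d)[q - 1]
    w = np.zeros(n)
    if h > 0:
        u = np.minimum(d / h, 1.0)
        w = (1.0 - u**3) ** 3
    else:
        w[:] = 1.0
    X = np.column_stack([(x - x0) ** p for p in range(degree + 1)])
    W = np.diag(w)
    beta = np.linalg.inv(X.T @ W @ X) @ (X.T @ W @ y)
    return beta[0]


def ols_slope_with_p(t, y):
    """Closed-form OLS slope and two-sided P-value for slope != 0."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    n = t.size
    tbar, ybar = t.mean(), y.mean()
    sxx = np.sum((t - tbar) ** 2)
    slope = np.sum((t - tbar) * (y - ybar)) / sxx
    intercept = ybar - slope * tbar
    resid = y - intercept - slope * t
    s2 = np.sum(resid**2) / (n - 2)
    se = np.sqrt(s2 / sxx)
    if se == 0:
        return slope, 0.0
    tstat = slope / se
    p = 2.0 * t_dist.sf(abs(tstat), n - 2)
    return slope, p


def two_sample_t_p(a, b):
    """Closed-form pooled two-sample t statistic and two-sided P."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    tstat = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2.0 * t_dist.sf(abs(tstat), na + nb - 2)
    return tstat, p
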