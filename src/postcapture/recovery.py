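"""Recovery (rebound) times from centred smooths and their SE bands.

The fitted smooth of each capture method is centred on zero, so zero is the
individual-adjusted average of the metric.  The recovery time is the first
day the curve attains zero (or changes sign from its sign at t = 0), located
by linear interpolation on a fine grid; the interval comes from the zero
crossings of the f - SE and f + SE band curves.  A curve that never crosses
within the search horizon is censored and reported at the horizon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RecoveryEstimate", "crossing_time", "recovery_interval"]


@dataclass(frozen=True)
class RecoveryEstimate:
    metric: str  # "d_cog" | "step"
    method: str
    tau_days: float
    ci_low_days: float
    ci_high_days: float
    censored: bool
    horizon_days: float


def crossing_time(t_grid: np.ndarray, values: np.ndarray) -> float | None:
    """First time the curve attains zero, or ``None`` when censored.

    The reference sign is the sign at the start of the grid; the first grid
    interval where the value reaches zero or flips sign is interpolated
    linearly.  A curve starting exactly at zero returns the first grid time
    (already at average behaviour).
    """
    t = np.asarray(t_grid, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape or t.ndim != 1 or t.size == 0:
        raise ValueError("t_grid and values must be equal-length 1-d arrays")
    if not np.all(np.isfinite(v)):
        raise ValueError("curve values must be finite")
    if v[0] == 0.0:
        return float(t[0])
    s0 = np.sign(v[0])
    opposite = np.nonzero(s0 * v <= 0.0)[0]
    if opposite.size == 0:
        return None
    i = int(opposite[0])
    if v[i] == 0.0:
        return float(t[i])
    # linear interpolation between the bracketing grid points
    t0, t1 = t[i - 1], t[i]
    v0, v1 = v[i - 1], v[i]
    return float(t0 + (t1 - t0) * v0 / (v0 - v1))


def _round_tenth(x: float) -> float:
    return round(x * 10.0) / 10.0


def recovery_interval(
    t_grid: np.ndarray,
    f: np.ndarray,
    se: np.ndarray,
    metric: str = "",
    method: str = "",
) -> RecoveryEstimate:
    """Recovery estimate with a +/- 1 SE band interval.

    The point estimate is the zero crossing of f; the two band curves f - se
    and f + se each get their own crossing, the smaller becoming ci_low and
    the larger ci_high.  A band edge (or the point estimate) that never
    crosses within the grid is censored at the horizon (last grid time).
    The result is symmetric under a global sign flip of f.
    """
    t = np.asarray(t_grid, dtype=float)
    f = np.asarray(f, dtype=float)
    se = np.asarray(se, dtype=float)
    if not (t.shape == f.shape == se.shape):
        raise ValueError("t_grid, f and se must have identical shapes")
    if np.any(se < 0):
        raise ValueError("pointwise SEs must be non-negative")
    horizon = float(t[-1])

    tau = crossing_time(t, f)
    lo = crossing_time(t, f - se)
    hi = crossing_time(t, f + se)
    censored = tau is None
    band = sorted(horizon if c is None else c for c in (lo, hi))
    tau_val = horizon if censored else tau
    ci_low = min(band[0], tau_val)
    ci_high = max(band[1], tau_val)
    return RecoveryEstimate(
        metric=metric,
        method=method,
        tau_days=_round_tenth(tau_val),
        ci_low_days=_round_tenth(ci_low),
        ci_high_days=_round_tenth(ci_high),
        censored=censored,
        horizon_days=horizon,
    )
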