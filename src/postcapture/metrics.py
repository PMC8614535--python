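"""Response metrics per retained fix.

Two metrics describe post-release ranging behaviour: (i) the Euclidean
distance of each fix to the centre of gravity (COG) of all retained fixes in
the monitoring window, and (ii) the distance between successive retained
fixes ("step", attributed to the later fix).  Both are natural-log
transformed with a +1 m offset so that a distance of exactly zero maps to 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class UndefinedCOGError(ValueError):
    """Centre of gravity requested for an empty fix set."""


def centre_of_gravity(fixes: pd.DataFrame) -> tuple[float, float]:
    """Arithmetic mean (x, y) of the retained fixes."""
    if len(fixes) == 0:
        raise UndefinedCOGError("centre of gravity is undefined for zero fixes")
    return float(fixes["x_m"].mean()), float(fixes["y_m"].mean())


def log_transform(d_m) -> np.ndarray | float:
    """ln(d + 1) for non-negative distances in metres."""
    d = np.asarray(d_m, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    out = np.log1p(d)
    return float(out) if np.ndim(d_m) == 0 else out


def distance_series(
    fixes: pd.DataFrame,
    cog: tuple[float, float],
    capture: pd.Series | dict,
) -> pd.DataFrame:
    """Per-fix movement records for one regularized individual.

    Returns one row per retained fix: days since capture (real-valued),
    distance to the COG, step length from the previous retained fix (NaN for
    the first fix; steps are not divided by elapsed time), and the
    log-transforms of both.
    """
    t_capture = pd.Timestamp(capture["capture_time_utc"])
    if t_capture.tzinfo is None:
        t_capture = t_capture.tz_localize("UTC")
    x = fixes["x_m"].to_numpy(dtype=float)
    y = fixes["y_m"].to_numpy(dtype=float)
    t_days = (fixes["timestamp_utc"] - t_capture).dt.total_seconds().to_numpy() / 86400.0
    d_cog = np.hypot(x - cog[0], y - cog[1])
    step = np.full(len(fixes), np.nan)
    if len(fixes) > 1:
        step[1:] = np.hypot(np.diff(x), np.diff(y))
    out = pd.DataFrame(
        {
            "animal_id": fixes["animal_id"].to_numpy(),
            "site_id": fixes["site_id"].to_numpy(),
            "t_days": t_days,
            "x_m": x,
            "y_m": y,
            "d_cog_m": d_cog,
            "step_m": step,
        }
    )
    out["log_d_cog"] = log_transform(d_cog)
    with np.errstate(invalid="ignore"):
        out["log_step"] = np.log1p(step)
    return out


def movement_records(
    records: pd.DataFrame, capture: pd.Series | dict, log_hr: float
) -> pd.DataFrame:
    """Attach capture covariates and the log home-range covariate."""
    out = records.copy()
    out["method"] = capture["method"]
    out["sex"] = capture["sex"]
    out["age_class"] = capture["age_class"]
    out["log_hr"] = log_hr
    return out
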