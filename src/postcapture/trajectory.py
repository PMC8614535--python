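"""Fix/capture table IO, temporal regularization, and individual-level QC.

The study protocol retains at most six locations per 24 h (one per 4 h),
allows a maximum gap of 72 h between successive retained fixes (no
interpolation), and keeps individuals with at least 20 days of monitoring
whose first location falls within 3 days of capture.  Monitoring runs from
the capture to 15 April of the same capture season.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    AGE_CLASSES,
    METHODS,
    SEXES,
    SEASON_END_MD,
    SEASON_START_MD,
)
from .synthetic import monitoring_end_date

logger = logging.getLogger(__name__)

FIX_COLUMNS = ("animal_id", "site_id", "timestamp_utc", "x_m", "y_m")
CAPTURE_COLUMNS = ("animal_id", "site_id", "capture_time_utc", "method", "sex", "age_class")

EARTH_RADIUS_M = 6_371_008.8


class SchemaError(ValueError):
    """A CSV input violates the required schema (named row/column)."""


@dataclass(frozen=True)
class MonitoringWindow:
    """Capture-to-15-April observation window of one individual."""

    start: pd.Timestamp
    end: pd.Timestamp

    @property
    def length_days(self) -> float:
        return (self.end - self.start).total_seconds() / 86400.0


def monitoring_window(capture_time: pd.Timestamp) -> MonitoringWindow:
    capture_time = pd.Timestamp(capture_time)
    if capture_time.tzinfo is None:
        capture_time = capture_time.tz_localize("UTC")
    end_date = monitoring_end_date(capture_time.date())
    end = pd.Timestamp(dt.datetime.combine(end_date, dt.time(0, 0)), tz="UTC")
    return MonitoringWindow(start=capture_time, end=end)


def in_capture_season(capture_time: pd.Timestamp) -> bool:
    """True when the date falls in the 3 Oct – 25 Mar winter capture window."""
    md = (capture_time.month, capture_time.day)
    return md >= SEASON_START_MD or md <= SEASON_END_MD


def _parse_times(raw: pd.Series, path: str, column: str) -> pd.Series:
    try:
        return pd.to_datetime(raw, utc=True, format="ISO8601")
    except (ValueError, TypeError):
        pass
    # find the offending row for the error message
    parsed = pd.to_datetime(raw, utc=True, format="ISO8601", errors="coerce")
    bad = parsed.isna() & raw.notna()
    row = int(np.argmax(bad.to_numpy())) if bad.any() else 0
    raise SchemaError(
        f"{path}: unparsable timestamp in column {column!r} at data row {row}: {raw.iloc[row]!r}"
    )


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _check_vocab(df: pd.DataFrame, column: str, vocab: tuple[str, ...], path: str) -> None:
    bad = ~df[column].isin(vocab)
    if bad.any():
        row = int(np.argmax(bad.to_numpy()))
        raise SchemaError(
            f"{path}: unknown {column} label {df[column].iloc[row]!r} at data row {row}; "
            f"allowed: {list(vocab)}"
        )


def _drop_duplicate_times(df: pd.DataFrame, time_col: str, path: str) -> pd.DataFrame:
    dup = df.duplicated(subset=["animal_id", time_col], keep="first")
    if dup.any():
        logger.warning(
            "%s: collapsed %d duplicate (animal, timestamp) row(s) to first occurrence",
            path,
            int(dup.sum()),
        )
        df = df.loc[~dup]
    return df


def read_fixes(path) -> pd.DataFrame:
    """Read a fix table; validate schema; sort by animal and time.

    Duplicate (animal, timestamp) rows are collapsed to the first occurrence
    with a logged warning.
    """
    df = pd.read_csv(path)
    _require_columns(df, FIX_COLUMNS, str(path))
    df["timestamp_utc"] = _parse_times(df["timestamp_utc"], str(path), "timestamp_utc")
    for col in ("x_m", "y_m"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = ~np.isfinite(values.to_numpy(dtype=float))
        if bad.any():
            row = int(np.argmax(bad))
            raise SchemaError(f"{path}: non-finite {col} at data row {row}: {df[col].iloc[row]!r}")
        df[col] = values.astype(float)
    df = df.sort_values(["animal_id", "timestamp_utc"], kind="mergesort").reset_index(drop=True)
    df = _drop_duplicate_times(df, "timestamp_utc", str(path))
    return df.reset_index(drop=True)


def read_captures(path, strict_season: bool = True) -> pd.DataFrame:
    """Read a capture-event table; validate closed vocabularies and season."""
    df = pd.read_csv(path)
    _require_columns(df, CAPTURE_COLUMNS, str(path))
    df["capture_time_utc"] = _parse_times(df["capture_time_utc"], str(path), "capture_time_utc")
    _check_vocab(df, "method", METHODS, str(path))
    _check_vocab(df, "sex", SEXES, str(path))
    _check_vocab(df, "age_class", AGE_CLASSES, str(path))
    if strict_season:
        ok = df["capture_time_utc"].map(in_capture_season)
        if not ok.all():
            row = int(np.argmax(~ok.to_numpy()))
            raise SchemaError(
                f"{path}: capture_time_utc at data row {row} "
                f"({df['capture_time_utc'].iloc[row]}) outside the 3 Oct - 25 Mar capture season"
            )
    df = df.sort_values(["animal_id", "capture_time_utc"], kind="mergesort").reset_index(drop=True)
    dup = df.duplicated(subset=["animal_id"], keep="first")
    if dup.any():
        logger.warning("%s: %d duplicate capture row(s) dropped (first capture kept)", path, int(dup.sum()))
        df = df.loc[~dup].reset_index(drop=True)
    return df


def regularize(
    fixes: pd.DataFrame,
    capture: pd.Series | dict,
    bin_hours: float = 4.0,
    max_gap_hours: float = 72.0,
) -> pd.DataFrame:
    """Subsample one animal's fixes to the protocol's retention rules.

    Steps, in order:

    1. clip to the monitoring window [capture, 15 April of the season];
    2. partition time into consecutive ``bin_hours`` bins anchored at the
       capture timestamp and keep the earliest fix of each bin;
    3. enforce a minimum spacing of ``bin_hours`` between retained fixes
       (a kept fix closer than that to the previously kept one is dropped),
       so that every sliding 24-h window holds at most 24/bin_hours fixes;
    4. truncate the series at the first gap longer than ``max_gap_hours``
       between retained fixes — missing data are never interpolated.

    Empty input yields empty output.  The output is always a subset of the
    input rows and the operation is idempotent.
    """
    if len(fixes) == 0:
        return fixes.copy()
    t_capture = pd.Timestamp(capture["capture_time_utc"])
    if t_capture.tzinfo is None:
        t_capture = t_capture.tz_localize("UTC")
    window = monitoring_window(t_capture)

    fx = fixes.sort_values("timestamp_utc", kind="mergesort")
    times = fx["timestamp_utc"]
    fx = fx.loc[(times >= window.start) & (times <= window.end)]
    if len(fx) == 0:
        return fx.reset_index(drop=True)

    hours = (fx["timestamp_utc"] - t_capture).dt.total_seconds().to_numpy() / 3600.0
    bins = np.floor(hours / bin_hours).astype(np.int64)
    first_in_bin = np.ones(len(fx), dtype=bool)
    first_in_bin[1:] = bins[1:] != bins[:-1]
    fx = fx.loc[first_in_bin]
    hours = hours[first_in_bin]

    # minimum-spacing guard (tolerance for exact bin-interval spacing)
    keep_idx: list[int] = []
    last = -math.inf
    for i, h in enumerate(hours):
        if h - last >= bin_hours - 1e-9:
            keep_idx.append(i)
            last = h
    fx = fx.iloc[keep_idx]
    hours = hours[keep_idx]

    gaps = np.diff(hours)
    over = np.nonzero(gaps > max_gap_hours)[0]
    if over.size:
        fx = fx.iloc[: over[0] + 1]
    return fx.reset_index(drop=True)


#: QC reason codes
NO_FIXES = "NO_FIXES"
FIRST_FIX_LATE = "FIRST_FIX_LATE"
SHORT_MONITORING = "SHORT_MONITORING"


@dataclass(frozen=True)
class QCDecision:
    animal_id: str
    keep: bool
    reasons: tuple[str, ...]
    first_fix_days: float | None
    span_days: float | None


def qc_individual(
    fixes: pd.DataFrame,
    capture: pd.Series | dict,
    min_monitoring_days: float = 20.0,
    max_first_fix_days: float = 3.0,
) -> QCDecision:
    """Keep/exclude decision for one regularized individual.

    Excluded when the first retained fix is more than ``max_first_fix_days``
    after capture, or when the retained span (last minus first fix) is less
    than ``min_monitoring_days``.
    """
    animal_id = str(capture["animal_id"])
    if len(fixes) == 0:
        return QCDecision(animal_id, False, (NO_FIXES,), None, None)
    t_capture = pd.Timestamp(capture["capture_time_utc"])
    if t_capture.tzinfo is None:
        t_capture = t_capture.tz_localize("UTC")
    first = (fixes["timestamp_utc"].iloc[0] - t_capture).total_seconds() / 86400.0
    span = (
        fixes["timestamp_utc"].iloc[-1] - fixes["timestamp_utc"].iloc[0]
    ).total_seconds() / 86400.0
    reasons = []
    if first > max_first_fix_days:
        reasons.append(FIRST_FIX_LATE)
    if span < min_monitoring_days:
        reasons.append(SHORT_MONITORING)
    return QCDecision(animal_id, not reasons, tuple(reasons), first, span)


def lonlat_to_metres(
    lon: np.ndarray, lat: np.ndarray, lon0: float | None = None, lat0: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Project lon/lat (degrees) to local planar metres.

    Local azimuthal equirectangular projection about the point cloud's
    centroid (or an explicit origin): adequate for home-range-scale extents
    where distances are effectively Euclidean.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if lon0 is None:
        lon0 = float(np.mean(lon))
    if lat0 is None:
        lat0 = float(np.mean(lat))
    x = np.radians(lon - lon0) * math.cos(math.radians(lat0)) * EARTH_RADIUS_M
    y = np.radians(lat - lat0) * EARTH_RADIUS_M
    return x, y
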