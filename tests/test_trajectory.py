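"""Fix/capture IO schema rules, temporal regularization and individual QC."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from postcapture.trajectory import (
    FIRST_FIX_LATE,
    SHORT_MONITORING,
    SchemaError,
    lonlat_to_metres,
    monitoring_window,
    qc_individual,
    read_captures,
    read_fixes,
    regularize,
)

from conftest import CAPTURE_T0, make_capture, make_fixes


# ---------------------------------------------------------------- IO


def test_read_fixes_roundtrip(tmp_path):
    path = tmp_path / "fixes.csv"
    make_fixes([0, 4, 8]).assign(
        timestamp_utc=lambda d: d.timestamp_utc.dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    ).to_csv(path, index=False)
    out = read_fixes(path)
    assert len(out) == 3
    assert out["timestamp_utc"].is_monotonic_increasing


def test_read_fixes_missing_column(tmp_path):
    path = tmp_path / "fixes.csv"
    make_fixes([0, 4]).drop(columns=["y_m"]).to_csv(path, index=False)
    with pytest.raises(SchemaError, match="y_m"):
        read_fixes(path)


def test_read_fixes_bad_timestamp_names_row(tmp_path):
    path = tmp_path / "fixes.csv"
    df = make_fixes([0, 4]).assign(
        timestamp_utc=lambda d: d.timestamp_utc.dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    )
    df.loc[1, "timestamp_utc"] = "not-a-time"
    df.to_csv(path, index=False)
    with pytest.raises(SchemaError, match="row 1"):
        read_fixes(path)


def test_read_fixes_collapses_duplicate_timestamps(tmp_path, caplog):
    path = tmp_path / "fixes.csv"
    df = make_fixes([0, 4, 4], xy=[[0, 0], [1, 1], [2, 2]])
    df.to_csv(path, index=False)
    with caplog.at_level(logging.WARNING):
        out = read_fixes(path)
    assert len(out) == 2
    assert out["x_m"].iloc[-1] == 1.0  # first occurrence kept
    assert any("duplicate" in r.message for r in caplog.records)


def test_read_captures_unknown_method(tmp_path):
    path = tmp_path / "captures.csv"
    cap = make_capture().to_frame().T
    cap["method"] = "cage_trap"
    cap.to_csv(path, index=False)
    with pytest.raises(SchemaError, match="cage_trap"):
        read_captures(path)


def test_read_captures_strict_season_toggle(tmp_path):
    path = tmp_path / "captures.csv"
    cap = make_capture(t0=pd.Timestamp("2022-06-15T12:00:00Z")).to_frame().T
    cap.to_csv(path, index=False)
    with pytest.raises(SchemaError, match="season"):
        read_captures(path, strict_season=True)
    assert len(read_captures(path, strict_season=False)) == 1


# ------------------------------------------------------- regularization


def test_regularize_hourly_month_keeps_six_per_day():
    fixes = make_fixes(np.arange(0, 720))  # 30 days of hourly fixes
    out = regularize(fixes, make_capture())
    assert len(out) == 180


def test_regularize_truncates_at_gap_over_72h():
    fixes = make_fixes([0.0, 100.0])
    out = regularize(fixes, make_capture())
    assert len(out) == 1


def test_regularize_clips_to_monitoring_window():
    window = monitoring_window(CAPTURE_T0)
    hours = [-5.0, 0.0, 24.0, window.length_days * 24.0 + 10.0]
    out = regularize(make_fixes(hours), make_capture())
    assert len(out) == 2  # pre-capture and post-15-April fixes dropped


def test_regularize_empty_input_is_empty_output():
    fixes = make_fixes([])
    out = regularize(fixes, make_capture())
    assert len(out) == 0


def _brute_max_in_24h(hours):
    hours = np.asarray(sorted(hours))
    return max(
        (int(((hours >= h) & (hours < h + 24.0)).sum()) for h in hours),
        default=0,
    )


@settings(max_examples=60, deadline=None)
@given(
    st.lists(
        st.floats(min_value=0.0, max_value=400.0, allow_nan=False),
        min_size=1,
        max_size=150,
    )
)
def test_regularize_idempotent_subset_and_sliding_window(hours):
    hours = sorted(set(round(h, 3) for h in hours))
    fixes = make_fixes(hours, xy=np.arange(2 * len(hours)).reshape(-1, 2))
    capture = make_capture()
    once = regularize(fixes, capture)
    twice = regularize(once, capture)
    pd.testing.assert_frame_equal(once, twice)
    # no synthesis: every output row is an input row
    merged = once.merge(fixes, how="left", indicator=True)
    assert (merged["_merge"] == "both").all()
    kept_h = (once["timestamp_utc"] - CAPTURE_T0).dt.total_seconds().to_numpy() / 3600.0
    assert _brute_max_in_24h(kept_h) <= 6


# ----------------------------------------------------------------- QC


def test_qc_excludes_late_first_fix():
    fixes = regularize(make_fixes(np.arange(96, 96 + 30 * 24, 4.0)), make_capture())
    decision = qc_individual(fixes, make_capture())
    assert not decision.keep and FIRST_FIX_LATE in decision.reasons


def test_qc_excludes_short_monitoring():
    fixes = regularize(make_fixes(np.arange(0, 19.5 * 24, 4.0)), make_capture())
    decision = qc_individual(fixes, make_capture())
    assert not decision.keep and SHORT_MONITORING in decision.reasons


def test_qc_retains_good_individual():
    fixes = regularize(make_fixes(np.arange(1, 1 + 40 * 24, 4.0)), make_capture())
    decision = qc_individual(fixes, make_capture())
    assert decision.keep and decision.reasons == ()


def test_monitoring_window_ends_april_15_of_season():
    w = monitoring_window(pd.Timestamp("2021-11-20T08:00:00Z"))
    assert w.end == pd.Timestamp("2022-04-15T00:00:00Z")
    w2 = monitoring_window(pd.Timestamp("2022-02-01T08:00:00Z"))
    assert w2.end == pd.Timestamp("2022-04-15T00:00:00Z")


def test_lonlat_projection_scales():
    # 0.001 degrees of latitude is ~111.2 m anywhere
    x, y = lonlat_to_metres(np.array([10.0, 10.0]), np.array([46.0, 46.001]))
    assert y[1] - y[0] == pytest.approx(111.19, rel=1e-3)
    # longitude shrinks with cos(latitude)
    x, y = lonlat_to_metres(np.array([10.0, 10.001]), np.array([60.0, 60.0]))
    assert x[1] - x[0] == pytest.approx(111.19 * np.cos(np.radians(60.0)), rel=1e-3)
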