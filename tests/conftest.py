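import datetime as dt

import numpy as np
import pandas as pd
import pytest

from postcapture.config import RunConfig, SimConfig
from postcapture.pipeline import build_records

CAPTURE_T0 = pd.Timestamp("2022-01-10T00:00:00Z")


def make_fixes(hours, xy=None, animal_id="a1", site_id="s1", t0=CAPTURE_T0):
    """Fix table from hours-since-capture and optional coordinates."""
    hours = np.asarray(hours, dtype=float)
    if xy is None:
        xy = np.zeros((len(hours), 2))
    xy = np.asarray(xy, dtype=float)
    return pd.DataFrame(
        {
            "animal_id": animal_id,
            "site_id": site_id,
            "timestamp_utc": t0 + pd.to_timedelta(hours, unit="h"),
            "x_m": xy[:, 0],
            "y_m": xy[:, 1],
        }
    )


def make_capture(
    animal_id="a1",
    site_id="s1",
    t0=CAPTURE_T0,
    method="box_trap",
    sex="female",
    age_class="adult",
):
    return pd.Series(
        {
            "animal_id": animal_id,
            "site_id": site_id,
            "capture_time_utc": t0,
            "method": method,
            "sex": sex,
            "age_class": age_class,
        }
    )


@pytest.fixture(scope="session")
def sim_records(tmp_path_factory):
    """Movement records from a 30-animal simulated winter campaign.

    Default capture effects are injected (a0 = 0.5, d0 = 300 m, tau = 5 d);
    reused by the model-fitting tests.
    """
    out = tmp_path_factory.mktemp("sim_records")
    sim = SimConfig(
        n_animals=30,
        season_start=dt.date(2022, 1, 20),
        season_end=dt.date(2022, 2, 10),
    )
    cfg = RunConfig(simulation=sim, out_dir=out, seed=5)
    records, qc_log, homeranges, counts, truth = build_records(cfg)
    return records
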