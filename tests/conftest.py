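import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_logs(rows):
    """Build a log table from (uuid, iso_minute, lat, lon, acc, ...) tuples."""
    out = []
    for r in rows:
        uuid, t, lat, lon, acc = r[:5]
        extra = r[5] if len(r) > 5 else {}
        out.append(
            {
                "uuid": uuid,
                "t": pd.Timestamp(t),
                "lat": lat,
                "lon": lon,
                "accuracy_m": acc,
                "sex": extra.get("sex", "unknown"),
                "age_group": extra.get("age_group", "unknown"),
                "daily_steps": extra.get("daily_steps", np.nan),
            }
        )
    return pd.DataFrame(out)


@pytest.fixture
def sendai_point():
    return 38.2682, 140.8694


@pytest.fixture
def one_user_month():
    """One user with 12 valid days (30 logs each) and 2 sparse days."""
    rows = []
    for d in range(1, 13):
        for i in range(30):
            rows.append(
                ("u1", dt.datetime(2019, 10, d, 8, 0) + dt.timedelta(minutes=7 * i),
                 38.26 + 0.0001 * i, 140.87, 10.0)
            )
    for d in (13, 14):  # invalid: only 5 logs
        for i in range(5):
            rows.append(
                ("u1", dt.datetime(2019, 10, d, 9, 0) + dt.timedelta(minutes=11 * i),
                 38.27, 140.88, 10.0)
            )
    return make_logs(rows)
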