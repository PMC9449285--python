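"""Reading GPS log tables and the first two trajectory-recovery steps.

Raw application logs arrive as delimited text with minute-resolution
timestamps.  This module applies the horizontal-accuracy filter, selects
*active users* (more than 10 days with at least 24 logs), and collapses
duplicate-minute logs into one representative point per (user, minute).

All tables are pandas DataFrames.  Log columns: ``uuid, t, lat, lon,
accuracy_m, sex, age_group, daily_steps``; trajectory-point columns:
``uuid, t, lat, lon, origin``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: columns a raw log table must provide
REQUIRED_COLUMNS = ["uuid", "year", "month", "day", "hour", "minute", "lat", "lon", "accuracy_m"]
OPTIONAL_COLUMNS = ["sex", "age_group", "daily_steps"]

LOG_COLUMNS = ["uuid", "t", "lat", "lon", "accuracy_m", "sex", "age_group", "daily_steps"]
POINT_COLUMNS = ["uuid", "t", "lat", "lon", "origin"]

MIN_LOGS_PER_DAY = 24  # a valid day has at least this many accuracy-filtered logs
MIN_VALID_DAYS = 11    # "more than 10" valid days, read strictly


class SchemaError(ValueError):
    """A required column is missing from an input table."""


def read_logs(path, sep: str = ",") -> pd.DataFrame:
    """Parse a raw GPS log table.

    Timestamps are assembled from the year..minute columns (one local
    timezone, no DST) and truncated to the minute.  Rows whose coordinates
    or timestamp fail to parse are dropped; the count is logged.
    """
    raw = pd.read_csv(path, sep=sep, dtype={"uuid": str}, keep_default_na=True)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"log table is missing required column(s): {', '.join(missing)}")
    for c in OPTIONAL_COLUMNS:
        if c not in raw.columns:
            raw[c] = np.nan

    n0 = len(raw)
    lat = pd.to_numeric(raw["lat"], errors="coerce")
    lon = pd.to_numeric(raw["lon"], errors="coerce")
    acc = pd.to_numeric(raw["accuracy_m"], errors="coerce")
    t = pd.to_datetime(
        raw[["year", "month", "day", "hour", "minute"]].apply(pd.to_numeric, errors="coerce"),
        errors="coerce",
    )
    ok = lat.notna() & lon.notna() & np.isfinite(lat) & np.isfinite(lon) & t.notna() & acc.notna()
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("read_logs: dropped %d of %d rows with unparseable fields", n_bad, n0)

    steps = pd.to_numeric(raw["daily_steps"], errors="coerce")
    out = pd.DataFrame(
        {
            "uuid": raw["uuid"].fillna(""),
            "t": t.dt.floor("min"),
            "lat": lat,
            "lon": lon,
            "accuracy_m": acc,
            "sex": raw["sex"].where(raw["sex"].notna(), "unknown"),
            "age_group": raw["age_group"].where(raw["age_group"].notna(), "unknown"),
            "daily_steps": steps,
        }
    )[ok.to_numpy()]
    return out.reset_index(drop=True)


def filter_accuracy(logs: pd.DataFrame, max_error_m: float = 200.0) -> pd.DataFrame:
    """Keep logs with horizontal accuracy strictly below ``max_error_m`` and
    a non-empty uuid.  The 200 m boundary itself is excluded."""
    uuid = logs["uuid"].astype(str)
    keep = (logs["accuracy_m"] < max_error_m) & (uuid != "") & uuid.notna()
    return logs[keep.to_numpy()].reset_index(drop=True)


@dataclass
class UserDayIndex:
    """Valid days and the active flag per user.

    A day is valid for a user when it carries at least 24 accuracy-filtered
    logs; a user is active with 11 or more valid days.
    """

    valid_days: dict[str, set] = field(default_factory=dict)  # uuid -> set of datetime.date
    active: dict[str, bool] = field(default_factory=dict)

    def is_valid(self, uuid: str, date) -> bool:
        return date in self.valid_days.get(uuid, ())

    def active_users(self) -> set[str]:
        return {u for u, a in self.active.items() if a}


def index_valid_days(
    logs: pd.DataFrame,
    min_logs_per_day: int = MIN_LOGS_PER_DAY,
    min_valid_days: int = MIN_VALID_DAYS,
) -> UserDayIndex:
    """Build the valid-day / active-user index from accuracy-filtered logs."""
    idx = UserDayIndex()
    if logs.empty:
        return idx
    date = logs["t"].dt.date
    counts = logs.groupby(["uuid", date], observed=True, sort=False).size()
    valid = counts[counts >= min_logs_per_day]
    for (uuid, d) in valid.index:
        idx.valid_days.setdefault(uuid, set()).add(d)
    for uuid in logs["uuid"].unique():
        idx.active[uuid] = len(idx.valid_days.get(uuid, ())) >= min_valid_days
    return idx


def select_active(logs: pd.DataFrame, index: UserDayIndex) -> pd.DataFrame:
    """Keep only logs of active users on their valid days.  Idempotent."""
    if logs.empty:
        return logs.copy()
    active = index.active_users()
    sub = logs[logs["uuid"].isin(active)]
    if sub.empty:
        return sub.reset_index(drop=True)
    date = sub["t"].dt.date
    keep = [index.is_valid(u, d) for u, d in zip(sub["uuid"], date)]
    return sub[np.asarray(keep, dtype=bool)].reset_index(drop=True)


def dedupe_minute(logs: pd.DataFrame) -> pd.DataFrame:
    """Collapse same-(uuid, minute) logs to their central coordinates.

    The representative position is the unweighted arithmetic mean of
    latitude and longitude in degree space.  Output is one observed
    trajectory point per (uuid, minute), time-sorted within user.
    """
    if logs.empty:
        return pd.DataFrame(columns=POINT_COLUMNS)
    g = logs.groupby(["uuid", "t"], sort=False, as_index=False).agg(
        lat=("lat", "mean"), lon=("lon", "mean")
    )
    g["origin"] = "observed"
    g = g.sort_values(["uuid", "t"], kind="stable").reset_index(drop=True)
    return g[POINT_COLUMNS]
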