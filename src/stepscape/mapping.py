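"""Aggregation of predicted daily steps to users and 500 m residence grids.

Predicted (fixed-effects) daily steps are averaged per user within day-type
cells — weekdays, weekends/holidays pooled, and each listed weekend pair
separately — then averaged over users per 500 m grid square of residence.
Grids with fewer than five resident users are suppressed as non-assessable.
"""

from __future__ import annotations

import datetime as dt
import json

import numpy as np
import pandas as pd

from . import meshgrid

#: national holidays falling in the October 2019 study month
DEFAULT_HOLIDAYS = (dt.date(2019, 10, 14), dt.date(2019, 10, 22))

#: the four weekend pairs of October 2019
DEFAULT_WEEKEND_PAIRS = (
    (dt.date(2019, 10, 5), dt.date(2019, 10, 6)),
    (dt.date(2019, 10, 12), dt.date(2019, 10, 13)),
    (dt.date(2019, 10, 19), dt.date(2019, 10, 20)),
    (dt.date(2019, 10, 26), dt.date(2019, 10, 27)),
)

DAY_TYPES = ["weekday", "weekend_holiday", "weekend_1", "weekend_2", "weekend_3", "weekend_4"]

SUMMARY_COLUMNS = ["grid", "day_type", "n_users", "mean_steps"]


def classify_day(date, holidays=DEFAULT_HOLIDAYS) -> str:
    """"weekday" or "weekend_holiday" for a calendar date.

    Saturdays, Sundays, and dates in ``holidays`` are weekend/holiday.
    """
    date = pd.Timestamp(date).date()
    if date.weekday() >= 5 or date in set(holidays):
        return "weekend_holiday"
    return "weekday"


def user_means(
    predictions: pd.DataFrame,
    holidays=DEFAULT_HOLIDAYS,
    weekend_pairs=DEFAULT_WEEKEND_PAIRS,
) -> pd.DataFrame:
    """Per-user mean predicted steps per day-type cell.

    ``predictions`` columns: uuid, date, predicted_steps.  Output is long
    form: uuid, day_type, mean_steps; users with no dates in a cell simply
    have no row for it.
    """
    preds = predictions.copy()
    date = pd.to_datetime(preds["date"]).dt.date
    hol = set(holidays)
    day_type = np.where(
        [d.weekday() >= 5 or d in hol for d in date], "weekend_holiday", "weekday"
    )
    frames = [
        preds.assign(day_type=day_type)
        .groupby(["uuid", "day_type"], sort=False, as_index=False)["predicted_steps"]
        .mean()
    ]
    for i, pair in enumerate(weekend_pairs, start=1):
        sub = preds[np.isin(np.asarray(date), np.asarray(list(pair)))]
        if sub.empty:
            continue
        frames.append(
            sub.groupby("uuid", sort=False, as_index=False)["predicted_steps"]
            .mean()
            .assign(day_type=f"weekend_{i}")
        )
    out = pd.concat(frames, ignore_index=True).rename(columns={"predicted_steps": "mean_steps"})
    return out[["uuid", "day_type", "mean_steps"]].sort_values(
        ["uuid", "day_type"], kind="stable"
    ).reset_index(drop=True)


def grid_summaries(
    means: pd.DataFrame, residences: pd.DataFrame, min_users: int = 5
) -> pd.DataFrame:
    """Mean of user means per 500 m residence grid and day type.

    Users are assigned to the 500 m grid square containing their residence
    point; rows with fewer than ``min_users`` users are suppressed.
    """
    valid = residences[residences["status"] == "valid"]
    grids = {
        str(r["uuid"]): meshgrid.to_mesh_code(
            float(r["residence_lat"]), float(r["residence_lon"]), "500m"
        ).code
        for _, r in valid.iterrows()
    }
    m = means[means["uuid"].isin(grids.keys())].copy()
    m["grid"] = m["uuid"].map(grids)
    g = m.groupby(["grid", "day_type"], as_index=False).agg(
        n_users=("uuid", "nunique"), mean_steps=("mean_steps", "mean")
    )
    g = g[g["n_users"] >= min_users].reset_index(drop=True)
    return g[SUMMARY_COLUMNS].sort_values(["grid", "day_type"], kind="stable").reset_index(
        drop=True
    )


def summaries_to_geojson(summaries: pd.DataFrame, path=None) -> dict:
    """500 m cell polygons with day_type/n_users/mean_steps properties."""
    features = []
    for _, r in summaries.iterrows():
        b = meshgrid.mesh_bounds(str(r["grid"]), "500m")
        ring = [
            [b.west, b.south],
            [b.east, b.south],
            [b.east, b.north],
            [b.west, b.north],
            [b.west, b.south],
        ]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "grid": str(r["grid"]),
                    "day_type": str(r["day_type"]),
                    "n_users": int(r["n_users"]),
                    "mean_steps": float(r["mean_steps"]),
                },
            }
        )
    gj = {"type": "FeatureCollection", "features": features}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(gj, fh)
    return gj
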