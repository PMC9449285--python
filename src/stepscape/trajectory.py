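"""Straight-line minute interpolation between consecutive observed points.

Smartphone logs arrive at irregular minute intervals; between two consecutive
observed points of one user, one interpolated point is created for every
intermediate minute, equally spaced on the straight segment in
longitude/latitude degree space (planar, not geodesic — the positional error
of this choice is negligible at the 100 m working resolution).  Interpolated
points are generated across calendar-day boundaries first, then every
interpolated point falling on a day that is not valid for the user is
deleted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ingest import POINT_COLUMNS, UserDayIndex


def interpolate_pair(a: pd.Series, b: pd.Series) -> pd.DataFrame:
    """Interpolated points between two consecutive observed points.

    For a time difference of ``dt`` whole minutes, emits ``dt - 1`` points;
    point ``i`` lies at fraction ``i/dt`` along the segment from *a* to *b*
    and is timestamped ``t(a) + i`` minutes.  Endpoints are never emitted:
    a one-minute gap yields nothing, a two-minute gap yields the midpoint.
    """
    if a["uuid"] != b["uuid"]:
        raise ValueError(f"interpolate_pair: different users {a['uuid']!r} vs {b['uuid']!r}")
    dt = (b["t"] - a["t"]) / pd.Timedelta(minutes=1)
    if dt <= 0:
        raise ValueError(f"interpolate_pair: non-increasing timestamps {a['t']} -> {b['t']}")
    dt = int(round(dt))
    i = np.arange(1, dt)
    frac = i / dt
    return pd.DataFrame(
        {
            "uuid": a["uuid"],
            "t": a["t"] + pd.to_timedelta(i, unit="min"),
            "lat": a["lat"] + frac * (b["lat"] - a["lat"]),
            "lon": a["lon"] + frac * (b["lon"] - a["lon"]),
            "origin": "interpolated",
        }
    )


def _interpolate_gaps(points: pd.DataFrame, max_gap_minutes: int | None = None) -> pd.DataFrame:
    """Vectorized interpolation over all consecutive same-user pairs."""
    t_min = points["t"].to_numpy("datetime64[m]").astype(np.int64)
    lat = points["lat"].to_numpy(float)
    lon = points["lon"].to_numpy(float)
    uu = points["uuid"].to_numpy()

    same_user = uu[1:] == uu[:-1]
    dt = t_min[1:] - t_min[:-1]
    if np.any(same_user & (dt <= 0)):
        raise ValueError("observed points are not strictly time-ordered within a user")
    fill = same_user if max_gap_minutes is None else same_user & (dt <= max_gap_minutes)
    ngap = np.where(fill, dt - 1, 0)  # interpolated points per pair
    total = int(ngap.sum())
    if total == 0:
        return pd.DataFrame(columns=POINT_COLUMNS)

    pair = np.repeat(np.arange(len(ngap)), ngap)           # source pair index
    step = np.arange(total) - np.repeat(np.cumsum(ngap) - ngap, ngap) + 1
    frac = step / dt[pair]
    out = pd.DataFrame(
        {
            "uuid": uu[pair],
            "t": (t_min[pair] + step).astype("datetime64[m]").astype("datetime64[ns]"),
            "lat": lat[pair] + frac * (lat[pair + 1] - lat[pair]),
            "lon": lon[pair] + frac * (lon[pair + 1] - lon[pair]),
            "origin": "interpolated",
        }
    )
    return out


def interpolate_user(
    points: pd.DataFrame, index: UserDayIndex, max_gap_minutes: int | None = None
) -> pd.DataFrame:
    """Observed points plus gap interpolation, purged of invalid-day points.

    ``points`` are the observed (deduplicated) points of one or more users,
    sorted by time within user.  Gaps are filled pairwise, including pairs
    that span whole missing days; interpolated points whose calendar date is
    not a valid day for their user are then deleted (observed points are
    never deleted here).  Output is time-sorted within user.
    ``max_gap_minutes`` optionally caps the gaps that are filled at all;
    by default no cap applies.
    """
    if points.empty:
        return points.copy()
    points = points.sort_values(["uuid", "t"], kind="stable").reset_index(drop=True)
    interp = _interpolate_gaps(points, max_gap_minutes)
    if not interp.empty:
        # membership test vectorized via (user, epoch-day) integer keys
        day = interp["t"].to_numpy("datetime64[D]").astype(np.int64)
        uid, uniq = pd.factorize(interp["uuid"])
        valid = []
        for ui, u in enumerate(uniq):
            for d in index.valid_days.get(u, ()):
                valid.append(ui * 10_000_000 + np.datetime64(d, "D").astype(np.int64))
        key = uid.astype(np.int64) * 10_000_000 + day
        interp = interp[np.isin(key, np.asarray(valid, dtype=np.int64))]
    out = points if interp.empty else pd.concat([points, interp], ignore_index=True)
    out = out.sort_values(["uuid", "t"], kind="stable").reset_index(drop=True)
    return out[POINT_COLUMNS]
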