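"""Residence estimation from daily first/last log clusters.

Because providers mask all logs inside the 100 m grid square of a user's
estimated home, the home must be re-estimated to strip the surrounding
interpolated points that would otherwise inflate near-home exposure.  The
procedure, per user:

1. take the first and last 5% of each day's time-sorted points (the *5% Log
   Set*), with ``k = max(1, ceil(0.05 n))`` points from each end;
2. per day, find the modal 250 m grid square of that day's 5% set;
3. over days, the most frequent modal grid(s) are the residential grid(s) —
   several are accepted when they are mutually adjacent or share a common
   adjacent cell (queen contiguity, Chebyshev distance <= 2), otherwise the
   user is *residence undefinable*;
4. the residence point is the mean of all 5%-set points inside the
   residential grid(s).

Trajectory points (observed and interpolated) inside the residential grids
are then removed, and users can be restricted to a study region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from . import meshgrid
from .meshgrid import MeshCode

RESIDENCE_COLUMNS = ["uuid", "status", "residential_grid_codes", "residence_lat", "residence_lon"]


@dataclass
class ResidenceResult:
    uuid: str
    status: str                     # "valid" | "undefinable"
    residential_grids: frozenset    # of 250 m code strings
    residence_lat: float
    residence_lon: float


def five_percent_set(points: pd.DataFrame) -> pd.DataFrame:
    """First and last 5% of one user-day's time-sorted points.

    ``k = max(1, ceil(0.05 n))`` from each end; if the ends would overlap
    (``2k >= n``) the whole day is returned.  A single point is returned
    once, not twice.
    """
    n = len(points)
    if n == 0:
        raise ValueError("five_percent_set: empty day")
    points = points.sort_values("t", kind="stable")
    k = max(1, int(np.ceil(0.05 * n)))
    if 2 * k >= n:
        return points
    return pd.concat([points.iloc[:k], points.iloc[-k:]])


def _five_percent_mask(points: pd.DataFrame) -> np.ndarray:
    """Vectorized 5%-set membership over a multi-user, multi-day table.

    ``points`` must be sorted by (uuid, t).  Returns a boolean mask aligned
    with ``points`` marking each day's first/last 5%.
    """
    date = points["t"].dt.normalize()
    grp = points.groupby(["uuid", date], sort=False)
    n = grp["t"].transform("size").to_numpy()
    pos = grp.cumcount().to_numpy()
    k = np.maximum(1, np.ceil(0.05 * n).astype(np.int64))
    return (pos < k) | (pos >= n - k) | (2 * k >= n)


def daily_modal_grid(subset: pd.DataFrame) -> str:
    """Modal 250 m grid code of one day's 5% set; ties -> smallest code."""
    if subset.empty:
        raise ValueError("daily_modal_grid: empty subset")
    row, col = meshgrid.point_to_indices(
        subset["lat"].to_numpy(float), subset["lon"].to_numpy(float), "250m"
    )
    codes = [meshgrid.code_from_indices(r, c, "250m") for r, c in zip(row, col)]
    counts = pd.Series(codes).value_counts()
    top = counts[counts == counts.iloc[0]].index
    return min(top)


def estimate_residence(
    points: pd.DataFrame, uuid: str | None = None, adjacency: str = "queen"
) -> ResidenceResult:
    """Estimate one user's residence from their trajectory points.

    ``points``: all valid-day trajectory points of one user (observed and
    interpolated), any order.  Ties among the most frequent daily modal
    grids are all retained; if the tied grids are not coresident the user is
    flagged ``undefinable`` (residence coordinates NaN).
    """
    if points.empty:
        raise ValueError("estimate_residence: no points")
    if uuid is None:
        uuid = str(points["uuid"].iloc[0])
    points = points.sort_values(["uuid", "t"], kind="stable").reset_index(drop=True)
    five = points[_five_percent_mask(points)]

    # one modal grid per day, each day counted once
    date = five["t"].dt.normalize()
    modal = {d: daily_modal_grid(sub) for d, sub in five.groupby(date, sort=False)}
    freq = pd.Series(list(modal.values())).value_counts()
    top = sorted(freq[freq == freq.iloc[0]].index)
    top_codes = [MeshCode(c, "250m") for c in top]

    if len(top_codes) > 1 and not meshgrid.coresident(top_codes, adjacency=adjacency):
        return ResidenceResult(uuid, "undefinable", frozenset(top), float("nan"), float("nan"))

    row, col = meshgrid.point_to_indices(
        five["lat"].to_numpy(float), five["lon"].to_numpy(float), "250m"
    )
    want = {meshgrid.indices_from_code(c, "250m") for c in top}
    inside = np.fromiter(((r, c) in want for r, c in zip(row, col)), dtype=bool, count=len(five))
    sel = five[inside]
    return ResidenceResult(
        uuid,
        "valid",
        frozenset(top),
        float(sel["lat"].mean()),
        float(sel["lon"].mean()),
    )


def estimate_residences(points: pd.DataFrame, adjacency: str = "queen") -> pd.DataFrame:
    """Residence table for every user in a trajectory-point table."""
    rows = []
    for uuid, sub in points.groupby("uuid", sort=True):
        r = estimate_residence(sub, uuid=str(uuid), adjacency=adjacency)
        rows.append(
            {
                "uuid": r.uuid,
                "status": r.status,
                "residential_grid_codes": ";".join(sorted(r.residential_grids)),
                "residence_lat": r.residence_lat,
                "residence_lon": r.residence_lon,
            }
        )
    return pd.DataFrame(rows, columns=RESIDENCE_COLUMNS)


def filter_residential(points: pd.DataFrame, result: ResidenceResult) -> pd.DataFrame:
    """Drop one user's points inside their residential 250 m grid(s).

    Points of other users are untouched.  Raises if the residence is
    undefinable.
    """
    if result.status != "valid":
        raise ValueError(f"filter_residential: residence of {result.uuid} is {result.status}")
    mine = (points["uuid"] == result.uuid).to_numpy()
    if not mine.any():
        return points.reset_index(drop=True)
    row, col = meshgrid.point_to_indices(
        points["lat"].to_numpy(float)[mine], points["lon"].to_numpy(float)[mine], "250m"
    )
    want = {meshgrid.indices_from_code(c, "250m") for c in result.residential_grids}
    in_home = np.fromiter(((r, c) in want for r, c in zip(row, col)), dtype=bool, count=mine.sum())
    drop = np.zeros(len(points), dtype=bool)
    drop[np.flatnonzero(mine)[in_home]] = True
    return points[~drop].reset_index(drop=True)


def filter_residential_all(points: pd.DataFrame, residences: pd.DataFrame) -> pd.DataFrame:
    """Vectorized residential-grid stripping for a whole residence table.

    Keeps only users with a valid residence, then removes each user's points
    whose 250 m cell is among that user's residential grids.
    """
    valid = residences[residences["status"] == "valid"]
    home: dict[str, set] = {}
    for _, r in valid.iterrows():
        codes = str(r["residential_grid_codes"]).split(";")
        home[str(r["uuid"])] = {meshgrid.indices_from_code(c, "250m") for c in codes}
    pts = points[points["uuid"].isin(home.keys())]
    if pts.empty:
        return pts.reset_index(drop=True)
    row, col = meshgrid.point_to_indices(
        pts["lat"].to_numpy(float), pts["lon"].to_numpy(float), "250m"
    )
    # (user, row, col) packed into one int64 key for a vectorized membership test
    uid, uniq = pd.factorize(pts["uuid"])
    home_keys = np.asarray(
        [
            (ui << 42) | (r << 21) | c
            for ui, u in enumerate(uniq)
            for (r, c) in home[u]
        ],
        dtype=np.int64,
    )
    key = (uid.astype(np.int64) << 42) | (row << 21) | col
    return pts[~np.isin(key, home_keys)].reset_index(drop=True)


def restrict_region(residences: pd.DataFrame, region) -> pd.DataFrame:
    """Keep users whose residence point falls inside ``region``.

    ``region`` may be ``None``/"none" (identity), a (lon_min, lat_min,
    lon_max, lat_max) box, a sequence of (lon, lat) ring vertices, or a
    shapely geometry.  Boundary points count as inside.
    """
    if region is None or (isinstance(region, str) and region.lower() == "none"):
        return residences.reset_index(drop=True)
    if isinstance(region, shapely.Geometry):
        geom = region
    else:
        region = list(region)
        if len(region) == 4 and np.ndim(region[0]) == 0:
            geom = shapely.box(*[float(v) for v in region])
        elif len(region) >= 3 and np.ndim(region[0]) == 1 or (
            len(region) >= 3 and isinstance(region[0], (list, tuple))
        ):
            geom = shapely.Polygon([(float(x), float(y)) for x, y in region])
        else:
            raise ValueError(f"malformed region specification: {region!r}")
    if not geom.is_valid:
        raise ValueError("malformed region specification: invalid polygon")
    pts = shapely.points(
        residences["residence_lon"].to_numpy(float), residences["residence_lat"].to_numpy(float)
    )
    inside = shapely.intersects(geom, pts)
    return residences[inside].reset_index(drop=True)
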