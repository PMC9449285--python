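"""Land-use reclassification and per-user-day exposure counting.

Land use comes as a table of 100 m grid squares, each carrying one of 17
original urban land-use categories; these are reclassified to 8 working
types.  A user-day's exposure to type *k* is the number of (trajectory
point, cell) incidences where the cell's centroid lies within 100 m
(great-circle) of the point and the cell is of type *k* — a cell hit by
*m* points that day counts *m* times, so the quantity is a visit frequency.

Cells absent from the land-use table (outside the mapped urban area) are
treated as type ``other``.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import meshgrid
from .meshgrid import haversine_m

#: the 8 reclassified types, fixed column order
TYPES = [
    "high_rise",
    "dense_low_rise",
    "low_rise",
    "factories",
    "parks_public",
    "roads",
    "railways",
    "other",
]
OTHER = TYPES.index("other")

#: original category -> reclassified type
RECLASS = {
    "High-rise buildings": "high_rise",
    "Dense low-rise buildings": "dense_low_rise",
    "Low-rise buildings": "low_rise",
    "Factories": "factories",
    "Public facilities": "parks_public",
    "Parks and green spaces": "parks_public",
    "Roads": "roads",
    "Railways": "railways",
    "Forests": "other",
    "Wastelands": "other",
    "Vacant lands": "other",
    "Rivers and lakes": "other",
    "Sea": "other",
    "Seashores": "other",
    "Golf courses": "other",
    "Rice fields": "other",
    "Other fields": "other",
}

RECORD_COLUMNS = ["uuid", "date", "steps", "sex", "age_group"] + TYPES

AGE_VALUES = {"10s": 10, "20s": 20, "30s": 30, "40s": 40, "50s": 50, "60s": 60}


def reclassify(original_type) -> str:
    """Map an original land-use category to its reclassified type.

    Missing values (no land-use information) map to ``other``; an unknown
    label raises.
    """
    if original_type is None or (isinstance(original_type, float) and math.isnan(original_type)):
        return "other"
    try:
        return RECLASS[original_type]
    except KeyError:
        raise ValueError(f"unknown land-use category: {original_type!r}") from None


class LandUseGrid:
    """Reclassified land-use raster over 100 m cell indices.

    Backed by a dense int8 array spanning the bounding index box of the
    cells present in the source table; lookups outside the box, or at cells
    the table does not mention, return ``other``.
    """

    def __init__(self, table: pd.DataFrame):
        if "mesh_code_100m" not in table.columns or "original_type" not in table.columns:
            raise ValueError("land-use table needs columns mesh_code_100m, original_type")
        codes = table["mesh_code_100m"].astype(str)
        rc = np.array(
            [meshgrid.indices_from_code(c, "100m") for c in codes], dtype=np.int64
        ).reshape(-1, 2)
        types = np.array([TYPES.index(reclassify(t)) for t in table["original_type"]], dtype=np.int8)
        if len(rc) == 0:
            self.row0 = self.col0 = 0
            self.grid = np.full((1, 1), OTHER, dtype=np.int8)
            return
        self.row0, self.col0 = int(rc[:, 0].min()), int(rc[:, 1].min())
        shape = (int(rc[:, 0].max()) - self.row0 + 1, int(rc[:, 1].max()) - self.col0 + 1)
        self.grid = np.full(shape, OTHER, dtype=np.int8)
        self.grid[rc[:, 0] - self.row0, rc[:, 1] - self.col0] = types

    def type_ids(self, row, col):
        """Reclassified type id at 100 m cell indices (vectorized)."""
        row = np.asarray(row) - self.row0
        col = np.asarray(col) - self.col0
        inside = (row >= 0) & (row < self.grid.shape[0]) & (col >= 0) & (col < self.grid.shape[1])
        out = np.full(row.shape, OTHER, dtype=np.int8)
        if inside.any():
            out[inside] = self.grid[row[inside], col[inside]]
        return out


def _centroid_of_indices(row, col):
    lat = (np.asarray(row, dtype=float) + 0.5) * 3.0 / 3600.0
    lon = 100.0 + (np.asarray(col, dtype=float) + 0.5) * 4.5 / 3600.0
    return lat, lon


def _halfwin(radius_m: float) -> int:
    # smallest window (in cells) that can contain every centroid within
    # radius; 100 m cells are >= 92.6 m across everywhere in the domain
    return max(1, int(math.ceil(radius_m / 92.6 - 0.5 + 1e-9)))


def cells_in_buffer(lat: float, lon: float, grid: LandUseGrid, radius_m: float = 100.0):
    """100 m cells whose centroid lies within ``radius_m`` of the point.

    Returns a list of (code, type_name) pairs.  Boundary inclusive.
    Only the cells' index neighbourhood is examined, not the whole table.
    """
    row, col = meshgrid.point_to_indices(lat, lon, "100m")
    h = _halfwin(radius_m)
    dr, dc = np.meshgrid(np.arange(-h, h + 1), np.arange(-h, h + 1), indexing="ij")
    rr, cc = row + dr.ravel(), col + dc.ravel()
    clat, clon = _centroid_of_indices(rr, cc)
    near = haversine_m(lat, lon, clat, clon) <= radius_m
    tids = grid.type_ids(rr[near], cc[near])
    return [
        (meshgrid.code_from_indices(int(r), int(c), "100m"), TYPES[t])
        for r, c, t in zip(rr[near], cc[near], tids)
    ]


def scan_cells_in_buffer(lat: float, lon: float, table: pd.DataFrame, radius_m: float = 100.0):
    """O(N) haversine scan over a full land-use table; the reference answer
    for :func:`cells_in_buffer` restricted to cells present in the table."""
    codes = table["mesh_code_100m"].astype(str).tolist()
    rc = np.array([meshgrid.indices_from_code(c, "100m") for c in codes]).reshape(-1, 2)
    clat, clon = _centroid_of_indices(rc[:, 0], rc[:, 1])
    near = haversine_m(lat, lon, clat, clon) <= radius_m
    return sorted(np.asarray(codes)[near].tolist())


def count_exposure(points: pd.DataFrame, grid: LandUseGrid, radius_m: float = 100.0,
                   chunk: int = 1_000_000) -> pd.DataFrame:
    """Visit-frequency counts per (uuid, date) over the 8 types.

    ``points`` are residence-filtered trajectory points (observed and
    interpolated both contribute).  Days on which a user has no surviving
    points yield no record.
    """
    if points.empty:
        return pd.DataFrame(columns=["uuid", "date"] + TYPES)
    keys = pd.DataFrame(
        {"uuid": points["uuid"].to_numpy(), "date": points["t"].to_numpy("datetime64[D]")}
    )
    gid, groups = pd.factorize(pd.MultiIndex.from_frame(keys))
    counts = np.zeros((len(groups), len(TYPES)), dtype=np.int64)

    lat_all = points["lat"].to_numpy(float)
    lon_all = points["lon"].to_numpy(float)
    h = _halfwin(radius_m)
    offs = [(dr, dc) for dr in range(-h, h + 1) for dc in range(-h, h + 1)]
    for start in range(0, len(points), chunk):
        sl = slice(start, min(start + chunk, len(points)))
        lat, lon, g = lat_all[sl], lon_all[sl], gid[sl]
        row, col = meshgrid.point_to_indices(lat, lon, "100m")
        for dr, dc in offs:
            rr, cc = row + dr, col + dc
            clat, clon = _centroid_of_indices(rr, cc)
            near = haversine_m(lat, lon, clat, clon) <= radius_m
            if not near.any():
                continue
            tids = grid.type_ids(rr[near], cc[near])
            np.add.at(counts, (g[near], tids), 1)

    out = pd.DataFrame(counts, columns=TYPES)
    out.insert(0, "date", pd.to_datetime(groups.get_level_values(1)))
    out.insert(0, "uuid", groups.get_level_values(0))
    return out.sort_values(["uuid", "date"], kind="stable").reset_index(drop=True)


def daily_exposure(points: pd.DataFrame, grid: LandUseGrid, radius_m: float = 100.0) -> pd.Series:
    """Counts for one user-day as a Series over the 8 types."""
    tab = count_exposure(points, grid, radius_m=radius_m)
    if len(tab) != 1:
        raise ValueError(f"daily_exposure expects points of exactly one user-day, got {len(tab)}")
    return tab[TYPES].iloc[0]


def attach_attributes(records: pd.DataFrame, logs: pd.DataFrame) -> pd.DataFrame:
    """Join per-day step counts and per-user sex/age onto exposure counts.

    Sex and age group are taken from each user's oldest log; daily steps
    from any log of the same user-day (they are constant within a day).
    """
    logs = logs.sort_values("t", kind="stable")
    first = logs.groupby("uuid", sort=False).first()
    attrs = first[["sex", "age_group"]]

    steps = (
        logs.assign(date=logs["t"].dt.normalize())
        .dropna(subset=["daily_steps"])
        .groupby(["uuid", "date"], sort=False)["daily_steps"]
        .first()
        .rename("steps")
    )
    out = records.merge(attrs, left_on="uuid", right_index=True, how="left")
    out = out.merge(steps, left_on=["uuid", "date"], right_index=True, how="left")
    out["sex"] = out["sex"].fillna("unknown")
    out["age_group"] = out["age_group"].fillna("unknown")
    return out[RECORD_COLUMNS]


def split_model_data(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition exposure records into the model-building set and the
    prediction set.

    The model set requires observed steps, known sex, and age group at most
    the sixties (users aged 70 and over, or of unknown age, are removed).
    The prediction set is every record without observed steps.
    """
    has_steps = records["steps"].notna()
    good_sex = records["sex"].isin(["male", "female"])
    good_age = records["age_group"].isin(AGE_VALUES.keys())
    with_steps = records[has_steps & good_sex & good_age].reset_index(drop=True)
    without_steps = records[~has_steps].reset_index(drop=True)
    return with_steps, without_steps
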