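"""Japanese standardized grid-square (mesh code) codec and topology.

The national grid divides Japan into nested rectangular cells identified by
digit strings: the Basic Grid Square spans 30 arcseconds of latitude by 45
arcseconds of longitude (about 1 km x 1 km) and carries an 8-digit code; each
halving step (500 m, 250 m) appends one quadrant digit (SW=1, SE=2, NW=3,
NE=4); the 1/10 subdivision (100 m) appends a latitude digit then a longitude
digit, each 0-9, to the 1 km code.

Cell membership is half-open, ``[south, north) x [west, east)``, so every
point maps to exactly one cell per level.  Internally a cell is a pair of
integer row/column indices counted in cell units from latitude 0 / longitude
100 degrees; all topology (neighbours, Chebyshev distance) is integer
arithmetic on those indices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "LEVELS",
    "MeshCode",
    "GridBounds",
    "to_mesh_code",
    "mesh_bounds",
    "mesh_centroid",
    "neighbors_250m",
    "coresident",
    "code_from_indices",
    "indices_from_code",
    "point_to_indices",
]

#: level -> (latitude extent, longitude extent) in arcseconds
LEVELS: dict[str, tuple[float, float]] = {
    "1km": (30.0, 45.0),
    "500m": (15.0, 22.5),
    "250m": (7.5, 11.25),
    "100m": (3.0, 4.5),
}

#: code string length per level (250 m and 100 m are both 10 digits; the
#: level must therefore always accompany a serialized code)
CODE_LENGTH = {"1km": 8, "500m": 9, "250m": 10, "100m": 10}

# Japan's standard-mesh domain
LAT_MIN, LAT_MAX = 20.0, 46.0
LON_MIN, LON_MAX = 122.0, 154.0

# tolerance, in cell-index units, absorbed when flooring a coordinate that
# was itself computed from a cell edge (~1e-9 cells ~ 0.1 um on the ground)
_EPS = 1e-9


@dataclass(frozen=True)
class MeshCode:
    """A grid-square identifier: digit string plus subdivision level."""

    code: str
    level: str

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown mesh level: {self.level!r}")
        if len(self.code) != CODE_LENGTH[self.level] or not self.code.isdigit():
            raise ValueError(
                f"malformed {self.level} mesh code: {self.code!r} "
                f"(expected {CODE_LENGTH[self.level]} digits)"
            )

    def __str__(self) -> str:  # serialized form: bare digits
        return self.code


@dataclass(frozen=True)
class GridBounds:
    """Geographic extent of one cell (degrees, half-open on north/east)."""

    south: float
    north: float
    west: float
    east: float

    def contains(self, lat: float, lon: float) -> bool:
        return self.south <= lat < self.north and self.west <= lon < self.east


def _cell_arcsec(level: str) -> tuple[float, float]:
    try:
        return LEVELS[level]
    except KeyError:
        raise ValueError(f"unknown mesh level: {level!r}") from None


def point_to_indices(lat, lon, level: str):
    """Row/column cell indices of the cell containing (lat, lon).

    Rows count cells of ``level`` north from latitude 0; columns count east
    from longitude 100.  Accepts scalars or numpy arrays.
    """
    lat_s, lon_s = _cell_arcsec(level)
    row = np.floor(np.asarray(lat) * 3600.0 / lat_s + _EPS).astype(np.int64)
    col = np.floor((np.asarray(lon) - 100.0) * 3600.0 / lon_s + _EPS).astype(np.int64)
    if row.ndim == 0:
        return int(row), int(col)
    return row, col


def code_from_indices(row: int, col: int, level: str) -> str:
    """Digit string for the cell at integer (row, col) of ``level``."""
    if level == "1km":
        # 80 one-km rows per first-mesh band (40' = 80 * 30"); 10 per 10-km
        p, q, e = row // 80, (row % 80) // 10, row % 10
        u, v, f = col // 80, (col % 80) // 10, col % 10
        if not (0 <= p <= 99 and 0 <= u <= 99):
            raise ValueError(f"cell index out of code range: row={row}, col={col}")
        return f"{p:02d}{u:02d}{q}{v}{e}{f}"
    if level in ("500m", "250m"):
        parent = code_from_indices(row // 2, col // 2, "1km" if level == "500m" else "500m")
        return parent + str(1 + (col % 2) + 2 * (row % 2))
    if level == "100m":
        return code_from_indices(row // 10, col // 10, "1km") + str(row % 10) + str(col % 10)
    raise ValueError(f"unknown mesh level: {level!r}")


def indices_from_code(code: str, level: str) -> tuple[int, int]:
    """Inverse of :func:`code_from_indices`; raises on malformed codes."""
    mc = MeshCode(code, level)  # validates digits/length
    c = mc.code
    p, u = int(c[0:2]), int(c[2:4])
    q, v, e, f = int(c[4]), int(c[5]), int(c[6]), int(c[7])
    if q > 7 or v > 7:
        raise ValueError(f"malformed mesh code {code!r}: 10 km digit out of range")
    row_1km = 80 * p + 10 * q + e
    col_1km = 80 * u + 10 * v + f
    if level == "1km":
        return row_1km, col_1km
    if level == "100m":
        return 10 * row_1km + int(c[8]), 10 * col_1km + int(c[9])
    row, col = row_1km, col_1km
    for d in c[8:]:
        quad = int(d)
        if not 1 <= quad <= 4:
            raise ValueError(f"malformed mesh code {code!r}: quadrant digit {d}")
        quad -= 1
        row = 2 * row + quad // 2
        col = 2 * col + quad % 2
    return row, col


def to_mesh_code(lat: float, lon: float, level: str) -> MeshCode:
    """Code of the cell containing (lat, lon) at ``level``.

    Coordinates must lie in the standard-mesh domain, latitude [20, 46) and
    longitude [122, 154).
    """
    if not (LAT_MIN <= lat < LAT_MAX):
        raise ValueError(f"latitude {lat!r} outside standard-mesh domain [20, 46)")
    if not (LON_MIN <= lon < LON_MAX):
        raise ValueError(f"longitude {lon!r} outside standard-mesh domain [122, 154)")
    row, col = point_to_indices(lat, lon, level)
    return MeshCode(code_from_indices(row, col, level), level)


def mesh_bounds(code: MeshCode | str, level: str | None = None) -> GridBounds:
    """Geographic bounds of a cell; exact multiples of the level's extent."""
    if isinstance(code, MeshCode):
        code, level = code.code, code.level
    elif level is None:
        raise ValueError("level is required when passing a bare code string")
    row, col = indices_from_code(code, level)
    lat_s, lon_s = _cell_arcsec(level)
    south = row * lat_s / 3600.0
    west = 100.0 + col * lon_s / 3600.0
    return GridBounds(south, south + lat_s / 3600.0, west, west + lon_s / 3600.0)


def mesh_centroid(code: MeshCode | str, level: str | None = None) -> tuple[float, float]:
    """(lat, lon) midpoint of the cell's bounds."""
    b = mesh_bounds(code, level)
    return (b.south + b.north) / 2.0, (b.west + b.east) / 2.0


def _require_250m(mc: MeshCode) -> None:
    if mc.level != "250m":
        raise ValueError(f"expected a 250m mesh code, got level {mc.level!r}")


def neighbors_250m(code: MeshCode) -> set[MeshCode]:
    """The 8 queen-contiguous 250 m cells around ``code``.

    Works by index arithmetic, so parent-cell (quadrant and 1 km) boundaries
    are crossed correctly.
    """
    _require_250m(code)
    row, col = indices_from_code(code.code, "250m")
    out = set()
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            out.add(MeshCode(code_from_indices(row + dr, col + dc, "250m"), "250m"))
    return out


def coresident(codes: Iterable[MeshCode], adjacency: str = "queen") -> bool:
    """Whether a set of 250 m cells is mutually adjacent or shares a common
    adjacent cell.

    Under queen contiguity this is Chebyshev distance <= 2 between every
    pair (distance 1 = adjacent, distance 2 = a common neighbour exists).
    ``adjacency="rook"`` uses the stricter 4-neighbour reading: every pair
    must be rook-adjacent or share a rook neighbour (Manhattan distance <= 2).
    Singleton sets are trivially coresident.
    """
    codes = list(codes)
    if not codes:
        raise ValueError("coresident requires a non-empty set of codes")
    for mc in codes:
        _require_250m(mc)
    idx = [indices_from_code(mc.code, "250m") for mc in codes]
    for i in range(len(idx)):
        for j in range(i + 1, len(idx)):
            dr = abs(idx[i][0] - idx[j][0])
            dc = abs(idx[i][1] - idx[j][1])
            if adjacency == "queen":
                if max(dr, dc) > 2:
                    return False
            elif adjacency == "rook":
                if dr + dc > 2:
                    return False
            else:
                raise ValueError(f"unknown adjacency mode: {adjacency!r}")
    return True


def haversine_m(lat1, lon1, lat2, lon2, radius_m: float = 6_371_000.0):
    """Great-circle distance in metres (vectorized).

    Earth radius fixed at 6,371,000 m.
    """
    la1, lo1, la2, lo2 = (np.radians(np.asarray(a, dtype=float)) for a in (lat1, lon1, lat2, lon2))
    dlat = la2 - la1
    dlon = lo2 - lo1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(la1) * np.cos(la2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * radius_m * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
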