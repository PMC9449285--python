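"""Synthetic GPS world generator.

Real provider data of this kind are proprietary, so every pipeline stage is
exercised on a generated world that reproduces the data's structural quirks:
minute-resolution timestamps at irregular intervals, duplicate-minute logs,
horizontal-accuracy noise with a tail beyond the 200 m filter, masking of
all logs inside the 100 m grid square of the user's home, a minority of
users carrying daily step counts with complete sex/age attributes, and step
counts drawn from the step model itself (user random intercept plus smooth
land-use effects plus day-level Gaussian noise).

The landscape is a concentric city: a high-rise core, a dense low-rise
ring, a low-rise periphery, radial railway lines, a 1 km road lattice, and
scattered park and factory patches, rasterized on 100 m grid squares.  One
"storm weekend" can be configured on which travel is suppressed, emulating
a typhoon's effect on mobility.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import exposure as exposure_mod
from . import meshgrid
from .exposure import TYPES, LandUseGrid

M_PER_DEG_LAT = 111_320.0

#: representative original-category label emitted for each reclassified type
ORIGINAL_LABEL = {
    "high_rise": "High-rise buildings",
    "dense_low_rise": "Dense low-rise buildings",
    "low_rise": "Low-rise buildings",
    "factories": "Factories",
    "roads": "Roads",
    "railways": "Railways",
}
PARK_LABELS = ("Public facilities", "Parks and green spaces")
OTHER_LABELS = ("Forests", "Rice fields", "Vacant lands")


def _ramp(x, knee, slope):
    return slope * np.maximum(np.asarray(x, dtype=float) - knee, 0.0)


#: true smooth shapes on x = ln(count + 1): rising for the walkable core
#: types, falling beyond a threshold for car-dependent ones, flat for the
#: uninformative ones.  Units: steps per unit of x.
TRUE_SMOOTHS = {
    "high_rise": lambda x: _ramp(x, 1.0, 350.0),
    "dense_low_rise": lambda x: 250.0 * np.minimum(np.asarray(x, float), 3.0) - _ramp(x, 3.0, 300.0),
    "low_rise": lambda x: -_ramp(x, 2.0, 250.0),
    "factories": lambda x: -_ramp(x, 1.0, 200.0),
    "parks_public": lambda x: 180.0 * np.asarray(x, dtype=float),
    "roads": lambda x: np.zeros_like(np.asarray(x, dtype=float)),
    "railways": lambda x: 250.0 * np.asarray(x, dtype=float),
    "other": lambda x: np.zeros_like(np.asarray(x, dtype=float)),
}


@dataclass(frozen=True)
class WorldConfig:
    """Study conditions of the synthetic world."""

    # extent (a Sendai-sized box; >= 20 x 20 one-km cells required)
    lat_min: float = 38.15
    lat_max: float = 38.40
    lon_min: float = 140.70
    lon_max: float = 141.00

    n_users: int = 200
    start: dt.date = dt.date(2019, 10, 1)
    n_days: int = 31
    seed: int = 0

    # true step-model parameters
    alpha: float = 7700.0
    beta_sex: float = -400.0
    beta_age: float = -20.0
    sigma_l1: float = 2000.0
    sigma_l2: float = 500.0

    # sampling behaviour
    mean_logs_per_day: float = 60.0
    duplicate_rate: float = 0.05
    noise_sd_m: float = 30.0
    accuracy_tail_frac: float = 0.10
    walkcoin_frac: float = 0.20
    day_start_min: int = 450     # 07:30
    day_end_min: int = 1290      # 21:30
    n_home_cells: int = 20

    # storm scenario: travel suppressed on these dates
    storm_dates: tuple = (dt.date(2019, 10, 12), dt.date(2019, 10, 13))
    storm_suppression: float = 0.15

    def dates(self) -> list:
        return [self.start + dt.timedelta(days=i) for i in range(self.n_days)]


# -- landscape -------------------------------------------------------------

def generate_landscape(config: WorldConfig) -> pd.DataFrame:
    """Land-use table (mesh_code_100m, original_type) for the extent.

    Deterministic for a given config.  About half the ``other`` cells are
    omitted from the table, emulating area outside the urban land-use
    survey (consumers must default absent cells to ``other``).
    """
    if (config.lat_max - config.lat_min) * 120 < 20 or (config.lon_max - config.lon_min) * 80 < 20:
        raise ValueError("extent too small: need at least 20 x 20 one-km cells")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))

    r0, c0 = meshgrid.point_to_indices(config.lat_min, config.lon_min, "100m")
    r1, c1 = meshgrid.point_to_indices(config.lat_max - 1e-9, config.lon_max - 1e-9, "100m")
    rows = np.arange(r0, r1 + 1)
    cols = np.arange(c0, c1 + 1)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    clat, clon = exposure_mod._centroid_of_indices(rr, cc)

    lat_c = (config.lat_min + config.lat_max) / 2
    lon_c = (config.lon_min + config.lon_max) / 2
    dx = (clon - lon_c) * M_PER_DEG_LAT * np.cos(np.radians(lat_c))
    dy = (clat - lat_c) * M_PER_DEG_LAT
    d = np.hypot(dx, dy)

    t = np.full(rr.shape, TYPES.index("other"), dtype=np.int8)
    t[d < 8000] = TYPES.index("low_rise")
    t[d < 3500] = TYPES.index("dense_low_rise")
    t[d < 1200] = TYPES.index("high_rise")

    # 1 km road lattice
    road = (rr % 10 == 0) | (cc % 10 == 0)
    t[road & (d < 9000)] = TYPES.index("roads")

    # park and factory patches (squares), parks mid-ring, factories outer
    for _ in range(15):
        pr = rng.integers(r0, r1 - 5)
        pc = rng.integers(c0, c1 - 5)
        size = int(rng.integers(3, 7))
        sel = (rr >= pr) & (rr < pr + size) & (cc >= pc) & (cc < pc + size)
        if d[sel].mean() < 7000:
            t[sel] = TYPES.index("parks_public")
    for _ in range(8):
        pr = rng.integers(r0, r1 - 5)
        pc = rng.integers(c0, c1 - 5)
        size = int(rng.integers(4, 8))
        sel = (rr >= pr) & (rr < pr + size) & (cc >= pc) & (cc < pc + size)
        if 5000 < d[sel].mean() < 10000:
            t[sel] = TYPES.index("factories")

    # radial railway lines along the centre row and column, 1 cell wide
    rc = (r0 + r1) // 2
    ccol = (c0 + c1) // 2
    t[(rr == rc) | (cc == ccol)] = TYPES.index("railways")

    # emit table rows; drop about half of the "other" cells
    flat_t = t.ravel()
    flat_r = rr.ravel()
    flat_c = cc.ravel()
    is_other = flat_t == TYPES.index("other")
    keep = ~is_other | (rng.random(flat_t.size) < 0.5)
    park_pick = rng.integers(0, 2, size=flat_t.size)
    other_pick = rng.integers(0, len(OTHER_LABELS), size=flat_t.size)

    labels = np.empty(flat_t.size, dtype=object)
    for k, name in enumerate(TYPES):
        sel = flat_t == k
        if name == "parks_public":
            labels[sel] = np.asarray(PARK_LABELS, dtype=object)[park_pick[sel]]
        elif name == "other":
            labels[sel] = np.asarray(OTHER_LABELS, dtype=object)[other_pick[sel]]
        else:
            labels[sel] = ORIGINAL_LABEL[name]

    codes = [
        meshgrid.code_from_indices(int(r), int(c), "100m")
        for r, c in zip(flat_r[keep], flat_c[keep])
    ]
    return pd.DataFrame({"mesh_code_100m": codes, "original_type": labels[keep]})


# -- users -----------------------------------------------------------------

AGE_GROUPS = ["10s", "20s", "30s", "40s", "50s", "60s", "70plus"]
AGE_P = [0.08, 0.29, 0.27, 0.22, 0.10, 0.02, 0.02]


def generate_users(config: WorldConfig, landscape: pd.DataFrame | None = None) -> pd.DataFrame:
    """User table: uuid, home position/cells, sex, age_group, walkcoin flag.

    Homes sit at the centre of 250 m cells drawn from a pool of
    ``n_home_cells`` residential (dense/low-rise) cells, never on railway
    cells.  Exactly ``round(walkcoin_frac * n_users)`` users carry step
    counts, and those users always have known sex and age.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    landscape = landscape if landscape is not None else generate_landscape(config)
    grid = LandUseGrid(landscape)

    lat_c = (config.lat_min + config.lat_max) / 2
    lon_c = (config.lon_min + config.lon_max) / 2

    # pool of residential 250 m cells: home centre's 100 m cell must be a
    # dense/low-rise cell 1.5-7 km from the centre
    pool = []
    tries = 0
    while len(pool) < config.n_home_cells and tries < 20000:
        tries += 1
        lat = rng.uniform(config.lat_min + 0.01, config.lat_max - 0.01)
        lon = rng.uniform(config.lon_min + 0.01, config.lon_max - 0.01)
        r250, c250 = meshgrid.point_to_indices(lat, lon, "250m")
        b = meshgrid.mesh_bounds(meshgrid.code_from_indices(r250, c250, "250m"), "250m")
        hlat, hlon = (b.south + b.north) / 2, (b.west + b.east) / 2
        dx = (hlon - lon_c) * M_PER_DEG_LAT * np.cos(np.radians(lat_c))
        dy = (hlat - lat_c) * M_PER_DEG_LAT
        if not 1500 < np.hypot(dx, dy) < 7000:
            continue
        r100, c100 = meshgrid.point_to_indices(hlat, hlon, "100m")
        tid = int(grid.type_ids(np.array([r100]), np.array([c100]))[0])
        if TYPES[tid] not in ("dense_low_rise", "low_rise"):
            continue
        key = (r250, c250)
        if key not in [p[0] for p in pool]:
            pool.append((key, (hlat, hlon)))
    if len(pool) < config.n_home_cells:
        raise ValueError("could not find enough residential home cells in the extent")

    n = config.n_users
    n_wc = int(round(config.walkcoin_frac * n))
    wc = np.zeros(n, dtype=bool)
    wc[rng.permutation(n)[:n_wc]] = True

    rows = []
    for i in range(n):
        (r250, c250), (hlat, hlon) = pool[int(rng.integers(0, len(pool)))]
        if wc[i]:
            sex = "female" if rng.random() < 0.45 else "male"
            age = AGE_GROUPS[int(rng.choice(len(AGE_GROUPS), p=AGE_P))]
        else:
            u = rng.random()
            sex = "unknown" if u < 0.6 else ("male" if u < 0.85 else "female")
            age = "unknown"
        rows.append(
            {
                "uuid": f"u{i:04d}",
                "home_lat": hlat,
                "home_lon": hlon,
                "home_250m": meshgrid.code_from_indices(r250, c250, "250m"),
                "home_100m": meshgrid.code_from_indices(
                    *meshgrid.point_to_indices(hlat, hlon, "100m"), "100m"
                ),
                "sex": sex,
                "age_group": age,
                "walkcoin": bool(wc[i]),
            }
        )
    return pd.DataFrame(rows)


# -- daily trajectories and logs ------------------------------------------

def _day_path(user_row, date, config: WorldConfig, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """True minute-resolution path for one user-day.

    Returns (minutes-of-day, lat, lon) over the active window.  The path is
    anchor-based: dwell at home, travel to 1-3 destinations with dwells,
    return home.  On storm dates destination distances shrink by the
    suppression factor.
    """
    lat_c = (config.lat_min + config.lat_max) / 2
    lon_c = (config.lon_min + config.lon_max) / 2
    hlat, hlon = user_row["home_lat"], user_row["home_lon"]
    storm = date in set(config.storm_dates)
    shrink = config.storm_suppression if storm else 1.0

    n_dest = int(rng.integers(1, 4))
    dests = []
    for _ in range(n_dest):
        u = rng.random()
        if not storm and u < 0.55:
            # downtown trip
            base_lat, base_lon = lat_c, lon_c
            spread = 800.0
        elif not storm and u < 0.75:
            # periphery errand (reaches the outer factory/park ring)
            base_lat, base_lon = lat_c, lon_c
            spread = 5000.0
        else:
            base_lat, base_lon = hlat, hlon
            spread = 1200.0 * shrink
        dlat = rng.normal(0.0, spread) / M_PER_DEG_LAT
        dlon = rng.normal(0.0, spread) / (M_PER_DEG_LAT * np.cos(np.radians(lat_c)))
        dests.append((base_lat + dlat, base_lon + dlon))

    t0, t1 = config.day_start_min, config.day_end_min
    t_dep = t0 + rng.uniform(45, 150)
    t_ret = t1 - rng.uniform(45, 150)
    anchors_t = [t0, t_dep]
    anchors_ll = [(hlat, hlon), (hlat, hlon)]
    span = (t_ret - t_dep) / n_dest
    for j, d in enumerate(dests):
        arr = t_dep + span * j + 0.35 * span
        dep = t_dep + span * (j + 1) - 0.05 * span
        anchors_t += [arr, dep]
        anchors_ll += [d, d]
    anchors_t += [t_ret, t1]
    anchors_ll += [(hlat, hlon), (hlat, hlon)]

    minutes = np.arange(t0, t1 + 1)
    at = np.asarray(anchors_t)
    lat = np.interp(minutes, at, [p[0] for p in anchors_ll])
    lon = np.interp(minutes, at, [p[1] for p in anchors_ll])
    return minutes, lat, lon


def generate_logs(user_row, date, config: WorldConfig, rng) -> pd.DataFrame:
    """Raw GPS logs for one user-day, with the provider's quirks applied.

    Irregular minute sampling (geometric gaps), Gaussian positional noise,
    an accuracy field with a tail above 200 m, occasional duplicate
    minutes, and deletion of every log inside the home 100 m grid square.
    """
    minutes, plat, plon = _day_path(user_row, date, config, rng)
    window = minutes[-1] - minutes[0]
    # oversample so that the emitted rate matches mean_logs_per_day after
    # home-cell masking removes the logs of the home dwell (~1/8 of the day)
    target = config.mean_logs_per_day * 1.12
    mean_gap = max(window / target, 1.0)
    gaps = rng.geometric(1.0 / mean_gap, size=int(3 * config.mean_logs_per_day + 20))
    tms = minutes[0] + np.concatenate([[0], np.cumsum(gaps)])
    tms = tms[tms <= minutes[-1]]

    # duplicates: re-log the same minute
    dup = rng.random(tms.size) < config.duplicate_rate
    tms = np.sort(np.concatenate([tms, tms[dup]]))

    idx = (tms - minutes[0]).astype(np.int64)
    sd_lat = config.noise_sd_m / M_PER_DEG_LAT
    sd_lon = config.noise_sd_m / (M_PER_DEG_LAT * np.cos(np.radians(user_row["home_lat"])))
    lat = plat[idx] + rng.normal(0.0, sd_lat, size=idx.size)
    lon = plon[idx] + rng.normal(0.0, sd_lon, size=idx.size)

    acc = np.exp(rng.normal(np.log(25.0), 0.5, size=idx.size))
    tail = rng.random(idx.size) < config.accuracy_tail_frac
    acc[tail] = rng.uniform(200.0, 400.0, size=int(tail.sum()))

    # privacy masking: no logs inside the home 100 m grid square
    hr, hc = meshgrid.indices_from_code(user_row["home_100m"], "100m")
    r, c = meshgrid.point_to_indices(lat, lon, "100m")
    keep = ~((r == hr) & (c == hc))

    t = pd.Timestamp(date) + pd.to_timedelta(tms[keep], unit="min")
    return pd.DataFrame(
        {
            "uuid": user_row["uuid"],
            "t": t,
            "lat": lat[keep],
            "lon": lon[keep],
            "accuracy_m": acc[keep],
            "sex": user_row["sex"],
            "age_group": user_row["age_group"],
            "daily_steps": np.nan,
        }
    )


# -- step counts -----------------------------------------------------------

def true_smooth_sum(counts: pd.DataFrame) -> np.ndarray:
    """sum_k s_k(ln(count_k + 1)) under the generator's true smooths."""
    total = np.zeros(len(counts))
    for name in TYPES:
        total += TRUE_SMOOTHS[name](np.log1p(counts[name].to_numpy(float)))
    return total


def generate_steps(
    counts: pd.DataFrame, sex01, age, b0u, config: WorldConfig, rng
) -> np.ndarray:
    """Daily step counts from the true model, floored at zero.

    ``counts`` holds the 8 true exposure columns per user-day; ``b0u`` is
    the user's random intercept (one value per row), ``sex01`` and ``age``
    the numeric codings.
    """
    eps = rng.normal(0.0, config.sigma_l1, size=len(counts))
    y = (
        np.asarray(b0u, dtype=float)
        + config.beta_sex * np.asarray(sex01, dtype=float)
        + config.beta_age * np.asarray(age, dtype=float)
        + true_smooth_sum(counts)
        + eps
    )
    return np.maximum(y, 0.0)


_SEX01 = {"male": 0.0, "female": 1.0}
_AGENUM = {"10s": 10.0, "20s": 20.0, "30s": 30.0, "40s": 40.0, "50s": 50.0,
           "60s": 60.0, "70plus": 70.0}


@dataclass
class World:
    """A fully generated synthetic study."""

    config: WorldConfig
    landscape: pd.DataFrame
    users: pd.DataFrame
    logs: pd.DataFrame
    truth: pd.DataFrame          # per walkcoin user-day: true exposure + steps
    user_intercepts: pd.DataFrame  # uuid, b0u


def generate_world(config: WorldConfig | None = None, seed: int | None = None) -> World:
    """Generate landscape, users, logs, and step-count truth in one call."""
    config = config or WorldConfig()
    if seed is not None:
        config = replace(config, seed=int(seed))
    landscape = generate_landscape(config)
    users = generate_users(config, landscape)
    grid = LandUseGrid(landscape)

    # one child stream per user-day so the true path can be replayed exactly
    frames = []
    truth_points = []
    for i, (_, u) in enumerate(users.iterrows()):
        for j, date in enumerate(config.dates()):
            day_seed = np.random.SeedSequence([config.seed, 303, i, j])
            frames.append(generate_logs(u, date, config, np.random.default_rng(day_seed)))
            if u["walkcoin"]:
                minutes, plat, plon = _day_path(
                    u, date, config, np.random.default_rng(day_seed)
                )
                truth_points.append(
                    pd.DataFrame(
                        {
                            "uuid": u["uuid"],
                            "t": pd.Timestamp(date) + pd.to_timedelta(minutes, unit="min"),
                            "lat": plat,
                            "lon": plon,
                        }
                    )
                )
    logs = pd.concat(frames, ignore_index=True)

    # true exposure of step-reporting users: minute path, home 250 m cell
    # excluded (mirroring the residential-grid stripping)
    b0u = {
        u: float(v)
        for u, v in zip(
            users["uuid"],
            np.random.default_rng(np.random.SeedSequence([config.seed, 404])).normal(
                config.alpha, config.sigma_l2, size=len(users)
            ),
        )
    }
    truth = pd.DataFrame(columns=["uuid", "date", "steps", "sex", "age_group"] + TYPES)
    if truth_points:
        tp = pd.concat(truth_points, ignore_index=True)
        home = {
            str(r["uuid"]): meshgrid.indices_from_code(r["home_250m"], "250m")
            for _, r in users.iterrows()
        }
        r250, c250 = meshgrid.point_to_indices(
            tp["lat"].to_numpy(float), tp["lon"].to_numpy(float), "250m"
        )
        at_home = np.fromiter(
            (home[u] == (r, c) for u, r, c in zip(tp["uuid"], r250, c250)),
            dtype=bool,
            count=len(tp),
        )
        counts = exposure_mod.count_exposure(tp[~at_home], grid)
        attrs = users.set_index("uuid")
        sex01 = counts["uuid"].map(lambda u: _SEX01[attrs.loc[u, "sex"]]).to_numpy()
        age = counts["uuid"].map(lambda u: _AGENUM[attrs.loc[u, "age_group"]]).to_numpy()
        b = counts["uuid"].map(b0u).to_numpy()
        srng = np.random.default_rng(np.random.SeedSequence([config.seed, 505]))
        steps = generate_steps(counts[TYPES], sex01, age, b, config, srng)
        truth = counts.copy()
        truth.insert(2, "steps", np.round(steps))
        truth.insert(3, "sex", truth["uuid"].map(attrs["sex"]))
        truth.insert(4, "age_group", truth["uuid"].map(attrs["age_group"]))

        # stamp daily step counts onto the walkcoin users' raw logs
        key = pd.MultiIndex.from_arrays(
            [truth["uuid"], pd.to_datetime(truth["date"]).dt.normalize()]
        )
        step_map = pd.Series(truth["steps"].to_numpy(), index=key)
        log_key = pd.MultiIndex.from_arrays([logs["uuid"], logs["t"].dt.normalize()])
        logs["daily_steps"] = step_map.reindex(log_key).to_numpy()

    intercepts = pd.DataFrame({"uuid": list(b0u), "b0u": list(b0u.values())})
    return World(config, landscape, users, logs, truth, intercepts)


def write_world(world: World, outdir) -> dict:
    """Write the log table, land-use table, and truth files as CSV."""
    import os

    os.makedirs(outdir, exist_ok=True)
    logs = world.logs.copy()
    t = logs.pop("t")
    logs.insert(1, "year", t.dt.year)
    logs.insert(2, "month", t.dt.month)
    logs.insert(3, "day", t.dt.day)
    logs.insert(4, "hour", t.dt.hour)
    logs.insert(5, "minute", t.dt.minute)
    paths = {
        "logs": f"{outdir}/logs.csv",
        "landuse": f"{outdir}/landuse.csv",
        "users": f"{outdir}/truth_users.csv",
        "truth": f"{outdir}/truth_exposure.csv",
        "intercepts": f"{outdir}/truth_intercepts.csv",
    }
    logs.to_csv(paths["logs"], index=False)
    world.landscape.to_csv(paths["landuse"], index=False)
    world.users.to_csv(paths["users"], index=False)
    world.truth.to_csv(paths["truth"], index=False)
    world.user_intercepts.to_csv(paths["intercepts"], index=False)
    return paths


# -- model-level generator (for parameter-recovery studies) ----------------

#: upper ends of the exposure-index ranges sampled per type
X_MAX = {
    "high_rise": 6.0,
    "dense_low_rise": 6.0,
    "low_rise": 5.0,
    "factories": 4.0,
    "parks_public": 4.0,
    "roads": 5.0,
    "railways": 4.0,
    "other": 7.0,
}


def generate_model_records(
    n_users: int = 200,
    n_days: int = 20,
    config: WorldConfig | None = None,
    seed: int = 0,
    null: bool = False,
) -> pd.DataFrame:
    """Exposure records with known-truth step counts, no GPS layer.

    Counts are drawn directly (zero-inflated, log-uniform) so the observed
    exposure indices cover each smooth's range; steps follow the true
    model.  ``null=True`` sets all smooths, sex/age effects, and the
    user-level variance to zero, leaving pure day-level noise around the
    grand mean.
    """
    config = config or WorldConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 606]))
    n = n_users * n_days

    counts = {}
    for name in TYPES:
        z = rng.uniform(0.0, X_MAX[name], size=n)
        z[rng.random(n) < 0.2] = 0.0
        counts[name] = np.round(np.expm1(z)).astype(np.int64)
    counts = pd.DataFrame(counts)

    sex = np.where(rng.random(n_users) < 0.5, "female", "male")
    age = rng.choice(["10s", "20s", "30s", "40s", "50s", "60s"], size=n_users)
    uid = np.repeat(np.arange(n_users), n_days)
    sex01 = np.array([_SEX01[s] for s in sex])[uid]
    agen = np.array([_AGENUM[a] for a in age])[uid]

    sigma_l2 = 0.0 if null else config.sigma_l2
    b0 = rng.normal(config.alpha, sigma_l2, size=n_users)[uid]
    eps = rng.normal(0.0, config.sigma_l1, size=n)
    if null:
        y = b0 + eps
    else:
        y = (
            b0
            + config.beta_sex * sex01
            + config.beta_age * agen
            + true_smooth_sum(counts)
            + eps
        )
    y = np.maximum(y, 0.0)

    out = pd.DataFrame(
        {
            "uuid": [f"u{i:04d}" for i in uid],
            "date": np.tile(pd.date_range("2019-10-01", periods=n_days), n_users),
            "steps": np.round(y),
            "sex": np.asarray(sex)[uid],
            "age_group": np.asarray(age)[uid],
        }
    )
    return pd.concat([out, counts], axis=1)
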