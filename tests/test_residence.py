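"""Residence estimation: 5% sets, modal grids, merging, stripping, region."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from stepscape import meshgrid as mg
from stepscape import residence


def _points(uuid, items):
    return pd.DataFrame(
        [
            {"uuid": uuid, "t": pd.Timestamp(t), "lat": la, "lon": lo, "origin": "observed"}
            for t, la, lo in items
        ]
    )


def _day(uuid, date, n, lat=38.26, lon=140.87):
    base = pd.Timestamp(date) + pd.Timedelta(hours=6)
    return _points(uuid, [(base + pd.Timedelta(minutes=i), lat, lon) for i in range(n)])


class TestFivePercentSet:
    @pytest.mark.parametrize("n,expected", [(100, 10), (10, 2), (1, 1), (30, 4)])
    def test_sizes(self, n, expected):
        out = residence.five_percent_set(_day("a", "2019-10-01", n))
        assert len(out) == expected  # max(1, ceil(.05 n)) from each end

    def test_takes_the_ends(self):
        day = _day("a", "2019-10-01", 100)
        out = residence.five_percent_set(day)
        assert list(out["t"]) == list(day["t"].iloc[:5]) + list(day["t"].iloc[-5:])

    def test_whole_day_when_ends_overlap(self):
        out = residence.five_percent_set(_day("a", "2019-10-01", 2))
        assert len(out) == 2


class TestDailyModalGrid:
    def test_majority_cell(self):
        c_a = mg.to_mesh_code(38.26, 140.87, "250m")
        a_lat, a_lon = mg.mesh_centroid(c_a)
        b_lat, b_lon = mg.mesh_centroid(
            next(iter(mg.neighbors_250m(c_a)))
        )
        pts = _points(
            "a",
            [(f"2019-10-01 08:0{i}", a_lat, a_lon) for i in range(3)]
            + [(f"2019-10-01 09:0{i}", b_lat, b_lon) for i in range(2)],
        )
        assert residence.daily_modal_grid(pts) == c_a.code

    def test_tie_breaks_to_smallest_code(self):
        r, c = mg.indices_from_code(mg.to_mesh_code(38.26, 140.87, "250m").code, "250m")
        codes = [mg.code_from_indices(r, c, "250m"), mg.code_from_indices(r, c + 1, "250m")]
        pts_list = []
        for i, code in enumerate(codes):
            la, lo = mg.mesh_centroid(code, "250m")
            pts_list += [(f"2019-10-01 08:{10*i+j:02d}", la, lo) for j in range(2)]
        out = residence.daily_modal_grid(_points("a", pts_list))
        assert out == min(codes)
        # enumeration oracle: both cells are indeed modal
        rows, cols = mg.point_to_indices(
            _points("a", pts_list)["lat"].to_numpy(), _points("a", pts_list)["lon"].to_numpy(), "250m"
        )
        counts = pd.Series([mg.code_from_indices(r_, c_, "250m") for r_, c_ in zip(rows, cols)]).value_counts()
        assert set(counts[counts == counts.max()].index) == set(codes)


def _month_of_days(uuid, grids_by_day, n_mid=40):
    """Synthesize a month: each day starts/ends in the given 250m cell."""
    frames = []
    for day, code in grids_by_day:
        la, lo = mg.mesh_centroid(code, "250m")
        base = pd.Timestamp(day)
        items = [(base + pd.Timedelta(hours=6, minutes=i), la, lo) for i in range(3)]
        items += [
            (base + pd.Timedelta(hours=12, minutes=i), 38.30, 140.95) for i in range(n_mid)
        ]
        items += [(base + pd.Timedelta(hours=21, minutes=i), la, lo) for i in range(3)]
        frames.append(_points(uuid, items))
    return pd.concat(frames, ignore_index=True)


def _codes_around(lat=38.26, lon=140.87):
    base = mg.to_mesh_code(lat, lon, "250m")
    r, c = mg.indices_from_code(base.code, "250m")
    return base.code, r, c


class TestEstimateResidence:
    def test_dominant_grid_recovered_with_centroid(self):
        code, r, c = _codes_around()
        days = [(dt.date(2019, 10, d), code) for d in range(1, 21)]
        other = mg.code_from_indices(r, c + 5, "250m")
        days += [(dt.date(2019, 10, d), other) for d in range(21, 26)]
        pts = _month_of_days("a", days)
        res = residence.estimate_residence(pts)
        assert res.status == "valid"
        assert res.residential_grids == frozenset({code})
        la, lo = mg.mesh_centroid(code, "250m")
        assert res.residence_lat == pytest.approx(la, abs=1e-6)
        assert res.residence_lon == pytest.approx(lo, abs=1e-6)

    def test_adjacent_tie_merges_both(self):
        code, r, c = _codes_around()
        adj = mg.code_from_indices(r, c + 1, "250m")
        days = [(dt.date(2019, 10, d), code) for d in range(1, 11)]
        days += [(dt.date(2019, 10, d), adj) for d in range(11, 21)]
        res = residence.estimate_residence(_month_of_days("a", days))
        assert res.status == "valid"
        assert res.residential_grids == frozenset({code, adj})

    def test_far_tie_is_undefinable(self):
        code, r, c = _codes_around()
        far = mg.code_from_indices(r, c + 5, "250m")
        days = [(dt.date(2019, 10, d), code) for d in range(1, 11)]
        days += [(dt.date(2019, 10, d), far) for d in range(11, 21)]
        res = residence.estimate_residence(_month_of_days("a", days))
        assert res.status == "undefinable"
        assert np.isnan(res.residence_lat)

    def test_deterministic(self):
        code, r, c = _codes_around()
        days = [(dt.date(2019, 10, d), code) for d in range(1, 15)]
        pts = _month_of_days("a", days)
        r1 = residence.estimate_residence(pts)
        r2 = residence.estimate_residence(pts.sample(frac=1.0, random_state=3))
        assert r1 == r2


class TestFilterResidential:
    def test_strips_home_points_only(self):
        code, r, c = _codes_around()
        days = [(dt.date(2019, 10, d), code) for d in range(1, 15)]
        pts = _month_of_days("a", days)
        res = residence.estimate_residence(pts)
        out = residence.filter_residential(pts, res)
        # geometric oracle: count points whose 250m bounds contain them
        b = mg.mesh_bounds(code, "250m")
        inside = pts.apply(lambda q: b.contains(q["lat"], q["lon"]), axis=1)
        assert len(out) == len(pts) - int(inside.sum())
        rows, cols = mg.point_to_indices(out["lat"].to_numpy(), out["lon"].to_numpy(), "250m")
        assert (r, c) not in set(zip(rows, cols))

    def test_other_users_conserved(self):
        code, r, c = _codes_around()
        days = [(dt.date(2019, 10, d), code) for d in range(1, 15)]
        pts_a = _month_of_days("a", days)
        pts_b = _month_of_days("b", days)
        both = pd.concat([pts_a, pts_b], ignore_index=True)
        res_a = residence.estimate_residence(pts_a, uuid="a")
        out = residence.filter_residential(both, res_a)
        assert (out["uuid"] == "b").sum() == len(pts_b)

    def test_undefinable_is_state_error(self):
        r = residence.ResidenceResult("a", "undefinable", frozenset(), np.nan, np.nan)
        with pytest.raises(ValueError, match="undefinable"):
            residence.filter_residential(_day("a", "2019-10-01", 3), r)

    def test_batch_matches_per_user(self):
        code, r, c = _codes_around()
        days = [(dt.date(2019, 10, d), code) for d in range(1, 15)]
        pts = pd.concat(
            [_month_of_days("a", days), _month_of_days("b", days)], ignore_index=True
        )
        res_tab = residence.estimate_residences(pts)
        batch = residence.filter_residential_all(pts, res_tab)
        ra = residence.estimate_residence(pts[pts["uuid"] == "a"], uuid="a")
        single = residence.filter_residential(pts[pts["uuid"] == "a"], ra)
        assert (batch["uuid"] == "a").sum() == len(single)


class TestRestrictRegion:
    def _residences(self):
        return pd.DataFrame(
            {
                "uuid": ["a", "b"],
                "status": ["valid", "valid"],
                "residential_grid_codes": ["", ""],
                "residence_lat": [38.26, 39.5],
                "residence_lon": [140.87, 141.5],
            }
        )

    def test_box_and_polygon_and_none(self):
        res = self._residences()
        box = (140.0, 38.0, 141.0, 39.0)
        assert list(residence.restrict_region(res, box)["uuid"]) == ["a"]
        ring = [(140.0, 38.0), (141.0, 38.0), (141.0, 39.0), (140.0, 39.0)]
        assert list(residence.restrict_region(res, ring)["uuid"]) == ["a"]
        assert len(residence.restrict_region(res, None)) == 2
        assert len(residence.restrict_region(res, "none")) == 2

    def test_malformed_region(self):
        with pytest.raises(ValueError, match="region"):
            residence.restrict_region(self._residences(), (1.0, 2.0))
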