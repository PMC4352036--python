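"""Presence/background assembly, withholding arithmetic, and combination."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from sdmtransfer import reference
from sdmtransfer.datasets import (SplitSpec, annotate_covariates,
                                  build_background, build_presences,
                                  combine_populations, round_half_away,
                                  withhold_split)
from sdmtransfer.density import containment_contour, kernel_density
from sdmtransfer.geospatial import EqualAreaFrame
from sdmtransfer.tracks import TrackSet

FRAME = EqualAreaFrame(0.0, -50.0)


def _tracks(frame, xy, month):
    lon, lat = frame.inverse(xy[:, 0], xy[:, 1])
    n = len(lon)
    idx = np.arange(n)
    ts = pd.to_datetime({"year": np.full(n, 2009 if month >= 10 else 2010),
                         "month": np.full(n, month),
                         "day": (idx // 2) % 28 + 1,
                         "hour": np.where(idx % 2 == 0, 0, 12)})
    return pd.DataFrame({"bird_id": np.char.add("b", (idx // 56).astype(str)),
                         "colony": "c", "timestamp": ts,
                         "lon": lon, "lat": lat})


@pytest.fixture()
def cluster_tracks(rng):
    xy = np.column_stack([rng.normal(0, 250, 80), rng.normal(0, 250, 80)])
    return TrackSet(_tracks(FRAME, xy, 11)), xy


class TestBuildPresences:
    def test_all_inside_counts_all(self, cluster_tracks):
        tracks, xy = cluster_tracks
        surf = kernel_density(xy, 200, 25, FRAME)
        cores = {11: containment_contour(surf, xy, 99.99)}
        pres = build_presences(tracks, cores, population="p")
        assert len(pres) == len(tracks)
        assert (pres["label"] == 1).all()

    def test_count_matches_polygon_oracle(self, cluster_tracks):
        from matplotlib.path import Path

        tracks, xy = cluster_tracks
        surf = kernel_density(xy, 200, 25, FRAME)
        cores = {11: containment_contour(surf, xy, 50)}
        pres = build_presences(tracks, cores, population="p")
        # independent point-in-polygon oracle (matplotlib path, tiny outward
        # tolerance for boundary-inclusive semantics)
        count = 0
        polys = [Path(np.asarray(p.exterior.coords)) for p in cores[11].polygons]
        for p in xy:
            count += any(path.contains_point(p, radius=1e-6) for path in polys)
        assert len(pres) == count

    def test_missing_month_contour(self, cluster_tracks):
        tracks, _ = cluster_tracks
        with pytest.raises(ValueError, match="month 11"):
            build_presences(tracks, {}, population="p")

    def test_boundary_fix_counts_inside(self):
        anchor = np.array([[12.0, 12.0]])
        surf = kernel_density(np.tile(anchor, (30, 1)), 200, 25, FRAME)
        core = containment_contour(surf, np.tile(anchor, (30, 1)), 50)
        corner = core.union.exterior.coords[0]  # a point exactly on the boundary
        assert core.contains_xy([corner[0]], [corner[1]])[0]


class TestBuildBackground:
    def test_month_replication(self, cluster_tracks):
        tracks, xy = cluster_tracks
        surf = kernel_density(xy, 200, 25, FRAME)
        avail = containment_contour(surf, xy, 90)
        bg = build_background(avail, months=[10, 11, 12], population="p")
        per_month = bg.groupby("month").size()
        assert per_month.nunique() == 1
        coords = {m: sorted(zip(g["lon"], g["lat"])) for m, g in bg.groupby("month")}
        assert coords[10] == coords[11] == coords[12]

    def test_lattice_covers_core_region(self, cluster_tracks):
        # background must extend through the 50% core, not mask it out
        tracks, xy = cluster_tracks
        surf = kernel_density(xy, 200, 25, FRAME)
        avail = containment_contour(surf, xy, 90)
        core = containment_contour(surf, xy, 50)
        bg = build_background(avail, months=[11], spacing_km=50.0, population="p")
        inside_core = core.contains_lonlat(bg["lon"].to_numpy(), bg["lat"].to_numpy())
        assert inside_core.any()

    def test_empty_lattice_error(self, cluster_tracks):
        tracks, xy = cluster_tracks
        surf = kernel_density(xy[:1], 200, 25, FRAME)
        tiny = containment_contour(surf, xy[:1], 50)
        with pytest.raises(ValueError):
            build_background(tiny, months=[11], spacing_km=5000.0)


class TestAnnotateCovariates:
    @pytest.fixture()
    def small_env(self):
        lats = np.array([-50.25, -49.75])
        lons = np.array([10.25, 10.75])
        months = [11, 12]
        static = {v: (("lat", "lon"), np.full((2, 2), i + 1.0))
                  for i, v in enumerate(["depth", "slope", "geomorph",
                                         "dist_seamount"])}
        dyn_base = {"mld": [80.0, 120.0], "t050": [10.0, 11.0],
                    "curr": [0.2, 0.3], "eke": [100.0, 150.0],
                    "chl": [0.5, 0.6]}
        dyn = {v: (("month", "lat", "lon"),
                   np.stack([np.full((2, 2), a), np.full((2, 2), b)]))
               for v, (a, b) in dyn_base.items()}
        return xr.Dataset({**static, **dyn},
                          coords={"lat": lats, "lon": lons, "month": months})

    def test_month_matched_extraction(self, small_env):
        rows = pd.DataFrame({"label": [1, 1], "month": [11, 12],
                             "weight": 1.0, "population": "p",
                             "lon": [10.3, 10.3], "lat": [-50.2, -50.2]})
        out = annotate_covariates(rows, small_env)
        assert out.loc[out["month"] == 11, "mld"].iloc[0] == 80.0
        assert out.loc[out["month"] == 12, "mld"].iloc[0] == 120.0
        assert (out["depth"] == 1.0).all()  # static, month-invariant

    def test_out_of_extent_dropped(self, small_env):
        rows = pd.DataFrame({"label": [1, 1], "month": [11, 11], "weight": 1.0,
                             "population": "p", "lon": [10.3, 40.0],
                             "lat": [-50.2, -50.2]})
        out = annotate_covariates(rows, small_env)
        assert len(out) == 1

    def test_nearest_cell_oracle(self, mini_env, rng):
        lons = rng.uniform(float(mini_env.lon.min()), float(mini_env.lon.max()), 1000)
        lats = rng.uniform(float(mini_env.lat.min()), float(mini_env.lat.max()), 1000)
        rows = pd.DataFrame({"label": 1, "month": 11, "weight": 1.0,
                             "population": "p", "lon": lons, "lat": lats})
        out = annotate_covariates(rows, mini_env)
        grid_lon = mini_env["lon"].to_numpy()
        grid_lat = mini_env["lat"].to_numpy()
        depth = mini_env["depth"].to_numpy()
        mld = mini_env["mld"].sel(month=11).to_numpy()
        for k in rng.choice(len(out), 50, replace=False):
            i = np.abs(grid_lat - out["lat"].iloc[k]).argmin()
            j = np.abs(grid_lon - out["lon"].iloc[k]).argmin()
            assert out["depth"].iloc[k] == depth[i, j]
            assert out["mld"].iloc[k] == mld[i, j]


def _synthetic_table(rng, monthly_presences, monthly_background):
    rows = []
    for m, n_p in monthly_presences.items():
        for label, n in ((1, n_p), (0, monthly_background)):
            rows.append(pd.DataFrame({
                "label": label, "month": m, "weight": 1.0, "population": "p",
                "lon": rng.uniform(0, 10, n), "lat": rng.uniform(-55, -45, n)}))
    return pd.concat(rows, ignore_index=True)


class TestWithholdSplit:
    def test_rounding_rule(self):
        np.testing.assert_array_equal(
            round_half_away([95.6, 122.8, 61.2, 26.6, 49.6]),
            [96, 123, 61, 27, 50])

    def test_monthly_withheld_counts(self, rng):
        presences = reference.ANTIPODES_MONTHLY_PRESENCES
        table = _synthetic_table(rng, presences, 150)
        train, test = withhold_split(table, SplitSpec(seed=1))
        for m, n_p in presences.items():
            got = ((test["month"] == m) & (test["label"] == 1)).sum()
            assert got == reference.monthly_withheld(presences)[m]
            assert ((test["month"] == m) & (test["label"] == 0)).sum() == 100

    def test_conservation_and_determinism(self, rng):
        table = _synthetic_table(rng, {10: 101, 11: 57}, 120)
        train, test = withhold_split(table, SplitSpec(seed=5))
        for m in (10, 11):
            for lab in (0, 1):
                n_tr = ((train["month"] == m) & (train["label"] == lab)).sum()
                n_te = ((test["month"] == m) & (test["label"] == lab)).sum()
                n_in = ((table["month"] == m) & (table["label"] == lab)).sum()
                assert n_tr + n_te == n_in
        train2, test2 = withhold_split(table, SplitSpec(seed=5))
        pd.testing.assert_frame_equal(test, test2)

    def test_zero_fraction(self, rng):
        table = _synthetic_table(rng, {10: 50}, 120)
        _, test = withhold_split(table, SplitSpec(presence_withhold_fraction=0.0,
                                                  seed=0))
        assert (test["label"] == 1).sum() == 0
        assert (test["label"] == 0).sum() == 100

    def test_insufficient_background(self, rng):
        table = _synthetic_table(rng, {10: 50}, 80)
        with pytest.raises(ValueError, match="month 10"):
            withhold_split(table, SplitSpec(seed=0))


class TestCombinePopulations:
    def _table(self, rng, n, pop):
        return pd.DataFrame({"label": rng.integers(0, 2, n), "month": 11,
                             "weight": 1.0, "population": pop,
                             "lon": 0.0, "lat": -50.0})

    def test_equal_sizes_unit_weights(self, rng):
        out = combine_populations([self._table(rng, 100, "a"),
                                   self._table(rng, 100, "b")])
        assert (out["weight"] == 1.0).all()

    def test_row_balance_ratio(self, rng):
        out = combine_populations([self._table(rng, 200, "a"),
                                   self._table(rng, 100, "b")])
        assert out.loc[out["population"] == "a", "weight"].unique() == [0.5]
        assert out.loc[out["population"] == "b", "weight"].unique() == [1.0]

    def test_fixed_downweight(self, rng):
        out = combine_populations([self._table(rng, 200, "a"),
                                   self._table(rng, 100, "b")],
                                  balance="fixed:0.76")
        assert out.loc[out["population"] == "a", "weight"].unique() == [0.76]
        assert out.loc[out["population"] == "b", "weight"].unique() == [1.0]

    def test_errors(self, rng):
        t = self._table(rng, 10, "a")
        with pytest.raises(ValueError):
            combine_populations([t])
        with pytest.raises(ValueError):
            combine_populations([t, t.iloc[:0]])
        with pytest.raises(ValueError):
            combine_populations([t, self._table(rng, 10, "a")])
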