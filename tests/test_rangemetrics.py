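"""Centroids, geodesy, weighted KDE, isopleths, and the metric pipeline."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2

from rangeshift import rangemetrics as rm


class TestWeightedCentroid:
    def test_point_mass(self):
        assert rm.weighted_centroid([40.0], [-70.0], [5.0]) == (40.0, -70.0)

    def test_midpoint_equal_weights(self):
        lat, lon = rm.weighted_centroid([40.0, 42.0], [-70.0, -70.0], [1.0, 1.0])
        assert (lat, lon) == (41.0, -70.0)

    def test_weighted_mean(self):
        lat, lon = rm.weighted_centroid([40.0, 42.0], [-70.0, -70.0], [1.0, 3.0])
        assert lat == pytest.approx(41.5) and lon == -70.0

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            rm.weighted_centroid([40.0], [-70.0], [0.0])

    def test_brute_force_oracle(self, rng):
        lats = rng.uniform(35, 45, 200)
        lons = rng.uniform(-75, -65, 200)
        w = rng.gamma(1.0, 2.0, 200)
        lat, lon = rm.weighted_centroid(lats, lons, w)
        assert lat == pytest.approx(float(np.sum(lats * w) / np.sum(w)), abs=1e-12)
        assert lon == pytest.approx(float(np.sum(lons * w) / np.sum(w)), abs=1e-12)


class TestGeodesic:
    def test_zero_distance(self):
        assert rm.geodesic_km((40.0, -70.0), (40.0, -70.0)) == 0.0

    def test_one_degree_meridian(self):
        assert rm.geodesic_km((40.0, -70.0), (41.0, -70.0)) == pytest.approx(
            111.195, abs=0.001)

    def test_symmetry_random_pairs(self, rng):
        for _ in range(100):
            a = (rng.uniform(-80, 80), rng.uniform(-179, 179))
            b = (rng.uniform(-80, 80), rng.uniform(-179, 179))
            assert rm.geodesic_km(a, b) == pytest.approx(rm.geodesic_km(b, a), rel=1e-12)

    def test_law_of_cosines_oracle(self, rng):
        # independent spherical-law-of-cosines computation, > 1 km apart
        R = 6371.0088
        for _ in range(200):
            a = (rng.uniform(-60, 60), rng.uniform(-179, 179))
            b = (rng.uniform(-60, 60), rng.uniform(-179, 179))
            p1, p2 = np.radians(a[0]), np.radians(b[0])
            dl = np.radians(b[1] - a[1])
            d = R * np.arccos(np.clip(
                np.sin(p1) * np.sin(p2) + np.cos(p1) * np.cos(p2) * np.cos(dl), -1, 1))
            if d > 1.0:
                assert rm.geodesic_km(a, b) == pytest.approx(d, rel=1e-6)

    def test_invalid_latitude(self):
        with pytest.raises(ValueError):
            rm.geodesic_km((95.0, 0.0), (0.0, 0.0))


class TestWeightedKde:
    def test_mass_normalized(self, rng):
        s = rm.weighted_kde(rng.uniform(-71, -69, 300), rng.uniform(39, 41, 300),
                            rng.gamma(1, 2, 300))
        assert s.mass.sum() == pytest.approx(1.0, abs=1e-6)
        assert (s.mass >= 0).all()

    def test_point_mass_concentration(self):
        # all weight on one point, small fixed bandwidth: > 99% of mass within 3h
        lons = np.array([-70.0, -69.0])
        lats = np.array([40.0, 41.0])
        w = np.array([5.0, 0.0])
        s = rm.weighted_kde(lons, lats, w, rm.KdeOptions(bandwidth=(0.05, 0.05),
                                                         grid_size=150))
        near = (np.abs(s.lat_centers[:, None] - 40.0) < 0.15) & \
               (np.abs(s.lon_centers[None, :] + 70.0) < 0.15)
        assert s.mass[near].sum() > 0.99

    def test_weight_rescaling_invariance(self, rng):
        lons = rng.uniform(-71, -69, 200)
        lats = rng.uniform(39, 41, 200)
        w = rng.gamma(1, 2, 200)
        s1 = rm.weighted_kde(lons, lats, w)
        s2 = rm.weighted_kde(lons, lats, 2.0 * w)
        np.testing.assert_allclose(s1.mass, s2.mass, atol=1e-12)

    def test_degenerate_points_rejected(self):
        with pytest.raises(ValueError):
            rm.weighted_kde([-70.0] * 5, [40.0] * 5, [1.0] * 5)

    def test_bivariate_normal_isopleth_oracle(self):
        # 95% isopleth area of a standard bivariate normal: pi * chi2_2(0.95)
        rng = np.random.default_rng(42)
        xy = rng.standard_normal((5000, 2))
        s = rm.weighted_kde(xy[:, 0], xy[:, 1], np.ones(5000),
                            rm.KdeOptions(planar=True))
        _, area = rm.isopleth(s, 0.95)
        assert area == pytest.approx(np.pi * chi2.ppf(0.95, 2), rel=0.05)


class TestIsopleth:
    def uniform_surface(self):
        return rm.DensitySurface(
            lon_centers=np.arange(10.0), lat_centers=np.arange(10.0),
            mass=np.full((10, 10), 0.01), cell_area=np.ones((10, 10)),
            bandwidth=(1.0, 1.0))

    def test_uniform_100_cells_gives_95(self):
        mask, area = rm.isopleth(self.uniform_surface(), 0.95)
        assert mask.sum() == 95 and area == 95.0

    def test_all_mass_one_cell(self):
        m = np.zeros((5, 5))
        m[2, 3] = 1.0
        s = rm.DensitySurface(np.arange(5.0), np.arange(5.0), m,
                              np.full((5, 5), 2.0), (1.0, 1.0))
        mask, area = rm.isopleth(s, 0.95)
        assert mask.sum() == 1 and area == 2.0 and mask[2, 3]

    def test_monotone_in_level(self, rng):
        s = rm.weighted_kde(rng.uniform(-71, -69, 300), rng.uniform(39, 41, 300),
                            rng.gamma(1, 2, 300))
        _, a95 = rm.isopleth(s, 0.95)
        _, a99 = rm.isopleth(s, 0.99)
        assert a99 >= a95

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6), st.floats(0.5, 0.99))
    def test_nestedness_property(self, seed, level):
        r = np.random.default_rng(seed)
        s = rm.weighted_kde(r.uniform(-71, -69, 80), r.uniform(39, 41, 80),
                            r.gamma(1, 2, 80))
        small, _ = rm.isopleth(s, level * 0.9)
        big, _ = rm.isopleth(s, level)
        assert np.all(big[small])  # lower-level region nested in higher

    def test_bad_level(self):
        with pytest.raises(ValueError):
            rm.isopleth(self.uniform_surface(), 1.5)


class TestRangeExtent:
    def test_single_and_two_cells(self):
        s = rm.DensitySurface(np.arange(3.0), np.array([39.0, 41.5, 44.0]),
                              np.zeros((3, 3)), np.ones((3, 3)), (1, 1))
        mask = np.zeros((3, 3), bool)
        mask[1, 0] = True
        assert rm.range_extent(s, mask) == (41.5, 41.5)
        mask[0, 2] = True
        assert rm.range_extent(s, mask) == (39.0, 41.5)

    def test_empty_region_rejected(self):
        s = rm.DensitySurface(np.arange(3.0), np.arange(3.0), np.zeros((3, 3)),
                              np.ones((3, 3)), (1, 1))
        with pytest.raises(ValueError):
            rm.range_extent(s, np.zeros((3, 3), bool))


def _records(rng, lat_center, n=300, years=(1986, 1990), cpue_scale=3.0):
    y = rng.integers(years[0], years[1] + 1, n)
    return pd.DataFrame({
        "species": "sp", "season": "fall", "year": y,
        "lat": rng.normal(lat_center, 0.8, n),
        "lon": rng.normal(-70.0, 0.8, n),
        "cpue": rng.gamma(1.0, cpue_scale, n)})


class TestComputeRangeMetrics:
    def test_identical_pattern_both_periods(self):
        rng = np.random.default_rng(0)
        p1 = _records(rng, 40.0)
        p2 = p1.copy()
        p2["year"] = p2["year"] + 28  # same spatial pattern, later years
        m = rm.compute_range_metrics(pd.concat([p1, p2], ignore_index=True))
        assert m.shift_km == pytest.approx(0.0, abs=1e-9)
        assert m.pct_area_change == pytest.approx(0.0, abs=1e-9)
        assert m.d_north == 0.0 and m.d_south == 0.0

    def test_pct_area_change_formula(self):
        # period-2 cloud dispersed ~sqrt(1.5) wider: area2/area1 -> 1.5
        rng = np.random.default_rng(1)
        p1 = _records(rng, 40.0)
        p2 = _records(rng, 40.0, years=(2014, 2018))
        p2["lat"] = 40.0 + (p2["lat"] - 40.0) * np.sqrt(1.5)
        p2["lon"] = -70.0 + (p2["lon"] + 70.0) * np.sqrt(1.5)
        m = rm.compute_range_metrics(pd.concat([p1, p2], ignore_index=True))
        assert m.pct_area_change == pytest.approx(
            100.0 * (m.area2_km2 - m.area1_km2) / m.area1_km2)
        assert m.pct_area_change == pytest.approx(50.0, abs=12.0)

    def test_cpue_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        df = pd.concat([_records(rng, 40.0),
                        _records(rng, 40.6, years=(2014, 2018))], ignore_index=True)
        m1 = rm.compute_range_metrics(df)
        df2 = df.assign(cpue=df["cpue"] * 7.5)
        m2 = rm.compute_range_metrics(df2)
        assert m1.shift_km == pytest.approx(m2.shift_km, rel=1e-9)
        assert m1.area1_km2 == pytest.approx(m2.area1_km2, rel=1e-9)

    def test_empty_period_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            rm.compute_range_metrics(_records(rng, 40.0))  # no period-2 hauls

    def test_include_area_false_skips_kde(self):
        rng = np.random.default_rng(4)
        df = pd.concat([_records(rng, 40.0),
                        _records(rng, 40.6, years=(2014, 2018))], ignore_index=True)
        m = rm.compute_range_metrics(df, include_area=False)
        assert m.shift_km > 0 and m.area1_km2 is None and m.d_north is None

    def test_periods_validation(self):
        with pytest.raises(ValueError):
            rm.PeriodSpec(period1=(1986, 1990), period2=(1988, 1995))


class TestShiftedSpeciesEdges:
    def test_poleward_shift_moves_north_edge(self):
        # default-domain pelagic archetype with an imposed poleward drift
        from dataclasses import replace

        from rangeshift import simulate
        cfg = simulate.default_config(9)
        cfg = replace(cfg, species=(cfg.species[0],), seasons=("fall",))
        survey, truth = simulate.build_survey(cfg)
        m = rm.compute_range_metrics(survey)
        assert m.d_north > 0  # poleward truth shift raises the northern edge
        assert m.shift_km > 50.0
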