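"""Synthetic-survey generator: determinism, allocation, noise, imposed shifts."""
import numpy as np
import pandas as pd
import pytest

from rangeshift import simulate
from rangeshift._geo import KM_PER_DEG


class TestEnvironment:
    def test_zero_warming_gives_identical_fields(self, small_config, small_env):
        cfg = simulate.SimulationConfig(
            seed=small_config.seed, strata=small_config.strata,
            species=small_config.species, warming_rate=0.0, grid_resolution=0.2)
        env = simulate.generate_environment(cfg)
        np.testing.assert_array_equal(env.temperature(1986, "fall"),
                                      env.temperature(2018, "fall"))

    def test_linear_warming_trend(self, small_config):
        cfg = simulate.SimulationConfig(
            seed=5, strata=small_config.strata, species=small_config.species,
            warming_rate=0.05, grid_resolution=0.2)
        env = simulate.generate_environment(cfg)
        d = env.temperature(2018, "spring").mean() - env.temperature(1986, "spring").mean()
        assert d == pytest.approx(32 * 0.05, abs=1e-9)

    def test_seeded_determinism_bit_identical(self, small_config):
        e1 = simulate.generate_environment(small_config)
        e2 = simulate.generate_environment(small_config)
        np.testing.assert_array_equal(e1.grainsize, e2.grainsize)
        np.testing.assert_array_equal(e1.temperature(2000, "fall"),
                                      e2.temperature(2000, "fall"))
        assert e1.salin_anomaly == e2.salin_anomaly

    def test_colder_poleward_and_static_substrate(self, small_env):
        t = small_env.temperature(1990, "spring")
        rowmeans = t.mean(axis=1)
        assert np.all(np.diff(rowmeans) < 0)  # monotone colder with latitude
        assert np.all(small_env.grainsize > 0)
        assert np.all(small_env.depth > 0)

    def test_degenerate_grid_rejected(self, small_config):
        with pytest.raises(simulate.ConfigurationError):
            simulate.generate_environment(
                simulate.SimulationConfig(seed=1, strata=small_config.strata,
                                          species=small_config.species,
                                          grid_resolution=10.0))


class TestStations:
    def test_proportional_allocation(self):
        strata = (simulate.StratumSpec("A", (38, 40), (-72, -70), 80, 100.0),
                  simulate.StratumSpec("B", (40, 42), (-72, -70), 120, 300.0))
        cfg = simulate.SimulationConfig(seed=1, strata=strata,
                                        species=simulate.default_species(1),
                                        stations_per_unit_area=0.02)
        st = simulate.sample_stations(cfg, 1986, "spring")
        counts = st["stratum"].value_counts()
        assert counts["A"] == 2 and counts["B"] == 6

    def test_floor_of_one_station(self):
        strata = (simulate.StratumSpec("tiny", (38, 39), (-71, -70), 80, 1.0),)
        cfg = simulate.SimulationConfig(seed=1, strata=strata,
                                        species=simulate.default_species(1),
                                        stations_per_unit_area=1e-6)
        assert len(simulate.sample_stations(cfg, 1986, "fall")) == 1

    def test_containment_and_determinism(self, small_config):
        s1 = simulate.sample_stations(small_config, 1999, "fall")
        s2 = simulate.sample_stations(small_config, 1999, "fall")
        pd.testing.assert_frame_equal(s1, s2)
        for st in small_config.strata:
            sub = s1[s1["stratum"] == st.stratum_id]
            assert sub["lat"].between(*st.lat_range).all()
            assert sub["lon"].between(*st.lon_range).all()

    def test_allocation_ratio_matches_area_ratio(self):
        # Monte-Carlo reading of the proportional rule: station-count
        # ratio over many seeded draws stays within 1% of the area ratio
        strata = (simulate.StratumSpec("A", (38, 40), (-72, -70), 80, 137.0),
                  simulate.StratumSpec("B", (40, 42), (-72, -70), 120, 411.0))
        tot_a = tot_b = 0
        for seed in range(1000):
            cfg = simulate.SimulationConfig(
                seed=seed, strata=strata, species=simulate.default_species(1),
                stations_per_unit_area=0.05)
            counts = simulate.sample_stations(cfg, 1986, "spring")[
                "stratum"].value_counts()
            tot_a += counts["A"]
            tot_b += counts["B"]
        assert tot_b / tot_a == pytest.approx(411.0 / 137.0, rel=0.01)


class TestCpue:
    def test_flat_response_mean(self, small_config, small_env, rng):
        profile = simulate.SpeciesProfile(
            name="flat", life_history="demersal", niche={}, baseline_log_cpue=1.3)
        st = simulate.sample_stations(small_config, 1990, "fall")
        draws = np.concatenate([
            simulate.simulate_cpue(profile, st, small_env, 1990, "fall", 2.0,
                                   np.random.default_rng(k)) for k in range(300)])
        assert draws.mean() == pytest.approx(np.exp(1.3), rel=0.05)

    def test_negative_binomial_variance(self, rng):
        # Var = mu + mu^2/theta at fixed mean, checked at n = 1e5
        mu, theta, n = 6.0, 2.0, 100_000
        draws = rng.negative_binomial(theta, theta / (theta + mu), n)
        assert draws.var() == pytest.approx(mu + mu * mu / theta, rel=0.05)

    def test_poisson_limit_of_dispersion(self, small_config, small_env):
        # theta -> infinity: variance/mean ratio -> 1
        profile = simulate.SpeciesProfile(
            name="flat", life_history="pelagic", niche={}, baseline_log_cpue=1.5)
        st = simulate.sample_stations(small_config, 1990, "fall").iloc[:1]
        st = pd.concat([st] * 1000, ignore_index=True)
        rng = np.random.default_rng(7)
        draws = np.concatenate([
            simulate.simulate_cpue(profile, st, small_env, 1990, "fall", 1e6, rng)
            for _ in range(100)])
        assert draws.var() / draws.mean() == pytest.approx(1.0, rel=0.03)

    def test_station_outside_grid_rejected(self, small_config, small_env):
        profile = small_config.species[0]
        bad = pd.DataFrame({"lat": [10.0], "lon": [-70.0]})
        with pytest.raises(LookupError):
            simulate.simulate_cpue(profile, bad, small_env, 1990, "fall", 2.0,
                                   np.random.default_rng(0))


class TestShiftTruth:
    def test_anchored_species_expected_centroid_static(self, small_config, small_env):
        benthic = next(s for s in small_config.species if s.life_history == "benthic")
        c1 = simulate.expected_surface_centroid(benthic, small_env, 1986, "spring")
        c2 = simulate.expected_surface_centroid(benthic, small_env, 2018, "spring")
        assert c1 == c2

    def test_shifted_species_expected_centroid_rate(self):
        # expected-CPUE surface centroid moves at ~ the configured rate
        cfg = simulate.default_config(3)
        env = simulate.generate_environment(cfg)
        sp = next(s for s in cfg.species if s.life_history == "pelagic")
        c1 = simulate.expected_surface_centroid(sp, env, 1986, "spring")
        c2 = simulate.expected_surface_centroid(sp, env, 2018, "spring")
        expected_deg = 32 * sp.true_shift_km_per_decade / 10.0 / KM_PER_DEG
        assert (c2[0] - c1[0]) == pytest.approx(expected_deg, rel=0.12)

    def test_truth_table_shifts(self, small_survey):
        _, truth = small_survey
        per_species = truth.groupby("species")["true_shift_km"].first()
        assert per_species["benthic_1"] == 0.0
        # 70 km/decade over 2.8 decades between the 5-year period midpoints
        assert per_species["pelagic_1"] == pytest.approx(196.0)

    def test_row_count(self, small_config, small_survey):
        survey, _ = small_survey
        per_pass = sum(simulate.stratum_station_count(s, small_config.stations_per_unit_area)
                       for s in small_config.strata)
        expected = per_pass * small_config.n_years * 2 * len(small_config.species)
        assert len(survey) == expected

    def test_survey_bit_reproducible(self, small_config):
        s1, t1 = simulate.build_survey(small_config)
        s2, t2 = simulate.build_survey(small_config)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_schema_columns(self, small_survey):
        survey, _ = small_survey
        assert list(survey.columns) == simulate.SURVEY_COLUMNS
        assert (survey["cpue"] >= 0).all()


class TestConfigValidation:
    def test_bad_configs_rejected(self, small_config):
        with pytest.raises(simulate.ConfigurationError):
            simulate.SimulationConfig(seed=1, strata=(), species=())
        with pytest.raises(simulate.ConfigurationError):
            simulate.SimulationConfig(seed=1, strata=small_config.strata,
                                      species=small_config.species, n_years=1)
        with pytest.raises(simulate.ConfigurationError):
            simulate.SimulationConfig(seed=1, strata=small_config.strata,
                                      species=small_config.species, nb_dispersion=0.0)
        with pytest.raises(simulate.ConfigurationError):
            simulate.StratumSpec("X", (40, 40), (-72, -70), 80, 10.0)
        with pytest.raises(simulate.ConfigurationError):
            simulate.SpeciesProfile("x", "abyssal", {})
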