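import numpy as np
import pandas as pd
import pytest

from rangeshift import pipeline, simulate


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    """Miniature survey/substrate/metadata CSVs written once per session."""
    out = tmp_path_factory.mktemp("fixtures")
    return pipeline.make_fixtures(out, seed=0)


@pytest.fixture(scope="session")
def small_config():
    """Two-stratum, three-species scenario small enough for fast tests."""
    strata = (
        simulate.StratumSpec("A", (38.0, 40.0), (-72.0, -70.0), 80.0, 3.0e4),
        simulate.StratumSpec("B", (40.0, 42.0), (-72.0, -70.0), 120.0, 6.0e4),
    )
    species = simulate.default_species(1)
    return simulate.SimulationConfig(seed=11, strata=strata, species=species,
                                     grid_resolution=0.2)


@pytest.fixture(scope="session")
def small_env(small_config):
    return simulate.generate_environment(small_config)


@pytest.fixture(scope="session")
def small_survey(small_config, small_env):
    survey, truth = simulate.build_survey(small_config, small_env)
    return survey, truth


def toy_survey(rows):
    """Build a minimal survey table from (species, year, season, cpue) rows.

    Coordinates/stratum/environment are filled with constants; useful for
    filter-rule tests where only occupancy patterns matter.
    """
    recs = []
    for k, (species, year, season, cpue) in enumerate(rows):
        recs.append({
            "haul_id": f"H{k:04d}", "year": year, "season": season,
            "stratum": "S1", "lat": 40.0, "lon": -70.0, "depth": 100.0,
            "btemp": 10.0, "bsalin": 34.0, "grainsize": 0.5,
            "species": species, "cpue": cpue})
    return pd.DataFrame(recs)


def full_coverage_rows(species, years, seasons=("spring", "fall"),
                       cpue=1.0, filler_species="filler"):
    """Rows giving one haul per (year, season); `species` gets `cpue` there.

    A filler species with CPUE 0 keeps every (year, season) cell sampled
    even where the focal species is absent.
    """
    rows = []
    for y in years:
        for s in seasons:
            rows.append((filler_species, y, s, 0.0))
    rows.extend(species)
    return rows


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
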