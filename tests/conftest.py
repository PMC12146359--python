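"""Shared fixtures: parameter sets, census anchors and cached fits.

Real-data fits are session-scoped because the stage-2 optimizer is the
slowest piece of the pipeline; every test that needs a calibrated model
reuses the same deterministic fit (seed 0, 4 multistarts).
"""

from __future__ import annotations

import pytest

import violencedyn as vd


@pytest.fixture(scope="session")
def family_params() -> vd.ModelParams:
    """Published family-violence estimates (20/40 scenario)."""
    return vd.FAMILY_VIOLENCE_PARAMS


@pytest.fixture(scope="session")
def nonfamily_params() -> vd.ModelParams:
    return vd.NON_FAMILY_VIOLENCE_PARAMS


@pytest.fixture(scope="session")
def census_population() -> vd.PopulationTrajectory:
    """Census anchors for the national population (millions)."""
    return vd.PopulationTrajectory(
        anchors=((2010, 112.34), (2015, 119.53), (2020, 126.01))
    )


@pytest.fixture(scope="session")
def incidence() -> vd.IncidenceTable:
    return vd.load_incidence()


@pytest.fixture(scope="session")
def fit_config() -> vd.FitConfig:
    return vd.FitConfig(seed=0, multistart=4)


def _fit_type(incidence, census_population, fit_config, violence_type):
    series = vd.build_scenario(
        incidence, census_population, vd.ScenarioConfig(violence_type=violence_type)
    )
    agg = vd.fit_aggressor_logistic(series, fit_config)
    result = vd.fit_full_model(series, agg, fit_config)
    return result.with_holdout(vd.validate_holdout(result, series)), series


@pytest.fixture(scope="session")
def family_fit(incidence, census_population, fit_config):
    """Calibrated base model for family violence, with holdout metrics."""
    return _fit_type(incidence, census_population, fit_config, "family")


@pytest.fixture(scope="session")
def nonfamily_fit(incidence, census_population, fit_config):
    return _fit_type(incidence, census_population, fit_config, "non_family")


@pytest.fixture(scope="session")
def selfinflicted_fit(incidence, census_population, fit_config):
    return _fit_type(incidence, census_population, fit_config, "self_inflicted")


@pytest.fixture(scope="session")
def noiseless_world():
    """Synthetic noiseless dataset generated from the published estimates."""
    spec = vd.GeneratorSpec(noise="none", seed=11)
    table, pop, truth = vd.generate(spec)
    return spec, table, pop, truth


@pytest.fixture(scope="session")
def noiseless_fit(noiseless_world):
    """Two-stage refit of the noiseless synthetic world."""
    spec, table, pop, truth = noiseless_world
    series = vd.series_from_truth(table, truth)
    cfg = vd.FitConfig(seed=1, multistart=4)
    agg = vd.fit_aggressor_logistic(series, cfg)
    return vd.fit_full_model(series, agg, cfg), series
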