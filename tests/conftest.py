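import dataclasses

import pytest

from telecea.io import (
    fixture_path,
    load_cost_config,
    load_distances,
    load_fares,
    load_tariff,
    load_trial_unit_costs,
)
from telecea.synthetic import default_params, generate_trial


@pytest.fixture(scope="session")
def cost_config():
    return load_cost_config(fixture_path("table2_components"))


@pytest.fixture(scope="session")
def unit_costs():
    return load_trial_unit_costs(fixture_path("table5_inputs"))


@pytest.fixture(scope="session")
def distances():
    return load_distances(fixture_path("table5_inputs"))


@pytest.fixture(scope="session")
def tariff():
    return load_tariff(fixture_path("uk_tto_tariff"))


@pytest.fixture(scope="session")
def fares():
    return load_fares(fixture_path("fares"))


@pytest.fixture(scope="session")
def default_trial(tariff):
    """One full-size synthetic trial (seed 0): (patients, consultations)."""
    return generate_trial(default_params(seed=0), tariff)


@pytest.fixture(scope="session")
def small_trial(tariff):
    """A reduced trial (60 patients per arm, seed 7) for cheap tests."""
    params = default_params(seed=7)
    params = dataclasses.replace(
        params,
        standard=dataclasses.replace(params.standard, n_patients=60),
        telemedicine=dataclasses.replace(params.telemedicine, n_patients=60),
    )
    return generate_trial(params, tariff)


@pytest.fixture(scope="session")
def null_params():
    """Both arms share the standard arm's distributions: every contrast null."""
    params = default_params(seed=0)
    telemedicine = dataclasses.replace(params.standard, n_patients=150)
    standard = dataclasses.replace(params.standard, n_patients=150)
    return dataclasses.replace(params, standard=standard, telemedicine=telemedicine)
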