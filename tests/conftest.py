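import numpy as np
import pytest

from coweda import clothing
from coweda.conditions import Activity, Environment, PersonProfile
from coweda.params import ModelParameters

EXTREME_ITEMS = [
    "Gen III ECWCS lightweight cold weather undershirt",
    "Gen III ECWCS lightweight cold weather drawers",
    "Gen III ECWCS midweight cold weather shirt",
    "Gen III ECWCS midweight cold weather drawers",
    "Gen III ECWCS fleece cold weather jacket",
    "Gen III ECWCS extreme cold weather parka (freed hood)",
    "Gen III ECWCS extreme cold weather trouser",
]


@pytest.fixture(scope="session")
def profile() -> PersonProfile:
    return PersonProfile()


@pytest.fixture(scope="session")
def params(profile) -> ModelParameters:
    return ModelParameters.for_person(profile)


@pytest.fixture(scope="session")
def database() -> list:
    return clothing.load_default_database()


@pytest.fixture(scope="session")
def heavy_ensemble(database) -> clothing.Ensemble:
    return clothing.Ensemble.from_names(EXTREME_ITEMS, database, label="extreme")


@pytest.fixture(scope="session")
def basal_activity(params) -> Activity:
    return Activity(m_rate=params.basal_met_rate, allow_below_basal=True)


@pytest.fixture(scope="session")
def bare_thermoneutral(params) -> clothing.RegionalInsulation:
    return clothing.total_insulation(clothing.Ensemble(), params.thermoneutral)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260917)
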