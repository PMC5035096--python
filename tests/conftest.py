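"""Shared fixtures: the synthetic morphology, reference models, and one
session-wide screening run that several test modules interrogate."""

import numpy as np
import pytest

from is3screen.biophysics import RegionPassiveMap, load_channels
from is3screen.features import MEASUREMENT_NAMES
from is3screen.fixtures import (DEFAULT_TRUTH_DENSITIES, FixtureMorphologySpec,
                                GroundTruth, make_fixture_model,
                                make_fixture_morphology, make_reference)
from is3screen.morphology import compartmentalize
from is3screen.screening import (ParameterGrid, default_protocols,
                                 generate_database, run_cips)
from is3screen.simulator import SimulationConfig


@pytest.fixture(scope="session")
def passive_map():
    return RegionPassiveMap()


@pytest.fixture(scope="session")
def channels():
    return load_channels()


@pytest.fixture(scope="session")
def fixture_morph():
    return make_fixture_morphology()


@pytest.fixture(scope="session")
def comp_model(fixture_morph, passive_map):
    return compartmentalize(fixture_morph, "frequency", passive=passive_map)


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def protocols():
    return default_protocols()


@pytest.fixture(scope="session")
def s2_model():
    """Somatic-channel model at the ground-truth grid point."""
    return make_fixture_model(scenario="S.2", densities=DEFAULT_TRUTH_DENSITIES)


@pytest.fixture(scope="session")
def s2_traces(s2_model, protocols, sim_config):
    """The four CIP traces of the ground-truth model."""
    return run_cips(s2_model, protocols, sim_config)


@pytest.fixture(scope="session")
def s2_reference():
    """Reference measurements generated by the ground-truth model."""
    return make_reference(GroundTruth())


#: The screening grid used across tests: 27 somatic-channel models spanning
#: the published final ranges plus a high-persistent-Na level that produces
#: models spiking during the passive step (so elimination is exercised).
SCREEN_GRID = ParameterGrid.from_dict({
    "na_t": (0.2, 0.225, 0.25),
    "na_p": (0.0001, 0.001),
    "ka": (0.2,),
    "kdrf_faster": (0.95, 1.0, 1.05),
})
# 3 * 2 * 1 * 3 = 18 models; truth (0.225, 1e-4, 0.2, 1.0) is a member.


@pytest.fixture(scope="session")
def screen_db(comp_model, s2_reference, passive_map, sim_config):
    """One full screening run, with per-model features retained."""
    return generate_database(comp_model, "S.2", SCREEN_GRID, s2_reference,
                             passive=passive_map, config=sim_config,
                             keep_features=True)
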