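"""Shared fixtures: one deterministic synthetic world reused across the suite."""

import numpy as np
import pytest

from convergemap.synthdata import (ConnectomeSpec, SyntheticSpec,
                                   make_connectome_cohort, make_lesion_cohort,
                                   make_resection_scenarios, make_stim_sites)
from convergemap.connectome import build_fbc


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticSpec(seed=7)


@pytest.fixture(scope="session")
def lesion_cohort(default_spec):
    cohort, truth = make_lesion_cohort(default_spec.lesion,
                                       default_spec.streams()["lesion"])
    return cohort, truth


@pytest.fixture(scope="session")
def connectome_cohort(default_spec):
    sets, atlas, truth = make_connectome_cohort(default_spec.connectome,
                                                default_spec.streams()["connectome"])
    return sets, atlas, truth


@pytest.fixture(scope="session")
def fbc_cohort(connectome_cohort):
    sets, atlas, truth = connectome_cohort
    return [build_fbc(s, atlas) for s in sets], atlas, truth


@pytest.fixture(scope="session")
def resection_world(default_spec):
    scenarios, atlas, truth = make_resection_scenarios(
        default_spec.resection, default_spec.connectome,
        default_spec.streams()["resection"])
    return scenarios, atlas, truth


@pytest.fixture(scope="session")
def stim_world(default_spec):
    sites, truth = make_stim_sites(default_spec.stim, default_spec.streams()["stim"])
    return sites, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
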