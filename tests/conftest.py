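"""Shared session fixtures: the default montage, head model, grid and
lead field are expensive enough (seconds) to build once per session."""

import numpy as np
import pytest

from resit import (
    ConcentricSphereHeadModel,
    SimulationConfig,
    build_source_grid,
    compute_leadfield,
    make_montage_fixture,
    simulate_eeg,
)


@pytest.fixture(scope="session")
def montage62():
    return make_montage_fixture(62)


@pytest.fixture(scope="session")
def head_model():
    return ConcentricSphereHeadModel()


@pytest.fixture(scope="session")
def grid():
    return build_source_grid()


@pytest.fixture(scope="session")
def leadfield(head_model, montage62, grid):
    return compute_leadfield(head_model, montage62, grid)


@pytest.fixture(scope="session")
def sim_rec(head_model, montage62):
    """A standard noisy average-referenced simulated recording (seed 0)."""
    rec, truth = simulate_eeg(head_model, montage62, SimulationConfig(seed=0))
    return rec, truth


def rng_for_cell(seed: int, fraction_index: int, repeat: int) -> np.random.Generator:
    """The assessment module's per-cell RNG convention, restated here so
    tests can reproduce draws independently."""
    return np.random.default_rng(np.random.SeedSequence((seed, fraction_index, repeat)))
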