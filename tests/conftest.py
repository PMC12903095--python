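import numpy as np
import pandas as pd
import pytest

from smtpop import (
    AcquisitionParams,
    CellSpec,
    DiffusionGrid,
    MotionState,
    PopulationConfig,
    simulate_population,
    two_state_mixture,
)


@pytest.fixture(scope="session")
def acq() -> AcquisitionParams:
    return AcquisitionParams()


@pytest.fixture(scope="session")
def grid() -> DiffusionGrid:
    return DiffusionGrid.default()


@pytest.fixture(scope="session")
def small_dataset(acq):
    """12-cell two-state population around FB 0.4 used by several suites."""
    config = PopulationConfig(n_cells=12, n_trajectories=200, fb_mean=0.4)
    return simulate_population(config, acq, seed=20240)


@pytest.fixture
def single_state_spec():
    def make(D, n_trajectories=1000, radius=50.0, name="state"):
        return CellSpec(
            cell_id=0,
            states=[MotionState(name, D, 1.0)],
            n_trajectories=n_trajectories,
            nucleus_center=(radius, radius),
            nucleus_radius=radius,
        )

    return make
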