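import numpy as np
import pytest

from depscreen import (
    CellShellParams,
    CohortConfig,
    DielectricMedium,
    FrequencyGrid,
    default_arms,
    default_grid,
    default_medium,
)


@pytest.fixture
def medium() -> DielectricMedium:
    return default_medium()


@pytest.fixture
def grid() -> FrequencyGrid:
    return default_grid()


@pytest.fixture
def control_cell() -> CellShellParams:
    return default_arms()[1].mean


@pytest.fixture
def cancer_cell() -> CellShellParams:
    return default_arms()[0].mean


@pytest.fixture
def quiet_config() -> CohortConfig:
    """Noise- and artifact-free cohort configuration."""
    return CohortConfig(
        noise_sd=0.0,
        dead_point_probability=0.0,
        low_cell_probability=0.0,
        n_low_cell_cancer=0,
        seed=7,
    )
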