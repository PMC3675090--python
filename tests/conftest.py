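import numpy as np
import pytest

from cellstretch import (
    ModelParams,
    ReorientationPolicy,
    StretchProtocol,
    build_orientation_table,
    run_ensemble,
)


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def rho_params():
    return ModelParams.rho_inhibited()


@pytest.fixture(scope="session")
def protocol_10_1hz():
    return StretchProtocol(amplitude=0.10, frequency_hz=1.0)


@pytest.fixture(scope="session")
def protocol_10_02hz():
    return StretchProtocol(amplitude=0.10, frequency_hz=0.2)


@pytest.fixture(scope="session")
def static_protocol():
    return StretchProtocol(amplitude=0.0, frequency_hz=0.0)


@pytest.fixture(scope="session")
def policy():
    return ReorientationPolicy()


@pytest.fixture(scope="session")
def table_1hz(protocol_10_1hz, params, policy):
    """Per-orientation trial outcomes for the 10% / 1 Hz protocol."""
    return build_orientation_table(protocol_10_1hz, params, policy)


@pytest.fixture(scope="session")
def table_02hz(protocol_10_02hz, params, policy):
    return build_orientation_table(protocol_10_02hz, params, policy)


POPULATION_HORIZON = 150_000.0
ENSEMBLE_SEEDS = tuple(range(1, 11))


@pytest.fixture(scope="session")
def ensemble_1hz(protocol_10_1hz, params, policy, table_1hz):
    return run_ensemble(
        100, protocol_10_1hz, params, policy, POPULATION_HORIZON,
        seeds=ENSEMBLE_SEEDS, table=table_1hz,
    )


@pytest.fixture(scope="session")
def ensemble_02hz(protocol_10_02hz, params, policy, table_02hz):
    return run_ensemble(
        100, protocol_10_02hz, params, policy, POPULATION_HORIZON,
        seeds=ENSEMBLE_SEEDS, table=table_02hz,
    )
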