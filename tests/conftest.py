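import numpy as np
import pytest

from pericell import (
    ConsumptionParams,
    GasSchedule,
    MediaColumn,
    SolverOptions,
    TransportParams,
)


@pytest.fixture
def col24() -> MediaColumn:
    """24-well with 1 mL medium: L = 1/1.9 cm."""
    return MediaColumn.from_vessel("24-well", 1.0)


@pytest.fixture
def col6() -> MediaColumn:
    return MediaColumn.from_vessel("6-well", 2.0)


@pytest.fixture
def transport() -> TransportParams:
    return TransportParams()  # D = 0.09684 cm2/h, kL = 0.1 cm/h


@pytest.fixture
def monolayer() -> ConsumptionParams:
    """Sub-confluent adherent culture."""
    return ConsumptionParams(density=21000.0)


@pytest.fixture
def gas_1pct() -> GasSchedule:
    return GasSchedule.constant(1.0)


@pytest.fixture
def gas_5pct() -> GasSchedule:
    return GasSchedule.constant(5.0)


@pytest.fixture
def coarse() -> SolverOptions:
    """Reduced spatial resolution for fit-heavy tests."""
    return SolverOptions(n_x=32)
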