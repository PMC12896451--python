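import datetime as dt

import numpy as np
import pytest

from pigbout import (
    BehaviorClass,
    BoutCriteria,
    PresenceSeries,
    SimulationConfig,
)

DAY = dt.date(2024, 7, 15)


@pytest.fixture
def day() -> dt.date:
    return DAY


@pytest.fixture
def criteria() -> BoutCriteria:
    return BoutCriteria.default()


@pytest.fixture
def cfg() -> SimulationConfig:
    return SimulationConfig(seed=12345)


@pytest.fixture
def noise_free_cfg(cfg) -> SimulationConfig:
    return cfg.noise_free()


def make_series(
    seconds, class_label=BehaviorClass.AGGRESSIVE, date=DAY
) -> PresenceSeries:
    """Presence series with 1s at the given seconds (iterable or slice)."""
    presence = np.zeros(86400, dtype=np.uint8)
    presence[list(seconds)] = 1
    return PresenceSeries(date=date, class_label=class_label, presence=presence)


def embed(bits, class_label=BehaviorClass.AGGRESSIVE, date=DAY) -> PresenceSeries:
    """Embed a short binary vector at the start of an otherwise empty day."""
    presence = np.zeros(86400, dtype=np.uint8)
    presence[: len(bits)] = np.asarray(bits, dtype=np.uint8)
    return PresenceSeries(date=date, class_label=class_label, presence=presence)
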