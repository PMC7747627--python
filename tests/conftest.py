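from datetime import datetime

import numpy as np
import pytest

from heattent.controller import ControllerConfig, SensorReading
from heattent.microclimate import default_sim_config

NIGHT = datetime(2019, 5, 26, 22, 0)  # inside the active and stress windows


@pytest.fixture
def cfg():
    return ControllerConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sim_config():
    return default_sim_config(seed=1)


def make_readings(values, when=NIGHT):
    """Build an array of readings; None entries become failed reads."""
    out = []
    for i, v in enumerate(values):
        sid = f"s{i + 1}"
        out.append(
            SensorReading.failed(sid, when) if v is None else SensorReading.ok(sid, when, v)
        )
    return out
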