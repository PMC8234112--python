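from __future__ import annotations

from datetime import date, datetime, timedelta

import pytest

from dronetrack.rfid_io import TagRead
from dronetrack.synthetic import SimConfig

T0 = datetime(2017, 10, 20, 6, 0, 0)


def make_reads(sensors: str, tag: str = "T1", start: datetime = T0, step_s: int = 10) -> list[TagRead]:
    """Build unit-spaced reads from a sensor string like 'ABBAA'."""
    return [TagRead(tag, start + timedelta(seconds=i * step_s), s) for i, s in enumerate(sensors)]


@pytest.fixture
def reads_factory():
    return make_reads


@pytest.fixture
def small_config() -> SimConfig:
    """A light simulation: 40 drones over 10 days, noiseless channel."""
    return SimConfig(
        n_drones=40,
        start_date=date(2017, 10, 15),
        end_date=date(2017, 10, 25),
        p_never_detected=0.05,
        p_single_read=0.05,
        morning_active_fraction=0.2,
        both_period_fraction=0.15,
        seed=7,
    )
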