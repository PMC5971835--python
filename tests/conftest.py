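import numpy as np
import pytest

from zygochron import (
    Condition,
    Side,
    VertebraRecord,
    ZygantralRecord,
    load_boavus_table,
)


@pytest.fixture(scope="session")
def boavus_records():
    return load_boavus_table()


@pytest.fixture(scope="session")
def lot_2770(boavus_records):
    return [v for v in boavus_records if v.lot_id == "YPM VP 2770"]


@pytest.fixture(scope="session")
def lot_3752(boavus_records):
    return [v for v in boavus_records if v.lot_id == "YPM VP 3752"]


@pytest.fixture
def rng():
    return np.random.default_rng(20180525)


def make_vertebra(record_id="v1", lot_id="L", left=5, right=5,
                  left_condition=Condition.INTACT,
                  right_condition=Condition.INTACT,
                  centrum=None, left_positions=None, right_positions=None):
    """Hand-build a vertebra record for unit tests."""
    def zyg(side, count, cond, pos):
        if cond is not Condition.INTACT:
            return ZygantralRecord(side=side, line_count=count, condition=cond)
        return ZygantralRecord(side=side, line_count=count,
                               line_positions=pos, condition=cond)
    return VertebraRecord(
        record_id=record_id, lot_id=lot_id,
        centrum_length_mm=centrum,
        left=zyg(Side.LEFT, left, left_condition, left_positions),
        right=zyg(Side.RIGHT, right, right_condition, right_positions),
    )
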