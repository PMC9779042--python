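import numpy as np
import pytest

from zeitfly.metrics import ActivitySeries, LDSchedule
from zeitfly.tracking import ChamberGeometry


@pytest.fixture
def schedule() -> LDSchedule:
    return LDSchedule()


@pytest.fixture
def geometry() -> ChamberGeometry:
    return ChamberGeometry()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_series(values, t0: int = 1, valid=None) -> ActivitySeries:
    """ActivitySeries from raw values; t starts at t0 with unit step."""
    values = np.asarray(values, dtype=float)
    t = np.arange(t0, t0 + len(values))
    if valid is None:
        valid = np.ones(len(values), dtype=bool)
    return ActivitySeries(t, values, np.asarray(valid, dtype=bool))


def brute_force_sleep_seconds(quiescent) -> set[int]:
    """Independent oracle: every maximal all-quiescent run of length >= 300
    contributes its sample indices; pure-Python linear scan."""
    out: set[int] = set()
    run_start = None
    q = list(quiescent) + [False]
    for i, flag in enumerate(q):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            if i - run_start >= 300:
                out.update(range(run_start, i))
            run_start = None
    return out
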