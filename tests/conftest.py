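import datetime as dt

import numpy as np
import pytest

from occucam.data_io import DetectionRecord, StationOperationLog
from occucam.history import DetectionHistory


WINDOW_10 = (dt.date(2020, 1, 1), dt.date(2020, 1, 10))


def rec(station, species, ts, n=1):
    return DetectionRecord(station, species, dt.datetime.fromisoformat(ts), n)


@pytest.fixture
def small_log():
    """Two fully operational stations plus one that fails mid-survey."""
    return StationOperationLog(
        {
            "A": [(dt.date(2020, 1, 1), dt.date(2020, 1, 10))],
            "B": [(dt.date(2020, 1, 1), dt.date(2020, 1, 10))],
            "C": [(dt.date(2020, 1, 1), dt.date(2020, 1, 4))],
        }
    )


def make_history(matrix, occasion_length=1, window=WINDOW_10, site_ids=None):
    mat = np.asarray(matrix, dtype=float)
    if site_ids is None:
        site_ids = [f"S{i + 1}" for i in range(mat.shape[0])]
    return DetectionHistory(mat, list(site_ids), occasion_length, window)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
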