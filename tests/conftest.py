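import datetime as dt

import numpy as np
import pandas as pd
import pytest

from coroost.association import GroupByDay
from coroost.solar import TableSunProvider


@pytest.fixture
def flat_sun():
    """Sun provider with fixed 05:30 sunrise / 21:00 sunset over 2015-2020."""
    start = dt.date(2015, 1, 1)
    table = {}
    for k in range((dt.date(2021, 1, 1) - start).days):
        d = start + dt.timedelta(days=k)
        table[d] = (dt.time(5, 30), dt.time(21, 0))
    return TableSunProvider(table)


def make_events(rows):
    """Event frame from (tag, roost, iso-timestamp) triples."""
    return pd.DataFrame(
        {
            "tag_id": [r[0] for r in rows],
            "roost_id": [r[1] for r in rows],
            "timestamp": pd.to_datetime([r[2] for r in rows]),
        }
    )


def make_day_roosts(rows):
    """Day-roost frame from (tag, iso-date, roost) triples."""
    return pd.DataFrame(
        {
            "tag_id": [r[0] for r in rows],
            "date": [dt.date.fromisoformat(r[1]) for r in rows],
            "roost_id": [r[2] for r in rows],
            "basis": "pre_sunset",
        }
    )


def gbd_from_occupancy(occ, bats=None, roosts=None, start=dt.date(2016, 5, 1)):
    """GroupByDay from an int array (days x bats); -1 = unobserved."""
    occ = np.asarray(occ, dtype=np.int32)
    n_days, n_bats = occ.shape
    bats = bats or [f"B{i:02d}" for i in range(n_bats)]
    n_roosts = int(occ.max()) + 1 if occ.size and occ.max() >= 0 else 0
    roosts = roosts or [f"R{k}" for k in range(n_roosts)]
    dates = [start + dt.timedelta(days=k) for k in range(n_days)]
    return GroupByDay(dates=dates, bats=list(bats), roosts=list(roosts), occupancy=occ)


def random_symmetric(n, rng, low=0.0, high=1.0):
    """Random symmetric matrix with zero diagonal."""
    M = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    M[iu] = rng.uniform(low, high, size=len(iu[0]))
    return M + M.T
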