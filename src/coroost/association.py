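"""Group-by-day structures and Simple Ratio Index association networks.

Under the gambit of the group, all bats assigned to the same roost on the
same day are taken to be associating pairwise.  For a dyad (A, B) over the
window's dates the sampling outcomes are counted as

* ``x``    — dates both were assigned the same roost,
* ``y_AB`` — dates both were assigned, to different roosts,
* ``y_A``  — dates only A was assigned,
* ``y_B``  — dates only B was assigned,

and the Simple Ratio Index is ``SRI = x / (x + y_AB + y_A + y_B)`` — the
fraction of days at least one of the pair was observed on which they
co-roosted.  Dyads never jointly sampled (denominator zero) are set to 0
and flagged so matrix regressions stay complete while sensitivity re-runs
can exclude them.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from coroost.io_records import AnalysisWindow, filter_individuals

logger = logging.getLogger(__name__)

__all__ = [
    "GroupByDay",
    "AssociationMatrix",
    "build_group_by_day",
    "sri_matrix",
    "yearly_networks",
]


@dataclasses.dataclass
class GroupByDay:
    """Day-by-individual occupancy for one window (or the full record).

    ``occupancy[d, i]`` is the integer roost code of bat ``bats[i]`` on
    ``dates[d]``, or -1 if the bat was not assigned that day.  ``roosts``
    maps codes back to roost ids.
    """

    dates: list[dt.date]
    bats: list[str]
    roosts: list[str]
    occupancy: np.ndarray  # (n_dates, n_bats) int, -1 = unobserved

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=np.int32)
        if self.occupancy.shape != (len(self.dates), len(self.bats)):
            raise ValueError("occupancy shape mismatch")

    @property
    def n_bats(self) -> int:
        return len(self.bats)

    @property
    def observed(self) -> np.ndarray:
        return self.occupancy >= 0

    def groups_on(self, d: int) -> list[list[str]]:
        """Roosting groups (lists of tag ids) on date index ``d``."""
        row = self.occupancy[d]
        out = []
        for code in np.unique(row[row >= 0]):
            out.append([self.bats[i] for i in np.flatnonzero(row == code)])
        return out


@dataclasses.dataclass
class AssociationMatrix:
    """Symmetric individual-by-individual SRI matrix with dyadic counts."""

    bats: list[str]
    sri: np.ndarray
    x: np.ndarray
    y_ab: np.ndarray
    y_a: np.ndarray  # y_a[i, j]: dates i assigned, j not
    year: Optional[int] = None
    zero_denominator: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n = len(self.bats)
        if self.sri.shape != (n, n):
            raise ValueError("sri shape mismatch")
        if self.zero_denominator is None:
            self.zero_denominator = np.zeros((n, n), dtype=bool)

    @property
    def n_bats(self) -> int:
        return len(self.bats)

    def denominator(self) -> np.ndarray:
        return self.x + self.y_ab + self.y_a + self.y_a.T

    def subset(self, bats: Sequence[str]) -> "AssociationMatrix":
        """Restrict to ``bats`` in the given order."""
        pos = {b: i for i, b in enumerate(self.bats)}
        idx = np.array([pos[b] for b in bats], dtype=int)
        ix = np.ix_(idx, idx)
        return AssociationMatrix(
            bats=list(bats),
            sri=self.sri[ix].copy(),
            x=self.x[ix].copy(),
            y_ab=self.y_ab[ix].copy(),
            y_a=self.y_a[ix].copy(),
            year=self.year,
            zero_denominator=self.zero_denominator[ix].copy(),
        )

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format dyad table (upper triangle)."""
        n = self.n_bats
        iu, ju = np.triu_indices(n, k=1)
        return pd.DataFrame(
            {
                "bat_i": [self.bats[i] for i in iu],
                "bat_j": [self.bats[j] for j in ju],
                "sri": self.sri[iu, ju],
                "x": self.x[iu, ju],
                "yab": self.y_ab[iu, ju],
                "ya": self.y_a[iu, ju],
                "yb": self.y_a.T[iu, ju],
                "zero_denominator": self.zero_denominator[iu, ju],
                "year": self.year,
            }
        )

    def to_square_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.sri, index=self.bats, columns=self.bats)


def build_group_by_day(
    day_roosts: pd.DataFrame,
    window: Optional[AnalysisWindow] = None,
    *,
    bats: Optional[Sequence[str]] = None,
) -> GroupByDay:
    """Build the day-by-individual occupancy structure.

    ``day_roosts`` should already be restricted to qualifying individuals
    (see :func:`coroost.io_records.filter_individuals`).  With a window, the
    date index spans every date from start to cutoff (empty days retained);
    without one it spans the observed date range of the table.
    """
    dr = day_roosts
    if window is not None:
        dr = dr.loc[dr["date"].map(window.contains)]
        start, end = window.start_date, window.parturition_cutoff_date
    elif not dr.empty:
        start, end = min(dr["date"]), max(dr["date"])
    else:
        return GroupByDay([], list(bats or []), [], np.zeros((0, len(bats or [])), int))
    n_days = (end - start).days + 1
    dates = [start + dt.timedelta(days=k) for k in range(n_days)]
    bat_list = sorted(bats) if bats is not None else sorted(dr["tag_id"].unique())
    roost_list = sorted(dr["roost_id"].unique())
    bat_pos = {b: i for i, b in enumerate(bat_list)}
    roost_pos = {r: i for i, r in enumerate(roost_list)}
    date_pos = {d: i for i, d in enumerate(dates)}
    occ = np.full((n_days, len(bat_list)), -1, dtype=np.int32)
    for tag, date, roost in zip(dr["tag_id"], dr["date"], dr["roost_id"]):
        if tag in bat_pos:
            occ[date_pos[date], bat_pos[tag]] = roost_pos[roost]
    return GroupByDay(dates=dates, bats=bat_list, roosts=roost_list, occupancy=occ)


def sri_matrix(gbd: GroupByDay, year: Optional[int] = None) -> AssociationMatrix:
    """Simple Ratio Index matrix from a group-by-day structure.

    Vectorized over days; for each dyad the four sampling counts obey the
    conservation identity ``x + y_AB + y_A + y_B = #days at least one of
    the pair was observed``.
    """
    if gbd.n_bats < 2:
        raise ValueError("need at least 2 bats for an association matrix")
    occ = gbd.occupancy
    obs = occ >= 0
    # day-wise pairwise indicators, summed over days in manageable chunks
    n = gbd.n_bats
    x = np.zeros((n, n), dtype=np.int64)
    y_ab = np.zeros((n, n), dtype=np.int64)
    y_a = np.zeros((n, n), dtype=np.int64)
    chunk = max(1, int(4e6 // max(n * n, 1)))
    for lo in range(0, occ.shape[0], chunk):
        o = occ[lo : lo + chunk]
        b = obs[lo : lo + chunk]
        both = b[:, :, None] & b[:, None, :]
        same = (o[:, :, None] == o[:, None, :]) & both
        x += same.sum(axis=0)
        y_ab += (both & ~same).sum(axis=0)
        y_a += (b[:, :, None] & ~b[:, None, :]).sum(axis=0)
    np.fill_diagonal(x, 0)
    np.fill_diagonal(y_ab, 0)
    np.fill_diagonal(y_a, 0)
    den = x + y_ab + y_a + y_a.T
    zero = den == 0
    np.fill_diagonal(zero, False)
    with np.errstate(invalid="ignore", divide="ignore"):
        sri = np.where(den > 0, x / np.maximum(den, 1), 0.0)
    np.fill_diagonal(sri, 0.0)
    if zero.any():
        logger.info("%d dyads with zero joint sampling set to SRI 0", zero.sum() // 2)
    return AssociationMatrix(
        bats=list(gbd.bats),
        sri=sri,
        x=x,
        y_ab=y_ab,
        y_a=y_a,
        year=year,
        zero_denominator=zero,
    )


def yearly_networks(
    day_roosts: pd.DataFrame,
    roster: pd.DataFrame,
    windows: dict[int, AnalysisWindow],
) -> dict[int, AssociationMatrix]:
    """Per-year SRI networks over each year's qualifying adult females.

    Each year's matrix is built independently on that year's qualifying
    bats; cross-year alignment (shared-bat intersection) happens later, at
    comparison time.
    Years with fewer than two qualifying bats are omitted with a warning.
    """
    networks: dict[int, AssociationMatrix] = {}
    for year in sorted(windows):
        window = windows[year]
        dr = filter_individuals(day_roosts, roster, window)
        n_bats = dr["tag_id"].nunique()
        if n_bats < 2:
            logger.warning("year %d: only %d qualifying bats, skipped", year, n_bats)
            continue
        gbd = build_group_by_day(dr, window)
        networks[year] = sri_matrix(gbd, year=year)
    return networks
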