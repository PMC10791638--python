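"""Lagged association rates, the analytic null rate, and daily roost counts.

The lagged association rate (LAR) at lag tau is the probability that an
ordered pair (i, j) associated on day t is still associated on day t + tau,
estimated over all ordered pairs and day pairs:

    g(tau) = sum_t #{(i,j): A_ij(t) and A_ij(t+tau)}
             / sum_t #{(i,j): A_ij(t) and i observed at t+tau}

where A_ij(t) means i and j were assigned the same roost on day t.  Over a
multiyear record, fall-winter gaps simply appear as large lags.  The null
rate of association is the level g(tau) would decay to if bats re-associated
at random among their ever-associates: the average number of connections
per individual divided by (N - 1).
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from coroost.association import AssociationMatrix, GroupByDay

__all__ = [
    "LARCurve",
    "lagged_association_rate",
    "null_association_rate",
    "roosts_in_use_by_day",
    "default_lag_bins",
]


@dataclasses.dataclass
class LARCurve:
    """Binned lagged association rate.

    ``rate[b] = numerator[b] / denominator[b]``; bins with a zero
    denominator have NaN rate and are excluded from plots.
    """

    bin_left: np.ndarray  # inclusive, days
    bin_right: np.ndarray  # inclusive, days
    numerator: np.ndarray
    denominator: np.ndarray
    null_rate: Optional[float] = None

    @property
    def rate(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.denominator > 0, self.numerator / np.maximum(self.denominator, 1), np.nan
            )

    @property
    def lag_mid(self) -> np.ndarray:
        return (self.bin_left + self.bin_right) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag_left": self.bin_left,
                "lag_right": self.bin_right,
                "rate": self.rate,
                "num": self.numerator,
                "den": self.denominator,
            }
        )


def default_lag_bins(max_lag: int, daily_up_to: int = 90, n_log_bins: int = 12) -> np.ndarray:
    """Default lag bin edges: daily bins up to ``daily_up_to``, then
    log-spaced bins out to ``max_lag`` (multiyear lags are sparse)."""
    if max_lag <= daily_up_to:
        return np.arange(1, max_lag + 2)
    daily = np.arange(1, daily_up_to + 1)
    log_edges = np.unique(
        np.round(
            np.logspace(np.log10(daily_up_to + 1), np.log10(max_lag + 1), n_log_bins)
        ).astype(int)
    )
    return np.concatenate([daily, log_edges])


def lagged_association_rate(
    gbd: GroupByDay,
    max_lag: int,
    bin_edges: Optional[Sequence[int]] = None,
    *,
    condition_on_first: bool = False,
) -> LARCurve:
    """Whitehead-style lagged association rate over the full record.

    Parameters
    ----------
    gbd:
        Group-by-day structure, typically spanning all years (empty days,
        including whole fall-winter gaps, are simply days with no
        observations).
    max_lag:
        Largest lag (days) to evaluate.
    bin_edges:
        Ascending inclusive-left bin edges in days; lag tau falls in bin b
        when ``edges[b] <= tau < edges[b+1]``.  Defaults to
        :func:`default_lag_bins`.
    condition_on_first:
        If set, only day pairs (t, t+tau) where t is the dyad's *first*
        observed association day contribute, so the curve reads "does the
        association persist tau days after it first occurs".  The default
        is the standard all-pairs-of-days estimator.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if len(gbd.dates) == 0:
        raise ValueError("empty group-by-day")
    edges = (
        np.asarray(bin_edges, dtype=int)
        if bin_edges is not None
        else default_lag_bins(max_lag)
    )
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    n_bins = len(edges) - 1
    num = np.zeros(n_bins, dtype=np.int64)
    den = np.zeros(n_bins, dtype=np.int64)

    occ = gbd.occupancy
    obs = occ >= 0
    # restrict to days with >= 1 observation
    day_idx = np.flatnonzero(obs.any(axis=1))
    # same-roost indicator per active day (off-diagonal)
    assoc = {}
    for d in day_idx:
        row = occ[d]
        s = (row[:, None] == row[None, :]) & obs[d][:, None] & obs[d][None, :]
        np.fill_diagonal(s, False)
        assoc[d] = s

    first_assoc = None
    if condition_on_first:
        n = gbd.n_bats
        first_assoc = np.full((n, n), np.iinfo(np.int64).max, dtype=np.int64)
        for d in day_idx:
            mask = assoc[d] & (first_assoc > d)
            first_assoc[mask] = d

    for ai, t1 in enumerate(day_idx):
        for t2 in day_idx[ai + 1 :]:
            tau = t2 - t1
            if tau > max_lag:
                break
            b = np.searchsorted(edges, tau, side="right") - 1
            if b < 0 or b >= n_bins:
                continue
            a1 = assoc[t1]
            if condition_on_first:
                a1 = a1 & (first_assoc == t1)
            num[b] += int((a1 & assoc[t2]).sum())
            den[b] += int((a1 & obs[t2][:, None]).sum())
    return LARCurve(
        bin_left=edges[:-1].astype(float),
        bin_right=(edges[1:] - 1).astype(float),
        numerator=num,
        denominator=den,
    )


def null_association_rate(source: AssociationMatrix | GroupByDay) -> float:
    """Analytic null association level.

    Mean over individuals of (number of distinct associates ever co-roosted
    with) / (N - 1); the level the LAR is compared against.
    """
    if isinstance(source, GroupByDay):
        occ = source.occupancy
        obs = occ >= 0
        n = source.n_bats
        ever = np.zeros((n, n), dtype=bool)
        for d in range(occ.shape[0]):
            row = occ[d]
            s = (row[:, None] == row[None, :]) & obs[d][:, None] & obs[d][None, :]
            ever |= s
        np.fill_diagonal(ever, False)
    else:
        ever = source.x > 0
        n = source.n_bats
    if n < 2:
        raise ValueError("need at least 2 individuals")
    degree = ever.sum(axis=1)
    return float(np.mean(degree / (n - 1)))


def roosts_in_use_by_day(day_roosts: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count distinct roosts occupied per (year, date).

    Returns ``(per_day, by_doy)``: per-day counts with year and day-of-year
    columns, and the cross-year mean count per day-of-year.
    """
    if day_roosts.empty:
        empty = pd.DataFrame(columns=["year", "date", "day_of_year", "n_roosts"])
        return empty, pd.DataFrame(columns=["day_of_year", "mean_n_roosts"])
    per_day = (
        day_roosts.groupby("date")["roost_id"].nunique().rename("n_roosts").reset_index()
    )
    per_day["year"] = per_day["date"].map(lambda d: d.year)
    per_day["day_of_year"] = per_day["date"].map(lambda d: d.timetuple().tm_yday)
    per_day = per_day[["year", "date", "day_of_year", "n_roosts"]]
    by_doy = (
        per_day.groupby("day_of_year")["n_roosts"].mean().rename("mean_n_roosts").reset_index()
    )
    return per_day, by_doy
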