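"""Roost-use profiles and the co-occurrence probability control matrix.

An individual's roost-use profile is the fraction of its assigned days it
spent in each monitored roost.  If two bats chose roosts independently
according to their profiles, the probability they would land in the same
box on a day is

    P_ij = sum_k p_ik * p_jk

— the expected co-roosting rate under roost fidelity alone, with no social
attraction.  This matrix is the control predictor in the MRQAP: it captures
exactly the co-occurrence that individual roost preferences would produce
by themselves.  Days on which a bat was not detected are ignored
(missingness treated as random), so profiles are over assigned days only.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from coroost.association import AssociationMatrix
from coroost.io_records import AnalysisWindow

logger = logging.getLogger(__name__)

__all__ = ["roost_use_profiles", "cooccurrence_probability", "CooccurrenceMatrix"]


class CooccurrenceMatrix:
    """Symmetric bat-by-bat matrix of no-social co-roosting probabilities."""

    def __init__(self, bats: Sequence[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(bats), len(bats)):
            raise ValueError("shape mismatch")
        self.bats = list(bats)
        self.values = values

    @property
    def n_bats(self) -> int:
        return len(self.bats)

    def subset(self, bats: Sequence[str]) -> "CooccurrenceMatrix":
        pos = {b: i for i, b in enumerate(self.bats)}
        idx = np.array([pos[b] for b in bats], dtype=int)
        return CooccurrenceMatrix(list(bats), self.values[np.ix_(idx, idx)].copy())

    def to_square_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.bats, columns=self.bats)


def roost_use_profiles(
    day_roosts: pd.DataFrame,
    window: Optional[AnalysisWindow] = None,
) -> pd.DataFrame:
    """Per-bat roost-use proportions over the window's monitored roosts.

    Returns a DataFrame indexed by tag_id with one column per roost; rows
    sum to 1 over each bat's assigned days.  Roosts unmonitored in the
    window (``window.monitored_roosts``) are dropped before normalization;
    bats with no assigned days on the remaining roosts are excluded with a
    warning.
    """
    dr = day_roosts
    if window is not None:
        dr = dr.loc[dr["date"].map(window.contains)]
        if window.monitored_roosts is not None:
            dr = dr.loc[dr["roost_id"].isin(window.monitored_roosts)]
    if dr.empty:
        raise ValueError("no assigned days in window")
    counts = dr.groupby(["tag_id", "roost_id"]).size().unstack(fill_value=0)
    if window is not None and window.monitored_roosts is not None:
        for r in sorted(window.monitored_roosts):
            if r not in counts.columns:
                counts[r] = 0
        counts = counts[sorted(counts.columns)]
    totals = counts.sum(axis=1)
    zero = totals == 0
    if zero.any():
        logger.warning("excluding %d bats with no assigned days", int(zero.sum()))
        counts = counts.loc[~zero]
        totals = totals.loc[~zero]
    profiles = counts.div(totals, axis=0)
    profiles.index = profiles.index.astype(str)
    return profiles.sort_index()


def cooccurrence_probability(profiles: pd.DataFrame) -> CooccurrenceMatrix:
    """Co-occurrence probability matrix ``P_ij = sum_k p_ik p_jk``.

    ``profiles`` must share one roost index (columns); each row must sum
    to 1.  The diagonal is zeroed (self-overlap carries no dyadic
    information and is excluded from all downstream statistics).
    """
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 profiles")
    p = profiles.to_numpy(dtype=float)
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("profiles must each sum to 1 over a common roost index")
    values = p @ p.T
    np.fill_diagonal(values, 0.0)
    return CooccurrenceMatrix(list(profiles.index), values)
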