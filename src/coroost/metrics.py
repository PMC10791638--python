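"""Node-level network metrics, age regressions, and the cohort comparison.

Networks are built from all qualifying individuals (known- and unknown-age
alike); metrics are then read off for known-aged bats only, so an
individual's position reflects the real topology, never a filtered one.

* degree — number of associates with SRI > 0;
* betweenness centrality — how often a bat sits on shortest paths between
  other bats (binary graph on SRI > 0 edges by default; a weighted variant
  uses edge length 1/SRI);
* CV SRI — sd/mean of a bat's dyadic SRI values; high values mean
  selective association.

The cohort comparison asks whether bats associate more strongly with bats
born the same year: per bat and year, mean SRI to same-cohort vs
different-cohort known-aged bats, averaged across years per bat (so bats
present in more years carry no extra weight), then a paired t-test.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from coroost.association import AssociationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "node_degree",
    "betweenness_centrality",
    "cv_sri",
    "node_metric_table",
    "age_metric_regression",
    "cohort_paired_test",
    "CohortComparison",
    "RegressionResult",
]


def _bat_index(A: AssociationMatrix, bat: str) -> int:
    try:
        return A.bats.index(bat)
    except ValueError:
        raise KeyError(f"bat {bat!r} not in matrix index") from None


def node_degree(A: AssociationMatrix, bat: str) -> int:
    """Number of other bats with a nonzero SRI to ``bat``."""
    i = _bat_index(A, bat)
    row = A.sri[i].copy()
    row[i] = 0.0
    return int(np.count_nonzero(row > 0))


def _graph(A: AssociationMatrix, weighted: bool) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(A.bats)
    n = A.n_bats
    iu, ju = np.triu_indices(n, k=1)
    for i, j in zip(iu, ju):
        w = A.sri[i, j]
        if w > 0:
            G.add_edge(A.bats[i], A.bats[j], sri=w, length=1.0 / w)
    return G


def betweenness_centrality(
    A: AssociationMatrix, mode: str = "binary"
) -> dict[str, float]:
    """Betweenness centrality for every bat.

    ``binary`` (default): shortest paths on the unweighted graph of
    SRI > 0 edges.  ``weighted``: shortest paths under edge length 1/SRI,
    so strong associations are short.  Unnormalized counts with fractional
    credit for tied shortest paths; disconnected graphs are fine.
    """
    if A.n_bats < 3:
        raise ValueError("need at least 3 bats")
    G = _graph(A, weighted=mode == "weighted")
    if mode == "binary":
        bc = nx.betweenness_centrality(G, normalized=False)
    elif mode == "weighted":
        bc = nx.betweenness_centrality(G, normalized=False, weight="length")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return {b: float(v) for b, v in bc.items()}


def cv_sri(
    A: AssociationMatrix, bat: str, *, include_zeros: bool = True
) -> float:
    """Coefficient of variation (sample sd / mean) of a bat's dyadic SRIs.

    Zero-SRI dyads are included by default; with a mean of 0 the CV is
    undefined and NaN is returned.
    """
    if A.n_bats < 2:
        raise ValueError("need at least 2 bats")
    i = _bat_index(A, bat)
    vals = np.delete(A.sri[i], i)
    if not include_zeros:
        vals = vals[vals > 0]
    if len(vals) == 0 or vals.mean() == 0:
        logger.warning("cv_sri undefined for %s (mean SRI 0)", bat)
        return float("nan")
    if len(vals) < 2:
        return float("nan")
    return float(vals.std(ddof=1) / vals.mean())


def node_metric_table(
    networks: Mapping[int, AssociationMatrix],
    roster: pd.DataFrame,
    *,
    betweenness_mode: str = "binary",
    cv_include_zeros: bool = True,
    known_age_only: bool = True,
) -> pd.DataFrame:
    """Per-(bat, year) metric rows.

    Metrics are computed on each year's full network; rows are emitted for
    known-aged bats (those with a cohort year) unless ``known_age_only``
    is off.  ``exact_age = year - cohort_year``.
    """
    cohort = roster.set_index("tag_id")["cohort_year"]
    rows = []
    for year in sorted(networks):
        A = networks[year]
        if A.n_bats < 3:
            continue
        bc = betweenness_centrality(A, mode=betweenness_mode)
        for bat in A.bats:
            cy = cohort.get(bat, np.nan)
            if known_age_only and pd.isna(cy):
                continue
            age = int(year - cy) if pd.notna(cy) else None
            if age is not None and age < 0:
                raise ValueError(f"bat {bat}: cohort year {cy} after network year {year}")
            rows.append(
                {
                    "tag_id": bat,
                    "year": year,
                    "exact_age": age,
                    "degree": node_degree(A, bat),
                    "betweenness": bc[bat],
                    "cv_sri": cv_sri(A, bat, include_zeros=cv_include_zeros),
                }
            )
    return pd.DataFrame(
        rows, columns=["tag_id", "year", "exact_age", "degree", "betweenness", "cv_sri"]
    )


@dataclasses.dataclass
class RegressionResult:
    metric: str
    slope: float
    intercept: float
    p_value: float
    r_value: float
    n: int
    n_per_age: dict[int, int]


def age_metric_regression(rows: pd.DataFrame, metric: str) -> RegressionResult:
    """Simple linear regression of a node metric on exact age.

    Pooled over bat-years (an individual present at several ages
    contributes one row per age).  Per-age sample counts are reported for
    plot labelling.
    """
    if metric not in rows.columns:
        raise KeyError(metric)
    sub = rows.dropna(subset=["exact_age", metric])
    if len(sub) < 3:
        raise ValueError("need at least 3 rows with known age")
    ages = sub["exact_age"].astype(float)
    if ages.nunique() < 2:
        raise ValueError("zero variance in age")
    fit = stats.linregress(ages, sub[metric].astype(float))
    n_per_age = sub.groupby("exact_age").size().to_dict()
    return RegressionResult(
        metric=metric,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
        r_value=float(fit.rvalue),
        n=len(sub),
        n_per_age={int(k): int(v) for k, v in n_per_age.items()},
    )


@dataclasses.dataclass
class CohortComparison:
    t_statistic: float
    df: int
    p_value: float
    per_bat: pd.DataFrame  # tag_id, mean_within, mean_among, n_years
    start_year: int


def cohort_paired_test(
    networks: Mapping[int, AssociationMatrix],
    roster: pd.DataFrame,
    *,
    min_known_aged: int = 2,
) -> CohortComparison:
    """Within- vs among-cohort association strengths, paired by bat.

    For each known-aged bat and year: mean SRI to same-cohort known-aged
    bats in that year's network, and mean SRI to different-cohort
    known-aged bats (cohort membership is unknowable for unknown-age
    associates, so the among-cohort mean is restricted to known-aged
    bats).  Each bat's yearly means are averaged across years before the
    paired t-test, so bats present in more years or with more associates
    carry no extra weight.  The analysis starts in the first year whose
    network holds at least ``min_known_aged`` known-aged bats.
    """
    cohort = roster.set_index("tag_id")["cohort_year"]
    start_year = None
    for year in sorted(networks):
        known = [b for b in networks[year].bats if pd.notna(cohort.get(b, np.nan))]
        if len(known) >= min_known_aged:
            start_year = year
            break
    if start_year is None:
        raise ValueError(
            f"no year has >= {min_known_aged} known-aged bats in its network"
        )
    within: dict[str, list[float]] = {}
    among: dict[str, list[float]] = {}
    for year in sorted(networks):
        if year < start_year:
            continue
        A = networks[year]
        known = [b for b in A.bats if pd.notna(cohort.get(b, np.nan))]
        if len(known) < 2:
            continue
        pos = {b: A.bats.index(b) for b in known}
        for bat in known:
            same = [
                pos[o]
                for o in known
                if o != bat and cohort[o] == cohort[bat]
            ]
            diff = [
                pos[o]
                for o in known
                if o != bat and cohort[o] != cohort[bat]
            ]
            if not same or not diff:
                continue
            i = pos[bat]
            within.setdefault(bat, []).append(float(A.sri[i, same].mean()))
            among.setdefault(bat, []).append(float(A.sri[i, diff].mean()))
    bats = sorted(set(within) & set(among))
    if len(bats) < 2:
        raise ValueError(
            "fewer than 2 bats have both within- and among-cohort means; "
            "the paired test needs bats with same-cohort partners in at "
            "least one year"
        )
    w = np.array([np.mean(within[b]) for b in bats])
    a = np.array([np.mean(among[b]) for b in bats])
    if np.allclose(w, a):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(w, a)
    per_bat = pd.DataFrame(
        {
            "tag_id": bats,
            "mean_within": w,
            "mean_among": a,
            "n_years": [len(within[b]) for b in bats],
        }
    )
    return CohortComparison(
        t_statistic=float(t),
        df=len(bats) - 1,
        p_value=float(p),
        per_bat=per_bat,
        start_year=start_year,
    )
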