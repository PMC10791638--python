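"""Agent-based synthetic maternity colony with known ground truth.

Generates multiyear roost-choice and PIT-tag detection data whose
statistical structure matches what the analysis assumes: a few dozen to a
couple of hundred adult females choosing among 8–11 roost boxes daily, with
each day's choice driven by a mixture of *individual roost preference*
(fidelity) and *persistent dyadic affinity* (social attraction), multiyear
attendance with annual loss and juvenile recruitment, missed detections,
and optionally fewer roosts open early in the season.

Daily group formation is leader–follower sequential placement: bats are
placed in random order; each bat either follows an already-placed partner
(chosen with probability proportional to its affinity to them, the whole
option weighted by ``w_social``) or samples a roost from its own
availability-restricted preference vector (weighted by ``w_fidelity``).
This is O(N·K) per day and plants a social signal orthogonal to the
preference structure, which is exactly the confound the matrix regressions
must separate.

With ``w_social = 0`` the expected dyadic co-roosting probability is
analytically ``P_ij = sum_k p_ik p_jk`` — the roost-fidelity control matrix
— which is the bridge that makes the control testable.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from coroost.io_records import AnalysisWindow
from coroost.solar import SolarSunProvider, SunProvider

__all__ = [
    "ColonyConfig",
    "GroundTruth",
    "SimulatedColony",
    "draw_population",
    "simulate_day",
    "advance_year",
    "emit_detections",
    "simulate_colony",
]


@dataclasses.dataclass
class ColonyConfig:
    """Study conditions for the synthetic colony.

    Defaults emulate the monitored system: ~60 adult females per year, 10
    roost boxes, an 80-day pregnancy window starting 28 April, detection
    probability 0.7 per bat-day, persistent affinity (``affinity_persistence
    = 1``), 20% annual loss with 12 juvenile recruits per year, and a 3.1%
    chance that a bat's morning entry roost differs from its final day
    roost (reproducing ~96.9% sunset/sunrise assignment agreement).
    """

    n_bats: int = 60
    n_roosts: int = 10
    n_years: int = 4
    days_per_season: int = 80
    start_year: int = 2015
    w_social: float = 0.5
    w_fidelity: float = 1.0
    affinity_persistence: float = 1.0  # rho: fraction of affinity carried between years
    pref_concentration: float = 0.5  # Dirichlet concentration of roost preferences
    p_detect: float = 0.7
    p_sunrise_detect: float = 0.9
    p_day_switch: float = 0.031  # morning roost differs from final day roost
    p_annual_loss: float = 0.2
    n_annual_recruits: int = 12
    affinity_partners: float = 3.0  # expected preferred associates per bat
    founder_known_age_fraction: float = 0.3
    cohort_assortativity: float = 1.0  # multiplier on within-cohort affinity
    roost_availability: Optional[dict[int, list[int]]] = None  # year index -> roost codes
    early_season_roost_ramp: Optional[tuple[int, int]] = None  # (n_open_at_start, ramp_days)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_roosts < 2:
            raise ValueError("n_roosts must be >= 2")
        for name in ("p_detect", "p_sunrise_detect", "p_day_switch", "p_annual_loss"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.p_detect:
            raise ValueError("p_detect must be positive")
        if not 0.0 <= self.affinity_persistence <= 1.0:
            raise ValueError("affinity_persistence must be in [0, 1]")
        if self.w_social < 0 or self.w_fidelity < 0:
            raise ValueError("weights must be nonnegative")

    def season_start(self, year_index: int) -> dt.date:
        return dt.date(self.start_year + year_index, 4, 28)

    def windows(self) -> dict[int, AnalysisWindow]:
        """Analysis windows matching the simulated seasons."""
        out = {}
        for y in range(self.n_years):
            start = self.season_start(y)
            out[start.year] = AnalysisWindow(
                year=start.year,
                start_date=start,
                parturition_cutoff_date=start + dt.timedelta(days=self.days_per_season - 1),
            )
        return out


@dataclasses.dataclass
class GroundTruth:
    """Latent state of the simulated colony.

    ``affinity[y]`` is the symmetric nonnegative dyadic affinity matrix over
    all bats ever created (rows/cols of absent bats are present but unused
    that year); ``preferences`` holds each bat's roost-preference vector;
    ``occupancy`` is the complete (tag_id, date, roost_id) record of where
    every present bat actually spent each day.
    """

    tag_ids: list[str]
    cohort_year: list[Optional[int]]  # None = unknown-age founder
    capture_year: list[int]
    preferences: np.ndarray  # (n_total, n_roosts)
    affinity: dict[int, np.ndarray]  # year index -> (n_total, n_total)
    present: dict[int, np.ndarray]  # year index -> bool mask over tag_ids
    occupancy: pd.DataFrame  # tag_id, date, roost_id (complete)

    def roost_ids(self, n_roosts: int) -> list[str]:
        return [f"R{k + 1:02d}" for k in range(n_roosts)]

    def roster(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tag_id": self.tag_ids,
                "sex": "F",
                "age_class_at_capture": [
                    "adult" if c is None else "juvenile" for c in self.cohort_year
                ],
                "capture_year": self.capture_year,
                "cohort_year": [
                    np.nan if c is None else c for c in self.cohort_year
                ],
            }
        )


def _symmetric_affinity(
    n_total: int,
    rng: np.random.Generator,
    cohorts: list[Optional[int]],
    assortativity: float,
    partners: float,
) -> np.ndarray:
    """Fresh symmetric nonnegative affinity, zero diagonal.

    Sparse "preferred associate" structure: each dyad carries positive
    affinity with probability ``partners / (n - 1)`` (so a bat has about
    ``partners`` preferred associates), with exponential strengths whose
    mean keeps each bat's total affinity O(1) — the follow-vs-prefer odds
    then stay stable as colony size varies, and the social signal is
    concentrated on specific dyads rather than diffused over all of them.
    Cohort assortativity multiplies the bond-formation rate for
    within-cohort dyads (both cohorts known and equal), so their expected
    affinity is ``assortativity`` times the baseline — familiarity makes
    preferred associations more likely, not individually stronger.
    """
    A = np.zeros((n_total, n_total))
    iu, ju = np.triu_indices(n_total, k=1)
    q = min(partners / max(n_total - 1, 1), 1.0)
    q_dyad = np.full(len(iu), q)
    if assortativity != 1.0:
        coh = np.array([np.nan if c is None else c for c in cohorts], dtype=float)
        same = np.isfinite(coh[iu]) & np.isfinite(coh[ju]) & (coh[iu] == coh[ju])
        q_dyad = np.where(same, np.minimum(q * assortativity, 1.0), q_dyad)
    active = rng.random(len(iu)) < q_dyad
    vals = active * rng.exponential(1.0 / max(partners, 1e-12), size=len(iu))
    A[iu, ju] = vals
    A = A + A.T
    return A


def draw_population(config: ColonyConfig, rng: np.random.Generator) -> GroundTruth:
    """Founding population: preferences, year-0 affinity, cohorts.

    A fraction of founders carry known birth cohorts (tagged as juveniles
    in pre-study years, 1–5 years before the first season), so several
    bats share birth years from the outset; the rest are unknown-age
    adults.
    """
    n = config.n_bats
    tag_ids = [f"B{i + 1:04d}" for i in range(n)]
    known = rng.random(n) < config.founder_known_age_fraction
    ages = rng.integers(1, 6, size=n)
    cohort_year: list[Optional[int]] = [
        int(config.start_year - ages[i]) if known[i] else None for i in range(n)
    ]
    capture_year = [
        int(config.start_year - ages[i]) if known[i] else config.start_year
        for i in range(n)
    ]
    preferences = rng.dirichlet(
        np.full(config.n_roosts, config.pref_concentration), size=n
    )
    affinity0 = _symmetric_affinity(
        n, rng, cohort_year, config.cohort_assortativity, config.affinity_partners
    )
    present0 = np.ones(n, dtype=bool)
    return GroundTruth(
        tag_ids=tag_ids,
        cohort_year=cohort_year,
        capture_year=capture_year,
        preferences=preferences,
        affinity={0: affinity0},
        present={0: present0},
        occupancy=pd.DataFrame(columns=["tag_id", "date", "roost_id"]),
    )


def simulate_day(
    present_idx: np.ndarray,
    affinity: np.ndarray,
    preferences: np.ndarray,
    available: np.ndarray,
    w_social: float,
    w_fidelity: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One day of leader–follower roost choice.

    Returns the chosen roost code for each bat in ``present_idx`` order.
    Bats are placed in random order; each either follows an already-placed
    partner j (option weight ``w_social * affinity_ij`` summed over placed
    partners, partner drawn proportional to affinity) or samples from its
    own availability-renormalized preference vector (weight
    ``w_fidelity``).
    """
    available = np.asarray(available, dtype=int)
    if len(available) == 0:
        raise ValueError("no available roosts")
    k = len(present_idx)
    pref = preferences[np.asarray(present_idx, dtype=int)][:, available]
    row_sums = pref.sum(axis=1, keepdims=True)
    uniform = np.full(len(available), 1.0 / len(available))
    pref = np.where(row_sums > 0, pref / np.maximum(row_sums, 1e-300), uniform)
    cum_pref = np.cumsum(pref, axis=1)
    A = affinity[np.ix_(present_idx, present_idx)]

    order = rng.permutation(k)
    choice = np.empty(k, dtype=int)  # local roost index per bat (present order)
    u_follow = rng.random(k)
    u_partner = rng.random(k)
    u_roost = rng.random(k)
    for t in range(k):
        b = order[t]
        placed = order[:t]
        if t > 0 and w_social > 0:
            a = A[b, placed]
            s = a.sum()
            w_s = w_social * s
            if w_s > 0 and u_follow[t] < w_s / (w_s + w_fidelity):
                ca = np.cumsum(a)
                j = int(np.searchsorted(ca, u_partner[t] * s, side="right"))
                j = min(j, t - 1)
                choice[b] = choice[placed[j]]
                continue
        r = int(np.searchsorted(cum_pref[b], u_roost[t], side="right"))
        choice[b] = min(r, len(available) - 1)
    return available[choice]


def advance_year(
    truth: GroundTruth, config: ColonyConfig, year_index: int, rng: np.random.Generator
) -> None:
    """Membership turnover and affinity update into ``year_index``.

    Survivors keep a mixed affinity ``rho * A_prev + (1 - rho) * fresh``
    (fresh on the same marginal scale); recruits enter as juveniles with
    new preferences and fresh affinities, cohort year = entry year.
    """
    prev = year_index - 1
    survivors = truth.present[prev] & (
        rng.random(len(truth.tag_ids)) >= config.p_annual_loss
    )
    n_old = len(truth.tag_ids)
    n_new = config.n_annual_recruits
    entry_year = config.start_year + year_index
    for j in range(n_new):
        truth.tag_ids.append(f"B{n_old + j + 1:04d}")
        truth.cohort_year.append(entry_year)
        truth.capture_year.append(entry_year)
    if n_new:
        new_prefs = rng.dirichlet(
            np.full(config.n_roosts, config.pref_concentration), size=n_new
        )
        truth.preferences = np.vstack([truth.preferences, new_prefs])
    n_total = n_old + n_new
    fresh = _symmetric_affinity(
        n_total,
        rng,
        truth.cohort_year,
        config.cohort_assortativity,
        config.affinity_partners,
    )
    A = fresh.copy()
    rho = config.affinity_persistence
    A[:n_old, :n_old] = rho * truth.affinity[prev] + (1.0 - rho) * fresh[:n_old, :n_old]
    truth.affinity[year_index] = A
    present = np.zeros(n_total, dtype=bool)
    present[: len(survivors)] = survivors
    present[n_old:] = True
    truth.present[year_index] = present


def _available_roosts(config: ColonyConfig, year_index: int, day: int) -> np.ndarray:
    if config.roost_availability and year_index in config.roost_availability:
        base = np.asarray(sorted(config.roost_availability[year_index]), dtype=int)
    else:
        base = np.arange(config.n_roosts)
    if config.early_season_roost_ramp is not None:
        n_start, ramp_days = config.early_season_roost_ramp
        if day < ramp_days:
            n_open = n_start + int(
                round((len(base) - n_start) * day / max(ramp_days, 1))
            )
            base = base[: max(n_open, 1)]
    return base


def _run_occupancy(
    truth: GroundTruth, config: ColonyConfig, rng: np.random.Generator
) -> None:
    """Fill ``truth.occupancy`` by simulating every season day by day."""
    records_tag: list[str] = []
    records_date: list[dt.date] = []
    records_roost: list[str] = []
    roost_names = truth.roost_ids(config.n_roosts)
    for y in range(config.n_years):
        if y > 0:
            advance_year(truth, config, y, rng)
        present_idx = np.flatnonzero(truth.present[y])
        start = config.season_start(y)
        for d in range(config.days_per_season):
            available = _available_roosts(config, y, d)
            roosts = simulate_day(
                present_idx,
                truth.affinity[y],
                truth.preferences,
                available,
                config.w_social,
                config.w_fidelity,
                rng,
            )
            date = start + dt.timedelta(days=d)
            for bi, r in zip(present_idx, roosts):
                records_tag.append(truth.tag_ids[bi])
                records_date.append(date)
                records_roost.append(roost_names[r])
    truth.occupancy = pd.DataFrame(
        {"tag_id": records_tag, "date": records_date, "roost_id": records_roost}
    )


def emit_detections(
    truth: GroundTruth,
    p_detect: float,
    sun: SunProvider,
    rng: np.random.Generator,
    *,
    p_sunrise_detect: float = 0.9,
    p_day_switch: float = 0.0,
    n_roosts: Optional[int] = None,
) -> pd.DataFrame:
    """Detection stream from the true occupancy.

    Each (bat, date, roost) independently yields, with probability
    ``p_detect``, a pre-sunset read at the day roost; detected bat-days
    additionally yield, with probability ``p_sunrise_detect``, a pre-sunrise
    read the same morning — at the day roost, except with probability
    ``p_day_switch`` at a different roost (the bat entered one box at dawn
    and moved before sunset).  Missingness is independent across bat-days.
    """
    occ = truth.occupancy
    if occ.empty:
        return pd.DataFrame(columns=["tag_id", "roost_id", "timestamp"])
    n_roosts = n_roosts if n_roosts is not None else truth.preferences.shape[1]
    roost_names = truth.roost_ids(n_roosts)
    m = len(occ)
    detected = rng.random(m) < p_detect
    morning = detected & (rng.random(m) < p_sunrise_detect)
    switched = morning & (rng.random(m) < p_day_switch)
    evening_offset_min = rng.uniform(30.0, 360.0, size=m)  # before sunset
    morning_offset_min = rng.uniform(5.0, 60.0, size=m)  # before sunrise
    other_roost_u = rng.random(m)

    sunset_cache: dict[dt.date, dt.datetime] = {}
    sunrise_cache: dict[dt.date, dt.datetime] = {}
    rows_tag, rows_roost, rows_ts = [], [], []
    tags = occ["tag_id"].to_numpy()
    dates = occ["date"].to_numpy()
    roosts = occ["roost_id"].to_numpy()
    for i in range(m):
        if not detected[i]:
            continue
        date = dates[i]
        if date not in sunset_cache:
            sunset_cache[date] = sun.sunset(date)
            sunrise_cache[date] = sun.sunrise(date)
        rows_tag.append(tags[i])
        rows_roost.append(roosts[i])
        rows_ts.append(
            sunset_cache[date] - dt.timedelta(minutes=float(evening_offset_min[i]))
        )
        if morning[i]:
            roost = roosts[i]
            if switched[i] and n_roosts > 1:
                k = roost_names.index(roost)
                alt = int(other_roost_u[i] * (n_roosts - 1))
                alt = alt if alt < k else alt + 1
                roost = roost_names[alt]
            rows_tag.append(tags[i])
            rows_roost.append(roost)
            rows_ts.append(
                sunrise_cache[date]
                - dt.timedelta(minutes=float(morning_offset_min[i]))
            )
    out = pd.DataFrame(
        {"tag_id": rows_tag, "roost_id": rows_roost, "timestamp": rows_ts}
    )
    return out.sort_values(["tag_id", "timestamp"], kind="mergesort").reset_index(
        drop=True
    )


def occupancy_to_day_roosts(truth: GroundTruth) -> pd.DataFrame:
    """True occupancy as a day-roost table (the table a perfect detector
    would recover)."""
    out = truth.occupancy.copy()
    out["basis"] = "pre_sunset"
    return out.sort_values(["tag_id", "date"], kind="mergesort").reset_index(drop=True)


@dataclasses.dataclass
class SimulatedColony:
    """Full simulation bundle: latent truth plus observable data."""

    config: ColonyConfig
    truth: GroundTruth
    detections: pd.DataFrame
    roster: pd.DataFrame
    windows: dict[int, AnalysisWindow]
    sun: SunProvider

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        det = self.detections.copy()
        det["timestamp"] = det["timestamp"].map(lambda t: t.isoformat())
        det.to_csv(outdir / "detections.csv", index=False)
        self.roster.to_csv(outdir / "roster.csv", index=False)
        occ = self.truth.occupancy.copy()
        occ["date"] = occ["date"].map(lambda d: d.isoformat())
        occ.to_csv(outdir / "true_occupancy.csv", index=False)
        meta = {
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(self.config).items()
            },
            "n_bats_total": len(self.truth.tag_ids),
            "years": sorted(self.windows),
        }
        (outdir / "ground_truth.json").write_text(json.dumps(meta, indent=2))
        windows_yaml = {
            "min_obs": 10,
            "years": {
                y: {
                    "start": w.start_date.isoformat(),
                    "parturition_cutoff": w.parturition_cutoff_date.isoformat(),
                }
                for y, w in self.windows.items()
            },
        }
        import yaml

        (outdir / "windows.yaml").write_text(yaml.safe_dump(windows_yaml))


def simulate_colony(
    config: ColonyConfig, sun: Optional[SunProvider] = None
) -> SimulatedColony:
    """Run the full multiyear simulation, bit-for-bit reproducible from
    ``config.seed``."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    sun = sun if sun is not None else SolarSunProvider()
    truth = draw_population(config, rng)
    _run_occupancy(truth, config, rng)
    detections = emit_detections(
        truth,
        config.p_detect,
        sun,
        rng,
        p_sunrise_detect=config.p_sunrise_detect,
        p_day_switch=config.p_day_switch,
        n_roosts=config.n_roosts,
    )
    return SimulatedColony(
        config=config,
        truth=truth,
        detections=detections,
        roster=truth.roster(),
        windows=config.windows(),
        sun=sun,
    )
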