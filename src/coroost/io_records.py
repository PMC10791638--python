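"""Detection-log ingestion, day-roost assignment, QC, and inclusion filters.

The raw material is a PIT-tag detection stream: antenna reads of
``(tag_id, roost_id, timestamp)`` at roost-box entrances.  Because a bat can
visit several boxes during the night, the day roost for a date is taken to
be the roost of the *last detection strictly before that date's sunset* —
the box the bat was in when it settled for the day.  A sunrise-based check
(last detection before the same morning's sunrise) quantifies how reliable
that rule is.  Analysis windows then restrict to adult females detected on
at least ``min_obs`` days between the season start and the parturition
cutoff.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from coroost.solar import SunProvider

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionEvent",
    "AnalysisWindow",
    "read_detections",
    "read_roster",
    "assign_day_roosts",
    "write_day_roosts",
    "read_day_roosts",
    "qc_sunrise_agreement",
    "filter_individuals",
    "windows_from_yaml",
]

DAY_ROOST_COLUMNS = ["tag_id", "date", "roost_id", "basis"]


class DetectionEvent(NamedTuple):
    """One antenna read: who, which roost, when (naive local time)."""

    tag_id: str
    roost_id: str
    timestamp: dt.datetime


@dataclasses.dataclass(frozen=True)
class AnalysisWindow:
    """Per-year analysis window for the pregnancy period.

    ``start_date`` defaults to 28 April of ``year``; the parturition cutoff
    must be supplied (it comes from an external assessment of parturition
    timing).  ``min_obs`` is the minimum number of assigned day roosts an
    individual needs inside the window to enter that year's network.
    """

    year: int
    parturition_cutoff_date: dt.date
    start_date: Optional[dt.date] = None
    min_obs: int = 10
    monitored_roosts: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        if self.start_date is None:
            object.__setattr__(self, "start_date", dt.date(self.year, 4, 28))
        if self.min_obs < 1:
            raise ValueError("min_obs must be >= 1")
        if not self.start_date < self.parturition_cutoff_date:
            raise ValueError("start_date must precede parturition_cutoff_date")
        if self.monitored_roosts is not None:
            object.__setattr__(
                self, "monitored_roosts", frozenset(self.monitored_roosts)
            )

    def contains(self, date: dt.date) -> bool:
        return self.start_date <= date <= self.parturition_cutoff_date


def read_detections(
    path: str | Path,
    *,
    columns: Mapping[str, str] | None = None,
    known_roosts: Optional[Iterable[str]] = None,
    allow_unknown: bool = False,
    max_malformed_fraction: float = 0.05,
    sep: str = ",",
) -> pd.DataFrame:
    """Read a delimited detection log into a tidy event table.

    Parameters
    ----------
    path:
        Delimited text file with (at least) tag, roost and timestamp
        columns.
    columns:
        Optional mapping from the canonical names ``tag_id``, ``roost_id``,
        ``timestamp`` to the file's column names.
    known_roosts:
        If given, roost ids outside this set are an error unless
        ``allow_unknown`` is set.
    max_malformed_fraction:
        Rows with unparseable timestamps or missing fields are dropped with
        a warning; if their fraction exceeds this threshold the file is
        rejected.

    Returns
    -------
    DataFrame with columns ``tag_id, roost_id, timestamp`` sorted by
    ``(tag_id, timestamp)``; the number of dropped rows is in
    ``df.attrs["n_malformed"]``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    colmap = {"tag_id": "tag_id", "roost_id": "roost_id", "timestamp": "timestamp"}
    if columns:
        colmap.update(columns)
    try:
        raw = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("detection file %s is empty", path)
        out = pd.DataFrame(columns=["tag_id", "roost_id", "timestamp"])
        out.attrs["n_malformed"] = 0
        return out
    missing = [v for v in colmap.values() if v not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    df = raw[[colmap["tag_id"], colmap["roost_id"], colmap["timestamp"]]].copy()
    df.columns = ["tag_id", "roost_id", "timestamp"]

    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    bad = ts.isna() | df["tag_id"].isna() | df["roost_id"].isna()
    n_bad = int(bad.sum())
    if len(df) and n_bad / len(df) > max_malformed_fraction:
        rows = (df.index[bad] + 2).tolist()  # 1-based incl. header
        raise ValueError(
            f"{path}: {n_bad}/{len(df)} malformed rows exceeds "
            f"{max_malformed_fraction:.0%} threshold (file rows {rows[:20]})"
        )
    if n_bad:
        logger.warning("%s: dropped %d malformed rows", path, n_bad)
    df = df.loc[~bad].copy()
    df["timestamp"] = ts.loc[~bad]

    if known_roosts is not None:
        known = set(map(str, known_roosts))
        unknown = set(df["roost_id"]) - known
        if unknown and not allow_unknown:
            raise ValueError(f"{path}: unknown roost ids {sorted(unknown)}")
    df = df.sort_values(["tag_id", "timestamp"], kind="mergesort").reset_index(
        drop=True
    )
    df.attrs["n_malformed"] = n_bad
    return df


def read_roster(path: str | Path, sep: str = ",") -> pd.DataFrame:
    """Read the individual roster.

    Expected columns: ``tag_id, sex, age_class_at_capture, capture_year``
    and optionally ``cohort_year`` (the birth-cohort year; equal to
    ``capture_year`` for bats first captured as juveniles) and
    ``reproductive_status``.
    """
    df = pd.read_csv(path, sep=sep, dtype={"tag_id": str})
    required = {"tag_id", "sex", "age_class_at_capture", "capture_year"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: roster missing columns {sorted(missing)}")
    if "cohort_year" not in df.columns:
        df["cohort_year"] = np.nan
    df["capture_year"] = df["capture_year"].astype(int)
    df["cohort_year"] = pd.to_numeric(df["cohort_year"], errors="coerce")
    juv = df["age_class_at_capture"].str.lower().eq("juvenile")
    # juveniles have age 0 in their capture year, so the cohort is known
    df.loc[juv & df["cohort_year"].isna(), "cohort_year"] = df.loc[
        juv, "capture_year"
    ]
    return df


def assign_day_roosts(
    events: pd.DataFrame,
    sun: SunProvider,
    *,
    sunrise_fallback: bool = False,
) -> pd.DataFrame:
    """Assign one day roost per (bat, date) from the detection stream.

    For each bat and calendar date, the roost of the last detection
    *strictly before* that date's sunset is the day roost
    (``basis="pre_sunset"``).  Detections at or after sunset never create an
    assignment for that date; a (bat, date) with no pre-sunset detection
    gets no row, unless ``sunrise_fallback`` is set, in which case a last
    detection before the same morning's sunrise is used with
    ``basis="pre_sunrise_only"``.

    The result is independent of the input row order and idempotent.
    """
    if events.empty:
        out = pd.DataFrame(columns=DAY_ROOST_COLUMNS)
        out.attrs["sun_source"] = type(sun).__name__
        return out
    ev = events.sort_values(["tag_id", "timestamp"], kind="mergesort")
    dates = ev["timestamp"].dt.date
    sunset_by_date: dict[dt.date, dt.datetime] = {}
    sunrise_by_date: dict[dt.date, dt.datetime] = {}
    missing_dates = []
    for d in pd.unique(dates):
        try:
            sunset_by_date[d] = sun.sunset(d)
            if sunrise_fallback:
                sunrise_by_date[d] = sun.sunrise(d)
        except KeyError:
            missing_dates.append(d)
    if missing_dates:
        raise ValueError(f"no sun times for dates: {sorted(missing_dates)}")

    sunset = dates.map(sunset_by_date)
    pre_sunset = ev.loc[ev["timestamp"] < pd.to_datetime(sunset)]
    # last pre-sunset read per (bat, date)
    grouped = pre_sunset.groupby(
        [pre_sunset["tag_id"], pre_sunset["timestamp"].dt.date], sort=True
    ).last()
    out = grouped.reset_index(names=["tag_id", "date"])[
        ["tag_id", "date", "roost_id"]
    ]
    out["basis"] = "pre_sunset"

    if sunrise_fallback:
        sunrise = dates.map(sunrise_by_date)
        pre_sunrise = ev.loc[ev["timestamp"] < pd.to_datetime(sunrise)]
        g2 = pre_sunrise.groupby(
            [pre_sunrise["tag_id"], pre_sunrise["timestamp"].dt.date], sort=True
        ).last()
        fb = g2.reset_index(names=["tag_id", "date"])[["tag_id", "date", "roost_id"]]
        assigned = set(zip(out["tag_id"], out["date"]))
        fb = fb.loc[[t not in assigned for t in zip(fb["tag_id"], fb["date"])]]
        fb = fb.assign(basis="pre_sunrise_only")
        out = pd.concat([out, fb], ignore_index=True)

    out = out.sort_values(["tag_id", "date"], kind="mergesort").reset_index(drop=True)
    out.attrs["sun_source"] = type(sun).__name__
    return out


def write_day_roosts(day_roosts: pd.DataFrame, path: str | Path) -> None:
    df = day_roosts.copy()
    df["date"] = df["date"].map(lambda d: d.isoformat())
    df.to_csv(path, index=False)


def read_day_roosts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"tag_id": str, "roost_id": str})
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df


def qc_sunrise_agreement(
    events: pd.DataFrame,
    day_roosts: pd.DataFrame,
    sun: SunProvider,
) -> tuple[float, pd.DataFrame]:
    """Sunset/sunrise roost-assignment agreement.

    For every assigned (bat, date) that also has a last detection strictly
    before that same morning's sunrise, record whether the pre-sunrise and
    pre-sunset roosts match.  Returns ``(agreement_fraction, flags)`` where
    the fraction's denominator counts only comparable records (those with a
    pre-sunrise detection); with no comparable records the fraction is NaN.
    """
    if day_roosts.empty:
        raise ValueError("day_roosts is empty")
    ev = events.sort_values(["tag_id", "timestamp"], kind="mergesort")
    dates = ev["timestamp"].dt.date
    sunrise_by_date = {d: sun.sunrise(d) for d in pd.unique(dates)}
    sunrise = dates.map(sunrise_by_date)
    pre_sunrise = ev.loc[ev["timestamp"] < pd.to_datetime(sunrise)]
    last_morning = (
        pre_sunrise.groupby([pre_sunrise["tag_id"], pre_sunrise["timestamp"].dt.date])
        .last()["roost_id"]
        .rename("morning_roost")
        .rename_axis(["tag_id", "date"])
        .reset_index()
    )
    merged = day_roosts.merge(last_morning, on=["tag_id", "date"], how="left")
    merged["comparable"] = merged["morning_roost"].notna()
    merged["agrees"] = merged["comparable"] & (
        merged["morning_roost"] == merged["roost_id"]
    )
    n_comp = int(merged["comparable"].sum())
    frac = float(merged["agrees"].sum() / n_comp) if n_comp else float("nan")
    return frac, merged


def is_adult_in_year(roster_row: pd.Series, year: int) -> bool:
    """Adult status for ``year``: captured as adult, or captured as a
    juvenile in an earlier year (juveniles qualify as adults from the year
    after their juvenile capture)."""
    age_class = str(roster_row["age_class_at_capture"]).lower()
    if age_class == "adult":
        return True
    return year > int(roster_row["capture_year"])


def filter_individuals(
    day_roosts: pd.DataFrame,
    roster: pd.DataFrame,
    window: AnalysisWindow,
    *,
    drop_unknown_tags: bool = True,
) -> pd.DataFrame:
    """Restrict a day-roost table to qualifying adult females in a window.

    Retains rows inside ``[start_date, parturition_cutoff_date]`` for
    females who are adults in ``window.year`` and have at least
    ``window.min_obs`` assigned day roosts inside the window.
    """
    if day_roosts.empty:
        return day_roosts.iloc[0:0].copy()
    years = {d.year for d in day_roosts["date"]}
    in_window = day_roosts["date"].map(window.contains)
    if window.year not in years and in_window.any():
        raise ValueError(
            f"window year {window.year} does not match day-roost dates {sorted(years)}"
        )
    dr = day_roosts.loc[in_window].copy()
    roster_idx = roster.set_index("tag_id")
    unknown = set(dr["tag_id"]) - set(roster_idx.index)
    if unknown:
        if not drop_unknown_tags:
            raise ValueError(f"tags absent from roster: {sorted(unknown)}")
        logger.warning("dropping %d tags absent from roster", len(unknown))
        dr = dr.loc[~dr["tag_id"].isin(unknown)]

    def qualifies(tag: str) -> bool:
        row = roster_idx.loc[tag]
        if str(row["sex"]).upper() != "F":
            return False
        return is_adult_in_year(row, window.year)

    eligible = {t for t in dr["tag_id"].unique() if qualifies(t)}
    dr = dr.loc[dr["tag_id"].isin(eligible)]
    counts = dr.groupby("tag_id").size()
    keep = set(counts.index[counts >= window.min_obs])
    out = dr.loc[dr["tag_id"].isin(keep)].reset_index(drop=True)
    return out


def windows_from_yaml(path: str | Path) -> dict[int, AnalysisWindow]:
    """Load per-year analysis windows from a YAML config.

    Schema::

        min_obs: 10            # optional global default
        years:
          2015:
            start: 2015-04-28          # optional, defaults to 28 April
            parturition_cutoff: 2015-07-16
            monitored_roosts: [R01, R02]   # optional
    """
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    default_min_obs = int(cfg.get("min_obs", 10))
    windows: dict[int, AnalysisWindow] = {}
    for year, spec in cfg["years"].items():
        year = int(year)
        cutoff = _as_date(spec["parturition_cutoff"])
        start = _as_date(spec["start"]) if "start" in spec else None
        roosts = spec.get("monitored_roosts")
        windows[year] = AnalysisWindow(
            year=year,
            parturition_cutoff_date=cutoff,
            start_date=start,
            min_obs=int(spec.get("min_obs", default_min_obs)),
            monitored_roosts=frozenset(map(str, roosts)) if roosts else None,
        )
    return windows


def _as_date(value: object) -> dt.date:
    if isinstance(value, dt.date) and not isinstance(value, dt.datetime):
        return value
    if isinstance(value, dt.datetime):
        return value.date()
    return dt.date.fromisoformat(str(value))
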