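"""End-to-end orchestration: one config in, a reproducible output bundle out.

Stages run in analysis order — day-roost assignment with QC, per-year SRI
networks, lagged association rate with the analytic null, Mantel tests for
all year pairs, MRQAP (previous-year association + roost co-occurrence)
for all focal/comparison pairs with fold-differences, node metrics with
age regressions, and the cohort paired comparison.  All randomness flows
from one root seed via named substreams, so re-running one stage never
perturbs another, and outputs are plain CSV/JSON regenerable figures can
be drawn from alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from coroost import association, fidelity, inference, io_records, lagged, metrics
from coroost.inference import COOCCURRENCE, PREV_ASSOCIATION
from coroost.io_records import AnalysisWindow
from coroost.solar import SolarSunProvider, SunProvider, TableSunProvider

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_full_pipeline", "make_figures"]


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration, serialized with the outputs."""

    detections_path: str
    roster_path: str
    windows_path: str
    output_dir: str
    seed: int = 0
    n_perm_mantel: int = 999
    n_perm_mrqap: int = 999
    max_lag: Optional[int] = None  # default: full record span
    betweenness_mode: str = "binary"
    cv_include_zeros: bool = True
    mantel_method: str = "pearson"
    latitude: float = 47.3
    longitude: float = -53.3
    utc_offset_hours: float = -2.5
    min_shared_bats: int = 4

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(**cfg)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def substream(root_seed: int, stage: str) -> np.random.Generator:
    """Named, independent random substream for one pipeline stage."""
    return np.random.default_rng(
        np.random.SeedSequence([root_seed & 0x7FFFFFFF, zlib.crc32(stage.encode())])
    )


@dataclasses.dataclass
class PipelineResult:
    day_roosts: pd.DataFrame
    qc_agreement: float
    networks: dict[int, association.AssociationMatrix]
    cooccurrence: dict[int, "fidelity.CooccurrenceMatrix"]
    lar: lagged.LARCurve
    null_rate: float
    roosts_per_day: pd.DataFrame
    mantel: list[inference.MantelResult]
    mrqap: list[inference.MRQAPResult]
    node_metrics: pd.DataFrame
    age_regressions: dict[str, metrics.RegressionResult]
    cohort: Optional[metrics.CohortComparison]
    output_dir: Optional[Path] = None


def run_full_pipeline(
    config: RunConfig,
    *,
    sun: Optional[SunProvider] = None,
    write_outputs: bool = True,
) -> PipelineResult:
    """Run every stage of the analysis and (optionally) write the bundle."""
    outdir = Path(config.output_dir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)
    sun = sun or SolarSunProvider(
        config.latitude, config.longitude, config.utc_offset_hours
    )

    logger.info("stage io: reading inputs")
    events = io_records.read_detections(config.detections_path)
    roster = io_records.read_roster(config.roster_path)
    windows = io_records.windows_from_yaml(config.windows_path)
    logger.info(
        "io: %d events, %d bats in roster, %d windows",
        len(events),
        len(roster),
        len(windows),
    )

    logger.info("stage assign: day-roost assignment")
    day_roosts = io_records.assign_day_roosts(events, sun)
    qc_frac, qc_flags = io_records.qc_sunrise_agreement(events, day_roosts, sun)
    logger.info(
        "assign: %d day-roost rows, sunrise agreement %.3f", len(day_roosts), qc_frac
    )

    logger.info("stage networks: per-year SRI matrices")
    networks = association.yearly_networks(day_roosts, roster, windows)
    filtered_by_year = {
        y: io_records.filter_individuals(day_roosts, roster, windows[y])
        for y in networks
    }

    logger.info("stage lar: lagged association rate")
    all_filtered = pd.concat(filtered_by_year.values(), ignore_index=True)
    gbd_all = association.build_group_by_day(all_filtered)
    span = (max(all_filtered["date"]) - min(all_filtered["date"])).days
    max_lag = config.max_lag if config.max_lag is not None else span
    lar = lagged.lagged_association_rate(gbd_all, max_lag=max(max_lag, 1))
    null_rate = lagged.null_association_rate(gbd_all)
    lar.null_rate = null_rate
    roosts_per_day, _ = lagged.roosts_in_use_by_day(all_filtered)

    logger.info("stage fidelity: co-occurrence probability matrices")
    cooc = {}
    for y in networks:
        profiles = fidelity.roost_use_profiles(filtered_by_year[y], windows[y])
        cooc[y] = fidelity.cooccurrence_probability(profiles)

    logger.info("stage mantel: all year pairs")
    rng_mantel = substream(config.seed, "mantel")
    mantel_results = []
    years = sorted(networks)
    for i, y1 in enumerate(years):
        for y2 in years[i + 1 :]:
            aligned = inference.align_years(
                networks[y1], networks[y2], min_shared=config.min_shared_bats
            )
            if aligned is None:
                continue
            m1, m2, _ = aligned
            mantel_results.append(
                inference.mantel_test(
                    m1,
                    m2,
                    n_perm=config.n_perm_mantel,
                    rng=rng_mantel,
                    method=config.mantel_method,
                    year_pair=(y1, y2),
                )
            )

    logger.info("stage mrqap: focal vs previous years")
    rng_mrqap = substream(config.seed, "mrqap")
    mrqap_results = []
    for focal in years:
        for comp in years:
            if comp >= focal:
                continue
            aligned = inference.align_years(
                networks[focal], networks[comp], min_shared=config.min_shared_bats
            )
            if aligned is None:
                continue
            net_f, net_c, shared = aligned
            cooc_f = cooc[focal].subset(shared)
            try:
                res = inference.mrqap_dsp(
                    net_f,
                    {PREV_ASSOCIATION: net_c, COOCCURRENCE: cooc_f},
                    n_perm=config.n_perm_mrqap,
                    rng=rng_mrqap,
                    focal_year=focal,
                    comparison_year=comp,
                )
            except ValueError as exc:
                logger.warning("mrqap %d vs %d skipped: %s", focal, comp, exc)
                continue
            mrqap_results.append(res)

    logger.info("stage metrics: node metrics and age regressions")
    node_rows = metrics.node_metric_table(
        networks,
        roster,
        betweenness_mode=config.betweenness_mode,
        cv_include_zeros=config.cv_include_zeros,
    )
    age_regs = {}
    for metric_name in ("degree", "betweenness", "cv_sri"):
        try:
            age_regs[metric_name] = metrics.age_metric_regression(node_rows, metric_name)
        except ValueError as exc:
            logger.warning("age regression for %s skipped: %s", metric_name, exc)

    logger.info("stage cohort: within- vs among-cohort paired test")
    cohort = None
    try:
        cohort = metrics.cohort_paired_test(networks, roster)
    except ValueError as exc:
        logger.warning("cohort test skipped: %s", exc)

    result = PipelineResult(
        day_roosts=day_roosts,
        qc_agreement=qc_frac,
        networks=networks,
        cooccurrence=cooc,
        lar=lar,
        null_rate=null_rate,
        roosts_per_day=roosts_per_day,
        mantel=mantel_results,
        mrqap=mrqap_results,
        node_metrics=node_rows,
        age_regressions=age_regs,
        cohort=cohort,
        output_dir=outdir if write_outputs else None,
    )
    if write_outputs:
        _write_bundle(result, config, qc_flags)
    return result


def _write_bundle(
    result: PipelineResult, config: RunConfig, qc_flags: pd.DataFrame
) -> None:
    outdir = result.output_dir
    assert outdir is not None
    cfg_hash = config.config_hash()

    io_records.write_day_roosts(result.day_roosts, outdir / "day_roosts.csv")
    qc = {
        "config_hash": cfg_hash,
        "sunrise_agreement": result.qc_agreement,
        "n_day_roosts": int(len(result.day_roosts)),
        "n_comparable": int(qc_flags["comparable"].sum()),
    }
    (outdir / "qc_report.json").write_text(json.dumps(qc, indent=2))

    long_frames = [result.networks[y].to_long_frame() for y in sorted(result.networks)]
    pd.concat(long_frames, ignore_index=True).to_csv(
        outdir / "networks_long.csv", index=False
    )
    for y in sorted(result.networks):
        result.networks[y].to_square_frame().to_csv(outdir / f"sri_{y}.csv")
        result.cooccurrence[y].to_square_frame().to_csv(outdir / f"cooccurrence_{y}.csv")

    result.lar.to_frame().to_csv(outdir / "lar.csv", index=False)
    (outdir / "lar_null.json").write_text(
        json.dumps({"config_hash": cfg_hash, "null_rate": result.null_rate}, indent=2)
    )
    result.roosts_per_day.to_csv(outdir / "roosts_in_use.csv", index=False)

    pd.DataFrame(
        [
            {
                "year_a": r.year_pair[0],
                "year_b": r.year_pair[1],
                "year_gap": r.year_gap,
                "n_shared_bats": r.n_shared_bats,
                "mantel_r": r.r,
                "p_two_tailed": r.p_two_tailed,
                "p_one_tailed": r.p_one_tailed,
                "n_permutations": r.n_permutations,
            }
            for r in result.mantel
        ]
    ).to_csv(outdir / "mantel.csv", index=False)

    rows = []
    for r in result.mrqap:
        fd = inference.fold_difference(r) if r.coefficients[PREV_ASSOCIATION] != 0 else None
        rows.append(
            {
                "focal_year": r.focal_year,
                "comparison_year": r.comparison_year,
                "year_gap": r.year_gap,
                "n": r.n_bats,
                "prev_association_estimate": r.coefficients[PREV_ASSOCIATION],
                "prev_association_p": r.p_two_tailed[PREV_ASSOCIATION],
                "cooccurrence_estimate": r.coefficients[COOCCURRENCE],
                "cooccurrence_p": r.p_two_tailed[COOCCURRENCE],
                "r_squared": r.r_squared,
                "fold_difference": fd,
                "n_permutations": r.n_permutations,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "mrqap.csv", index=False)

    result.node_metrics.to_csv(outdir / "node_metrics.csv", index=False)
    regs = {
        name: dataclasses.asdict(reg) for name, reg in result.age_regressions.items()
    }
    (outdir / "age_regressions.json").write_text(
        json.dumps({"config_hash": cfg_hash, "regressions": regs}, indent=2)
    )
    if result.cohort is not None:
        cohort_payload = {
            "config_hash": cfg_hash,
            "t": result.cohort.t_statistic,
            "df": result.cohort.df,
            "p": result.cohort.p_value,
            "start_year": result.cohort.start_year,
            "per_bat": result.cohort.per_bat.to_dict(orient="records"),
        }
        (outdir / "cohort_test.json").write_text(json.dumps(cohort_payload, indent=2))
    (outdir / "run_config.json").write_text(
        json.dumps(
            {"config_hash": cfg_hash, **dataclasses.asdict(config)}, indent=2
        )
    )


def make_figures(result: PipelineResult, outdir: Optional[str | Path] = None) -> list[Path]:
    """Figure panels mirroring the analysis outputs.

    LAR-vs-lag with the null line and a roosts-in-use inset; inter-year SRI
    scatter and Mantel R vs year gap; fold-difference vs year gap; node
    metrics vs age.  Stages with missing output skip their figure with a
    warning.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir) if outdir is not None else result.output_dir
    if outdir is None:
        raise ValueError("no output directory")
    outdir.mkdir(parents=True, exist_ok=True)
    made: list[Path] = []

    # --- LAR with null line and roosts-in-use inset
    lar_df = result.lar.to_frame().dropna(subset=["rate"])
    if len(lar_df):
        fig, ax = plt.subplots(figsize=(8, 5))
        mid = (lar_df["lag_left"] + lar_df["lag_right"]) / 2
        ax.plot(mid, lar_df["rate"], "-", color="black", lw=1)
        ax.axhline(result.null_rate, color="red", ls="--", label="null rate")
        ax.set_xscale("log")
        ax.set_xlabel("lag (days)")
        ax.set_ylabel("lagged association rate")
        ax.legend(loc="upper right")
        if len(result.roosts_per_day):
            inset = ax.inset_axes([0.55, 0.55, 0.4, 0.35])
            by_doy = (
                result.roosts_per_day.groupby("day_of_year")["n_roosts"].mean()
            )
            inset.plot(by_doy.index, by_doy.values, color="tab:blue", lw=1)
            inset.set_xlabel("Julian day", fontsize=7)
            inset.set_ylabel("roosts in use", fontsize=7)
            inset.tick_params(labelsize=6)
        path = outdir / "fig_lar.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        made.append(path)
    else:
        logger.warning("figure lar skipped: no defined LAR bins")

    # --- inter-year SRI scatter + Mantel R vs gap
    if result.mantel:
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4.5))
        years = sorted(result.networks)
        pair = None
        for r in result.mantel:
            if pair is None or r.n_shared_bats > pair.n_shared_bats:
                pair = r
        if pair is not None:
            y1, y2 = pair.year_pair
            aligned = inference.align_years(result.networks[y1], result.networks[y2])
            if aligned:
                m1, m2, _ = aligned
                iu = np.triu_indices(m1.n_bats, k=1)
                ax1.scatter(m1.sri[iu], m2.sri[iu], s=8, alpha=0.5)
                ax1.set_xlabel(f"SRI {y1}")
                ax1.set_ylabel(f"SRI {y2}")
        gaps = [r.year_gap for r in result.mantel]
        rs = [r.r for r in result.mantel]
        ax2.scatter(gaps, rs, s=20)
        ax2.set_xlabel("year gap")
        ax2.set_ylabel("Mantel R")
        path = outdir / "fig_mantel.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        made.append(path)
    else:
        logger.warning("figure mantel skipped: no Mantel results")

    # --- fold difference vs gap
    folds = [
        (r.year_gap, inference.fold_difference(r))
        for r in result.mrqap
        if r.coefficients[PREV_ASSOCIATION] != 0
    ]
    folds = [(g, f) for g, f in folds if f is not None]
    if folds:
        fig, ax = plt.subplots(figsize=(6, 4.5))
        ax.scatter(*zip(*folds), s=20)
        ax.set_xlabel("year gap")
        ax.set_ylabel("fold difference (co-occurrence / previous-year)")
        path = outdir / "fig_fold_difference.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        made.append(path)
    else:
        logger.warning("figure fold-difference skipped: no MRQAP results")

    # --- metrics vs age
    nm = result.node_metrics.dropna(subset=["exact_age"]) if len(result.node_metrics) else result.node_metrics
    if len(nm):
        fig, axes = plt.subplots(1, 3, figsize=(12, 4))
        for ax, metric in zip(axes, ("degree", "betweenness", "cv_sri")):
            ages = sorted(nm["exact_age"].unique())
            data = [nm.loc[nm["exact_age"] == a, metric].dropna() for a in ages]
            ax.boxplot(data, tick_labels=[str(int(a)) for a in ages])
            for k, d in enumerate(data):
                ax.annotate(
                    str(len(d)),
                    xy=(k + 1, ax.get_ylim()[0]),
                    ha="center",
                    fontsize=7,
                )
            ax.set_xlabel("exact age")
            ax.set_ylabel(metric)
        fig.tight_layout()
        path = outdir / "fig_age_metrics.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        made.append(path)
    else:
        logger.warning("figure age-metrics skipped: no known-aged rows")
    return made
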