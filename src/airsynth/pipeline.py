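"""End-to-end pipeline: simulate -> deweather -> design -> ASCM -> summaries.

Each stage reads its inputs from and writes its artifacts to a run
directory, so stages can be re-run individually (the CLI exposes them as
subcommands) and a completed run is reproducible from its manifest alone:
the manifest records the configuration, the global seed, package versions
and a checksum for every artifact.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ascm import RidgeAugmentedSCM, placebo_scan
from .design import (
    GroupSpec,
    HeatingCalendar,
    aggregate_daily,
    aggregate_weekly,
    compute_mda8,
    population_weighted,
)
from .deweather import RfConfig, build_features, train_rf
from .effects import (
    EffectSeries,
    multi_year_summary,
    summarize,
    synthetic_difference,
)
from .health import HealthParams, attributable_deaths, avoided_deaths
from .synthetic import PanelConfig, generate_panel

log = logging.getLogger("airsynth")

STAGES = ["simulate", "deweather", "design", "ascm", "placebo", "summarize", "health"]


@dataclass
class RunConfig:
    """Pipeline configuration; every stochastic stage derives from ``seed``."""

    outdir: Path
    seed: int = 0
    simulate: PanelConfig | None = None
    panel_csv: Path | None = None
    calendar_json: Path | None = None
    groups_json: Path | None = None
    pollutants: list[str] = field(default_factory=lambda: ["pm25"])
    rf: RfConfig = field(default_factory=RfConfig)
    use_deweathered: bool = True
    treated_group: str = "two_plus_26"
    lambda_grid: list[float] | None = None
    ci: bool = True
    placebo: bool = False
    convention: str = "annual"
    health: HealthParams | None = None
    min_weeks: int = 8

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.simulate is None and self.panel_csv is None:
            raise ValueError("either a simulate config or a panel CSV is required")


# ------------------------------------------------------------------ helpers
def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _split_by_anchor(weekly: pd.Series, year: int, anchor: pd.Timestamp, min_weeks: int):
    idx = pd.DatetimeIndex(weekly.index)
    pre_lo = pd.Timestamp(_dt.date(year, 5, 1))
    post_hi = pd.Timestamp(_dt.date(year + 1, 4, 30))
    pre = weekly[(idx >= pre_lo) & (idx < anchor)]
    post = weekly[(idx >= anchor) & (idx <= post_hi)]
    if len(pre) < min_weeks or len(post) < min_weeks:
        raise ValueError(
            f"heating year {year}: {len(pre)} pre / {len(post)} post weeks, "
            f"need >= {min_weeks}"
        )
    return pre, post


def heating_year_design(
    values: pd.DataFrame,
    calendar: HeatingCalendar,
    groups: GroupSpec,
    year: int,
    treated_group: str = "two_plus_26",
    mda8: bool = False,
    min_weeks: int = 8,
    max_missing_frac: float = 0.10,
) -> dict:
    """Weekly pre/post design matrices for one treated group x heating year.

    ``values`` is an hourly wide frame (one column per city). Weeks for all
    units are anchored to the treated group's heating start so the treatment
    boundary is a week boundary. Control cities missing more than
    ``max_missing_frac`` of the window's weeks are dropped; remaining gaps
    are linearly interpolated up to 2 consecutive weeks.
    """
    treated = groups.members(treated_group)
    controls = groups.members("nonheating")
    anchor = pd.Timestamp(calendar.group_start(treated, year))
    lo = pd.Timestamp(_dt.date(year, 5, 1))
    hi = pd.Timestamp(_dt.date(year + 1, 4, 30)) + pd.Timedelta(hours=23)
    window = values[(values.index >= lo) & (values.index <= hi)]

    def weekly_of(hourly: pd.Series) -> pd.Series:
        daily = compute_mda8(hourly) if mda8 else aggregate_daily(hourly)
        return aggregate_weekly(daily, anchor.date())

    treated_hourly = population_weighted(window[treated], groups.populations)
    y1 = weekly_of(treated_hourly)
    y1_pre, y1_post = _split_by_anchor(y1, year, anchor, min_weeks)

    rows_pre, rows_post, kept = [], [], []
    for c in controls:
        wk = weekly_of(window[c])
        wk = wk.reindex(y1.index)
        frac_missing = wk.isna().mean()
        if frac_missing > max_missing_frac:
            log.warning("dropping control %s (%.0f%% weeks missing)", c, 100 * frac_missing)
            continue
        wk = wk.interpolate(limit=2, limit_area="inside")
        if wk.isna().any():
            log.warning("dropping control %s (gaps too long to interpolate)", c)
            continue
        pre, post = _split_by_anchor(wk, year, anchor, min_weeks)
        rows_pre.append(pre)
        rows_post.append(post)
        kept.append(c)
    if len(kept) < 2:
        raise ValueError(f"only {len(kept)} usable control cities in {year}")
    Y0_pre = pd.DataFrame(rows_pre, index=kept)
    Y0_post = pd.DataFrame(rows_post, index=kept)
    return {
        "year": year,
        "anchor": anchor,
        "y1_pre": y1_pre,
        "y1_post": y1_post,
        "Y0_pre": Y0_pre,
        "Y0_post": Y0_post,
    }


def fit_heating_year(
    design: dict,
    lambda_grid=None,
    ci: bool = True,
    unit: str = "",
    pollutant: str = "pm25",
):
    """ASCM fit + effect series for one prepared heating-year design."""
    est = RidgeAugmentedSCM(lambda_grid=lambda_grid)
    est.fit(design["Y0_pre"], design["y1_pre"], design["Y0_post"])
    if ci:
        est.conformal_interval()
    factual = pd.concat([design["y1_pre"], design["y1_post"]])
    effect = synthetic_difference(
        factual,
        est.fit_,
        unit=unit,
        pollutant=pollutant,
        heating_year=design["year"],
        post_start=design["anchor"],
    )
    return est, effect


# ------------------------------------------------------------------- stages
class _Run:
    """Mutable state threaded through the pipeline stages."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.panel: pd.DataFrame | None = None
        self.calendar: HeatingCalendar | None = None
        self.groups: GroupSpec | None = None
        self.deweathered: pd.DataFrame | None = None  # long: city, pollutant, ts, value
        self.designs: dict = {}
        self.fits: dict = {}
        self.effects: dict = {}
        self.summaries: dict = {}


def _stage_simulate(run: _Run, outdir: Path) -> list[Path]:
    cfg = run.config.simulate
    if cfg is None:
        # external data: just load
        run.panel = pd.read_csv(run.config.panel_csv, parse_dates=["timestamp"])
        run.calendar = HeatingCalendar.from_json(run.config.calendar_json)
        run.groups = GroupSpec.from_json(run.config.groups_json)
        return []
    cfg = dataclasses.replace(cfg, seed=run.config.seed)
    panel, truth, calendar, groups = generate_panel(cfg)
    run.panel, run.calendar, run.groups = panel, calendar, groups
    panel_path = outdir / "panel.csv"
    panel.to_csv(panel_path, index=False)
    calendar.to_json(outdir / "calendar.json")
    groups.to_json(outdir / "groups.json")
    return [panel_path, outdir / "calendar.json", outdir / "groups.json"]


def _stage_deweather(run: _Run, outdir: Path) -> list[Path]:
    cfg = run.config
    frames, metrics = [], {}
    for ci, (city, sub) in enumerate(run.panel.groupby("city_id")):
        sub = sub.sort_values("timestamp")
        feats = build_features(sub)
        for pj, p in enumerate(cfg.pollutants):
            rf = dataclasses.replace(cfg.rf, seed=(cfg.seed * 1009 + ci * 31 + pj) % (2**31 - 1))
            target = pd.Series(sub[p].to_numpy(), index=feats.index)
            model, m = train_rf(feats, target, rf)
            dew = model.deweather(feats, n_resample=rf.n_resample)
            frames.append(
                pd.DataFrame(
                    {"city_id": city, "pollutant": p,
                     "timestamp": dew.index, "value": dew.to_numpy()}
                )
            )
            metrics[f"{city}:{p}"] = dataclasses.asdict(m)
    run.deweathered = pd.concat(frames, ignore_index=True)
    dew_path = outdir / "deweathered.csv"
    run.deweathered.to_csv(dew_path, index=False)
    with open(outdir / "rf_metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=1, sort_keys=True)
    return [dew_path, outdir / "rf_metrics.json"]


def _hourly_wide(run: _Run, pollutant: str) -> pd.DataFrame:
    if run.config.use_deweathered:
        sub = run.deweathered[run.deweathered["pollutant"] == pollutant]
        return sub.pivot(index="timestamp", columns="city_id", values="value")
    return run.panel.pivot(index="timestamp", columns="city_id", values=pollutant)


def _stage_design(run: _Run, outdir: Path) -> list[Path]:
    cfg = run.config
    if cfg.use_deweathered and run.deweathered is None:
        dew_path = outdir / "deweathered.csv"
        if not dew_path.exists():
            raise FileNotFoundError("design stage needs the deweather stage's output")
        run.deweathered = pd.read_csv(dew_path, parse_dates=["timestamp"])
    rows = []
    treated = run.groups.members(cfg.treated_group)
    years = sorted(
        {y for c in treated for y in run.calendar.years(c)}
    )
    for p in cfg.pollutants:
        wide = _hourly_wide(run, p)
        for year in years:
            d = heating_year_design(
                wide, run.calendar, run.groups, year,
                treated_group=cfg.treated_group,
                mda8=(p == "o3"), min_weeks=cfg.min_weeks,
            )
            run.designs[(p, year)] = d
            for period, series in (("pre", d["y1_pre"]), ("post", d["y1_post"])):
                for ts, v in series.items():
                    rows.append((cfg.treated_group, p, year, ts.date(), period, v))
            for period, frame in (("pre", d["Y0_pre"]), ("post", d["Y0_post"])):
                for city in frame.index:
                    for ts, v in frame.loc[city].items():
                        rows.append((city, p, year, ts.date(), period, v))
    weekly = pd.DataFrame(
        rows, columns=["unit", "pollutant", "heating_year", "week_start", "period", "value"]
    )
    path = outdir / "weekly_design.csv"
    weekly.to_csv(path, index=False)
    return [path]


def _stage_ascm(run: _Run, outdir: Path) -> list[Path]:
    cfg = run.config
    paths = []
    eff_rows = []
    for (p, year), d in sorted(run.designs.items()):
        est, effect = fit_heating_year(
            d, lambda_grid=cfg.lambda_grid, ci=cfg.ci,
            unit=cfg.treated_group, pollutant=p,
        )
        run.fits[(p, year)] = est
        run.effects[(p, year)] = effect
        art = outdir / f"ascm_{cfg.treated_group}_{p}_{year}.json"
        with open(art, "w") as fh:
            json.dump(est.fit_.to_dict(), fh, indent=1)
        paths.append(art)
        for ts, v in effect.effect.items():
            eff_rows.append(
                (cfg.treated_group, p, year, ts.date(),
                 "post" if ts >= effect.post_start else "pre", v)
            )
    eff = pd.DataFrame(
        eff_rows,
        columns=["unit", "pollutant", "heating_year", "week_start", "period", "effect"],
    )
    path = outdir / "effects.csv"
    eff.to_csv(path, index=False)
    paths.append(path)
    return paths


def _stage_placebo(run: _Run, outdir: Path) -> list[Path]:
    cfg = run.config
    out = {}
    for (p, year), d in sorted(run.designs.items()):
        res = placebo_scan(
            d["Y0_pre"], d["Y0_post"], d["y1_pre"], d["y1_post"],
            lambda_grid=cfg.lambda_grid,
        )
        out[f"{p}:{year}"] = {
            "treated_mean_effect": res.treated_mean_effect,
            "pseudo_p": res.pseudo_p,
            "placebo_mean_effects": res.placebo_mean_effects.to_dict(),
        }
    path = outdir / "placebo.json"
    with open(path, "w") as fh:
        json.dump(out, fh, indent=1, sort_keys=True)
    return [path]


def _stage_summarize(run: _Run, outdir: Path) -> list[Path]:
    cfg = run.config
    per_year, multi = {}, {}
    for p in cfg.pollutants:
        summaries = []
        for (pp, year), effect in sorted(run.effects.items()):
            if pp != p:
                continue
            d = run.designs[(p, year)]
            factual_annual = float(pd.concat([d["y1_pre"], d["y1_post"]]).mean())
            s = summarize(effect, factual_annual, convention=cfg.convention)
            summaries.append(s)
            per_year[f"{p}:{year}"] = dataclasses.asdict(s)
        if summaries:
            multi[p] = multi_year_summary(summaries)
    path = outdir / "effect_summary.json"
    with open(path, "w") as fh:
        json.dump({"per_year": per_year, "multi_year": multi}, fh, indent=1, sort_keys=True)
    report = outdir / "effect_summary.txt"
    with open(report, "w") as fh:
        for key, s in sorted(per_year.items()):
            fh.write(
                f"{key}: heating-period effect {s['heating_period_effect']:.2f}, "
                f"annual effect {s['annual_effect']:.2f} "
                f"({s['relative_contribution']:.1f}% of factual annual mean "
                f"{s['factual_annual_mean']:.2f})\n"
            )
    run.summaries = {"per_year": per_year, "multi_year": multi}
    return [path, report]


def _stage_health(run: _Run, outdir: Path) -> list[Path]:
    params = run.config.health or HealthParams()
    rows = {}
    deaths_by_year = {}
    for key, s in sorted(run.summaries.get("per_year", {}).items()):
        p, year = key.split(":")
        if p != "pm25":
            continue
        factual = attributable_deaths(max(s["factual_annual_mean"], 0.0), params)
        counter = attributable_deaths(
            max(s["counterfactual_annual_mean"], 0.0), params
        )
        rows[year] = {
            "factual_concentration": factual.concentration,
            "counterfactual_concentration": counter.concentration,
            "af_factual": factual.af,
            "af_counterfactual": counter.af,
            "deaths_factual": factual.deaths,
            "deaths_counterfactual": counter.deaths,
            "heating_attributable_deaths": factual.deaths - counter.deaths,
        }
        deaths_by_year[int(year)] = factual.deaths
    if deaths_by_year:
        first, last = min(deaths_by_year), max(deaths_by_year)
        rows["avoided_vs_baseline"] = {
            "baseline_year": first,
            "final_year": last,
            "avoided_deaths": avoided_deaths(deaths_by_year[first], deaths_by_year[last]),
        }
    path = outdir / "health.json"
    with open(path, "w") as fh:
        json.dump(rows, fh, indent=1, sort_keys=True)
    return [path]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "deweather": _stage_deweather,
    "design": _stage_design,
    "ascm": _stage_ascm,
    "placebo": _stage_placebo,
    "summarize": _stage_summarize,
    "health": _stage_health,
}


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> Path:
    """Execute the pipeline stages and write a manifest; returns the run dir.

    A stage failure aborts the run with the stage named in the error; the
    partial manifest is retained with the failed stage marked FAILED.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    selected = STAGES if stages is None else stages
    if config.simulate is None and "simulate" in selected:
        pass  # simulate doubles as the load stage for external panels
    if not config.placebo:
        selected = [s for s in selected if s != "placebo"]

    run = _Run(config)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "pollutants": config.pollutants,
        "treated_group": config.treated_group,
        "use_deweathered": config.use_deweathered,
        "convention": config.convention,
        "stages": {},
        "artifacts": {},
    }
    if config.simulate is not None:
        sim = dataclasses.asdict(config.simulate)
        sim["start"], sim["end"] = str(sim["start"]), str(sim["end"])
        sim["heating_start"] = list(sim["heating_start"])
        sim["pollutants"] = list(sim["pollutants"])
        manifest["simulate_config"] = sim

    for stage in STAGES:
        if stage not in selected:
            manifest["stages"][stage] = "SKIPPED"
            continue
        t0 = time.time()
        try:
            artifacts = _STAGE_FUNCS[stage](run, outdir)
        except Exception as exc:
            manifest["stages"][stage] = "FAILED"
            with open(outdir / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=1, sort_keys=True)
            (outdir / "FAILED").write_text(f"{stage}: {exc}\n")
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = "COMPLETE"
        for path in artifacts:
            manifest["artifacts"][path.name] = _sha256(path)
        log.info("stage %s complete in %.1fs", stage, time.time() - t0)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return outdir
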