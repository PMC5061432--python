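"""End-to-end orchestration: synthesize or ingest, preprocess, fit,
screen, correlate, ordinate, classify — one reproducible report bundle
per run.

The pipeline mirrors the analysis order of the underlying field
protocol: pair/normalize counts, drop zero-inflated taxa, hourly-bin
and 4-h-average the environment, fit free-period sinusoids per taxon,
Lomb-Scargle each environmental variable, cross-correlate biology
against periodic drivers, run the 12-h-lagged RDA, and average
everything into time-of-day waveforms with MESOR phase classes.

Every filtering decision and stage failure is logged; a stage failure
never silences the independent remaining stages.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .coupling import cross_correlation, lag_series, rda_fit, rda_report
from .periodogram import lomb_scargle
from .preprocess import (
    average_4h,
    bin_hourly,
    flow_vector_to_polar,
    pair_and_normalize,
    zero_inflation_filter,
    zscore,
)
from .rhythm import fit_sinusoid, fit_table
from .series import CountSeries, EnvSeries
from .synthetic import StudyConfig, default_study_config, gen_study
from .waveform import (
    DEFAULT_NIGHT_WINDOWS,
    NightWindow,
    classify_phase,
    compute_waveform,
    robustness_check,
)

logger = logging.getLogger("dielrhythms")

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]

# variables screened for periodicity and offered to CCF/RDA; flow
# direction is circular and excluded from both (no linear treatment)
RDA_VARIABLES = ["flow_magnitude", "temperature", "oxygen", "chlorophyll", "density"]


@dataclass
class PipelineConfig:
    """One run's configuration (YAML- or dict-loadable)."""

    mode: str = "synth"  # "synth" | "ingest"
    output_dir: str = "dielrhythms_out"
    rng_seed: int | None = 0
    months: list[str] = field(default_factory=list)
    transect_paths: dict[str, str] = field(default_factory=dict)
    env_paths: dict[str, str] = field(default_factory=dict)
    seasons: dict[str, str] = field(default_factory=dict)  # month -> summer|winter
    taxa_with_trend: list[str] = field(default_factory=list)
    lag_hours: float = 12.0
    max_lag_steps: int = 6
    alpha: float = 0.05
    period_band_h: tuple[float, float] = (16.0, 32.0)
    ls_period_band_h: tuple[float, float] = (2.0, 48.0)
    ls_ofac: float = 8.0
    zero_filter_threshold: float = 1.0 / 3.0
    nominal_pair_minutes: float = 20.0
    night_windows: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("synth", "ingest"):
            raise ValueError("mode must be 'synth' or 'ingest'")
        if self.mode == "synth" and self.rng_seed is None:
            raise ValueError("synthesis mode requires rng_seed")
        if self.mode == "ingest":
            for label, p in {**self.transect_paths, **self.env_paths}.items():
                if not Path(p).exists():
                    raise FileNotFoundError(f"{label}: input path {p} does not exist")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "period_band_h" in data:
            data["period_band_h"] = tuple(data["period_band_h"])
        if "ls_period_band_h" in data:
            data["ls_period_band_h"] = tuple(data["ls_period_band_h"])
        return cls(**data)

    def night_window(self, month: str) -> NightWindow:
        if month in self.night_windows:
            lo, hi = self.night_windows[month]
            return NightWindow(lo, hi)
        season = self.seasons.get(month, "summer")
        return DEFAULT_NIGHT_WINDOWS[season]


def validate_inputs(paths: list[str | Path]) -> list[dict]:
    """Schema/sanity check of input tables; returns machine-readable
    issues (empty list = clean)."""
    issues: list[dict] = []
    for p in paths:
        p = Path(p)
        if not p.exists():
            issues.append({"path": str(p), "issue": "missing", "detail": "file not found"})
            continue
        try:
            df = dio._read_table(p)
        except Exception as exc:  # unparseable file is one issue, not a crash
            issues.append({"path": str(p), "issue": "parse", "detail": str(exc)})
            continue
        cols = set(df.columns)
        is_env = set(dio.ENV_REQUIRED_COLUMNS) - {"timestamp"} <= cols - {"timestamp"} or (
            "ns_velocity" in cols
        )
        required = dio.ENV_REQUIRED_COLUMNS if is_env else dio.TRANSECT_META_COLUMNS
        missing = [c for c in required if c not in cols]
        if missing:
            issues.append(
                {"path": str(p), "issue": "schema", "detail": f"missing columns {missing}"}
            )
        if "timestamp" in cols:
            try:
                ts = pd.to_datetime(df["timestamp"])
            except Exception as exc:
                issues.append({"path": str(p), "issue": "timestamp", "detail": str(exc)})
                continue
            if not ts.is_monotonic_increasing:
                issues.append(
                    {"path": str(p), "issue": "monotonicity",
                     "detail": "timestamps are not non-decreasing"}
                )
            numeric = [c for c in df.columns if c != "timestamp" and c != "leg_id"]
            for c in numeric:
                if not pd.api.types.is_numeric_dtype(df[c]):
                    issues.append(
                        {"path": str(p), "issue": "dtype",
                         "detail": f"column {c!r} is not numeric"}
                    )
    return issues


def _month_env_series(env_df: pd.DataFrame) -> dict[str, EnvSeries]:
    """Hourly tables -> hourly EnvSeries incl. the polar flow pair."""
    ts = pd.DatetimeIndex(env_df["timestamp"])
    out: dict[str, EnvSeries] = {}
    for col in env_df.columns:
        if col == "timestamp":
            continue
        out[col] = bin_hourly(ts, env_df[col].values, variable=col)
    if "ns_velocity" in out and "ew_velocity" in out:
        mag, direction = flow_vector_to_polar(out["ns_velocity"], out["ew_velocity"])
        out[mag.variable] = mag
        out[direction.variable] = direction
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage for every month; write one report bundle.

    Returns a summary dict (also written as run_log.json) recording the
    seed, per-stage in/out counts, filtering decisions and failures.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.rng_seed, "mode": config.mode, "months": {},
                 "failures": []}

    if config.mode == "synth":
        study_cfg = default_study_config(seed=int(config.rng_seed))
        bundle = gen_study(study_cfg)
        input_dir = outdir / "inputs"
        bundle.write(input_dir)
        months = [m.label for m in study_cfg.months]
        seasons = {m.label: m.season for m in study_cfg.months}
        trend_taxa = [t.name for t in study_cfg.taxa if t.with_trend]
        transects = {m: bundle.transects[m] for m in months}
        env_tables = {m: bundle.env_hourly[m] for m in months}
    else:
        months = config.months or sorted(config.transect_paths)
        seasons = dict(config.seasons)
        trend_taxa = list(config.taxa_with_trend)
        transects = {m: dio.read_transects(config.transect_paths[m]) for m in months}
        env_tables = {m: dio.read_env_table(config.env_paths[m], required=False)
                      for m in months}

    all_fits, all_fit_labels = [], []
    for month in months:
        mlog: dict = {"filters": {}, "stages": {}}
        log["months"][month] = mlog
        mdir = outdir / month
        mdir.mkdir(exist_ok=True)
        season = seasons.get(month, "summer")
        night = config.night_window(month) if month in config.night_windows else (
            DEFAULT_NIGHT_WINDOWS.get(season, DEFAULT_NIGHT_WINDOWS["summer"])
        )

        # --- preprocess biology ---------------------------------------
        records = dio.transect_records(transects[month])
        taxa = [c for c in transects[month].columns
                if c not in dio.TRANSECT_META_COLUMNS]
        series: dict[str, CountSeries] = {}
        manifest_rows = []
        for taxon in taxa:
            cs = pair_and_normalize(
                records, taxon, nominal_pair_minutes=config.nominal_pair_minutes
            )
            keep = zero_inflation_filter(cs, threshold=config.zero_filter_threshold)
            zeros = int(np.sum(cs.dropna().values == 0))
            manifest_rows.append(
                {"month": month, "taxon": taxon, "n_obs": cs.n, "n_zero": zeros,
                 "kept": keep,
                 "reason": "" if keep else
                 f"zero counts in {zeros}/{cs.n} observations (> 1/3)"}
            )
            if keep:
                series[taxon] = cs
        manifest = pd.DataFrame(manifest_rows)
        manifest.to_csv(mdir / "series_manifest.tsv", sep="\t", index=False)
        mlog["filters"]["zero_inflation"] = {
            "in": len(taxa), "kept": len(series),
            "discarded": [r["taxon"] for r in manifest_rows if not r["kept"]],
        }

        # --- preprocess environment -----------------------------------
        env_hourly = _month_env_series(env_tables[month])
        bio_grid = next(iter(series.values())).timestamps if series else None
        env_4h: dict[str, EnvSeries] = {}
        for name in RDA_VARIABLES:
            if name in env_hourly:
                env_4h[name] = average_4h(env_hourly[name], bio_grid=bio_grid)

        # --- rhythm fits ----------------------------------------------
        month_fits = []
        for taxon, cs in series.items():
            try:
                fit = fit_sinusoid(
                    cs, with_trend=(taxon in trend_taxa),
                    period_band_h=config.period_band_h,
                )
                month_fits.append(fit)
                all_fits.append(fit)
                all_fit_labels.append(f"{month}:{taxon}")
            except Exception as exc:
                logger.exception("rhythm fit failed for %s/%s", month, taxon)
                log["failures"].append(
                    {"month": month, "stage": "rhythm", "taxon": taxon,
                     "error": str(exc)}
                )
        if month_fits:
            fit_table(month_fits).to_csv(mdir / "sinusoid_fits.tsv", sep="\t",
                                         index=False)
        mlog["stages"]["rhythm"] = {"fits": len(month_fits)}

        # --- periodograms ---------------------------------------------
        pg_rows, periodic_vars = [], []
        for name in RDA_VARIABLES:
            if name not in env_hourly:
                continue
            try:
                pg = lomb_scargle(
                    env_hourly[name], period_band_h=config.ls_period_band_h,
                    ofac=config.ls_ofac, alpha=config.alpha,
                )
                pg_rows.append(pg.summary())
                pg.to_frame().to_csv(mdir / f"periodogram_{name}.tsv", sep="\t",
                                     index=False)
                if pg.peak_p < config.alpha:
                    periodic_vars.append(name)
            except Exception as exc:
                logger.exception("periodogram failed for %s/%s", month, name)
                log["failures"].append(
                    {"month": month, "stage": "periodogram", "variable": name,
                     "error": str(exc)}
                )
        if pg_rows:
            pd.DataFrame(pg_rows).to_csv(mdir / "periodogram_summary.tsv", sep="\t",
                                         index=False)
        mlog["stages"]["periodogram"] = {
            "tested": len(pg_rows), "periodic": periodic_vars,
        }

        # --- cross-correlations (only periodic drivers are tested) ----
        ccf_rows = []
        for taxon, cs in series.items():
            for name in periodic_vars:
                try:
                    res = cross_correlation(env_4h[name], cs,
                                            max_lag_steps=config.max_lag_steps)
                    tbl = res.to_frame()
                    tbl.insert(0, "taxon", taxon)
                    tbl.insert(1, "env_variable", name)
                    ccf_rows.append(tbl)
                except Exception as exc:
                    logger.exception("CCF failed for %s/%s~%s", month, taxon, name)
                    log["failures"].append(
                        {"month": month, "stage": "ccf", "taxon": taxon,
                         "variable": name, "error": str(exc)}
                    )
        if ccf_rows:
            pd.concat(ccf_rows).to_csv(mdir / "ccf.tsv", sep="\t", index=False)
        mlog["stages"]["ccf"] = {"pairs": len(ccf_rows)}

        # --- RDA (biology lagged, environment z-scored) ---------------
        try:
            if series and env_4h:
                bio_lagged = {
                    taxon: lag_series(cs, config.lag_hours).data
                    for taxon, cs in series.items()
                }
                bio_df = pd.DataFrame(bio_lagged)
                env_df = pd.DataFrame(
                    {name: zscore(s).data for name, s in env_4h.items()}
                )
                rda = rda_fit(bio_df, env_df, lag_h=config.lag_hours)
                rda_report(rda).to_csv(mdir / "rda_scores.tsv", sep="\t", index=False)
                mlog["stages"]["rda"] = {
                    "eigenvalues": [float(e) for e in rda.eigenvalues],
                    "proportion_explained": [float(p)
                                             for p in rda.proportion_explained],
                    "dropped_predictors": rda.dropped_predictors,
                }
        except Exception as exc:
            logger.exception("RDA failed for %s", month)
            log["failures"].append({"month": month, "stage": "rda", "error": str(exc)})

        # --- waveforms -------------------------------------------------
        wf_rows, wf_summary = [], []
        for taxon, cs in series.items():
            try:
                wf, wf_trim = robustness_check(cs, label=taxon)
                tbl = wf.to_frame()
                tbl.insert(0, "series", taxon)
                wf_rows.append(tbl)
                phase = classify_phase(wf, night)
                wf_summary.append(
                    {"series": taxon, "kind": "biology", "mesor": wf.mesor,
                     "phase_class": phase,
                     "peak_bins_h": ",".join(f"{b:g}" for b in wf.peak_bins_h),
                     "peak_stable": set(wf.peak_bins_h) == set(wf_trim.peak_bins_h)}
                )
            except Exception as exc:
                logger.exception("waveform failed for %s/%s", month, taxon)
                log["failures"].append(
                    {"month": month, "stage": "waveform", "taxon": taxon,
                     "error": str(exc)}
                )
        for name in periodic_vars:
            try:
                wf = compute_waveform(env_hourly[name])
                tbl = wf.to_frame()
                tbl.insert(0, "series", name)
                wf_rows.append(tbl)
                wf_summary.append(
                    {"series": name, "kind": "environment", "mesor": wf.mesor,
                     "phase_class": "", "peak_bins_h":
                     ",".join(f"{b:g}" for b in wf.peak_bins_h),
                     "peak_stable": ""}
                )
            except Exception as exc:
                log["failures"].append(
                    {"month": month, "stage": "waveform", "variable": name,
                     "error": str(exc)}
                )
        if wf_rows:
            pd.concat(wf_rows).to_csv(mdir / "waveforms.tsv", sep="\t", index=False)
        if wf_summary:
            pd.DataFrame(wf_summary).to_csv(mdir / "waveform_summary.tsv", sep="\t",
                                            index=False)
        mlog["stages"]["waveform"] = {"series": len(wf_summary)}

    if all_fits:
        fit_table(all_fits, labels=all_fit_labels).to_csv(
            outdir / "fit_summary.tsv", sep="\t", index=False
        )
    import dielrhythms

    log["version"] = dielrhythms.__version__
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return log
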