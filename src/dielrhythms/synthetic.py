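"""Synthetic benthic-transect study generator.

Emulates a crawler-based visual census campaign at a deep-sea site:
monthly 5-day deployments with back-and-forth video transects every
4 h (two legs of ~10 min usable footage per slot) and concomitant
hourly environmental sensing (flow vector, temperature, oxygen,
chlorophyll, density).

The generative model mirrors the statistical structure the analysis
assumes:

* environmental variables are sums of sinusoids — a diel (~24 h) and
  optionally a tidal (~12.42 h, principal lunar semidiurnal M2)
  component — plus Gaussian sensor noise;
* animal counts are Poisson around a rectified sinusoidal rate
  λ(t) = max(0, mesor + A·cos(2π(t − acrophase)/period) + trend·step
  + gain·driver(t − lag)), so a taxon can carry an endogenous diel
  rhythm, a linear trend, a lagged environmental coupling, or any
  combination;
* the default biology-follows-environment delay is 12 h.

Counts are split between the two legs of a transect pair as independent
Poisson draws proportional to leg footage (a generator choice — the
field protocol only reports the pooled pair — recorded in the study
manifest). All randomness flows from one seed; per-variable and
per-taxon substreams are derived deterministically so adding a taxon
never perturbs another taxon's counts.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .series import CountSeries, EnvSeries, regular_grid

__all__ = [
    "RhythmSpec",
    "EnvDriverSpec",
    "CouplingSpec",
    "SamplingSpec",
    "TransectRecord",
    "StudyConfig",
    "StudyBundle",
    "gen_env_series",
    "gen_flow_components",
    "gen_count_series",
    "gen_study",
    "default_study_config",
]

M2_PERIOD_H = 12.42  # principal lunar semidiurnal tide


@dataclass
class RhythmSpec:
    """Endogenous rhythm of a taxon's detection rate.

    amplitude and mesor_level are in ind/10 min; acrophase is the local
    clock hour (hours after midnight) at which the rate peaks;
    trend_slope is ind/10 min per 4-h step (the linear-trend analogue
    used for taxa riding a lower-frequency, e.g. lunar-tidal, signal).
    """

    period_h: float = 24.0
    amplitude: float = 0.0
    mesor_level: float = 0.0
    acrophase_h: float = 0.0
    trend_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.period_h <= 0:
            raise ValueError("period must be positive")
        if self.amplitude < 0 or self.mesor_level < 0:
            raise ValueError("amplitude and mesor_level must be non-negative")
        self.acrophase_h = float(np.mod(self.acrophase_h, 24.0))


@dataclass
class EnvDriverSpec:
    """Sinusoidal model of one environmental variable.

    ``components`` is a list of (period_h, amplitude, phase_rad)
    triples; the generated series is
    baseline + Σ amp·cos(2π·t/period − phase) + N(0, noise_sd).
    """

    variable_name: str
    baseline: float = 0.0
    components: Sequence[tuple[float, float, float]] = field(default_factory=list)
    noise_sd: float = 0.0
    units: str = ""

    def __post_init__(self) -> None:
        for period, _amp, _ph in self.components:
            if period <= 0:
                raise ValueError("all component periods must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def noiseless(self, t_hours: np.ndarray) -> np.ndarray:
        t = np.asarray(t_hours, dtype=float)
        out = np.full(t.shape, float(self.baseline))
        for period, amp, phase in self.components:
            out = out + amp * np.cos(2 * np.pi * t / period - phase)
        return out


@dataclass
class CouplingSpec:
    """Linear coupling of a taxon's rate to a lagged driver variable."""

    driver: str
    lag_h: float = 12.0
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.lag_h < 0:
            raise ValueError("lag must be non-negative")


@dataclass
class SamplingSpec:
    """Campaign layout: when and how often biology and sensors sample."""

    start_time: pd.Timestamp = pd.Timestamp("2013-06-01 00:00")
    n_days: int = 5
    bio_interval_h: float = 4.0
    env_interval_h: float = 1.0
    footage_minutes_per_leg: float = 10.0
    footage_jitter_minutes: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        ratio = self.bio_interval_h / self.env_interval_h
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("bio_interval must be an integer multiple of env_interval")

    @property
    def n_env(self) -> int:
        return int(round(24 * self.n_days / self.env_interval_h))

    @property
    def n_bio(self) -> int:
        return int(round(24 * self.n_days / self.bio_interval_h))

    def env_grid(self) -> pd.DatetimeIndex:
        return regular_grid(self.start_time, self.n_env, self.env_interval_h)

    def bio_grid(self) -> pd.DatetimeIndex:
        return regular_grid(self.start_time, self.n_bio, self.bio_interval_h)


@dataclass
class TransectRecord:
    """One transect leg: timestamp of its 4-h slot, leg id, usable
    footage minutes and raw per-taxon counts."""

    timestamp: pd.Timestamp
    leg_id: str
    usable_minutes: float
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.usable_minutes < 0:
            raise ValueError("usable_minutes must be non-negative")
        for taxon, c in self.counts.items():
            if c < 0 or int(c) != c:
                raise ValueError(f"count for {taxon} must be a non-negative integer")


def _substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic named substream of the study-level seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(label.encode())])


def gen_env_series(
    spec: EnvDriverSpec,
    sampling: SamplingSpec,
    rng: np.random.Generator | None = None,
) -> EnvSeries:
    """Generate one hourly environmental series.

    t is measured in hours since the campaign start; reproducible under
    ``sampling.rng_seed`` (a substream keyed by the variable name, so
    each variable's noise is independent of the others).
    """
    if rng is None:
        rng = _substream(sampling.rng_seed, f"env:{spec.variable_name}")
    grid = sampling.env_grid()
    t_hours = (grid.asi8 - grid.asi8[0]) / 3.6e12
    values = spec.noiseless(t_hours)
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=len(grid))
    return EnvSeries(
        variable=spec.variable_name,
        data=pd.Series(values, index=grid),
        units=spec.units,
        interval_h=sampling.env_interval_h,
    )


def gen_flow_components(
    mag_spec: EnvDriverSpec,
    dir_deg: float,
    sampling: SamplingSpec,
    rng: np.random.Generator | None = None,
) -> tuple[EnvSeries, EnvSeries]:
    """Flow N-S / E-W component pair from a magnitude model and a fixed
    bearing (degrees clockwise from North, direction the flow moves
    toward). Magnitudes are clipped at zero before projection, so the
    pair round-trips exactly through ``flow_vector_to_polar``."""
    mag = gen_env_series(mag_spec, sampling, rng=rng)
    magnitude = np.clip(mag.values, 0.0, None)
    theta = np.deg2rad(dir_deg)
    ns = magnitude * np.cos(theta)
    ew = magnitude * np.sin(theta)
    grid = mag.timestamps
    return (
        EnvSeries("ns_velocity", pd.Series(ns, index=grid), units="m/s",
                  interval_h=sampling.env_interval_h),
        EnvSeries("ew_velocity", pd.Series(ew, index=grid), units="m/s",
                  interval_h=sampling.env_interval_h),
    )


def rate_at(
    rhythm: RhythmSpec,
    t_hours_since_midnight: np.ndarray,
    coupling: CouplingSpec | None = None,
    driver: EnvSeries | None = None,
    driver_midnight: pd.Timestamp | None = None,
    driver_window_h: float = 0.0,
) -> np.ndarray:
    """Rectified sinusoid-plus-driver detection rate, ind/10 min.

    ``t_hours_since_midnight`` is hours since local midnight of the
    campaign's first day, so ``acrophase_h`` keeps its clock meaning.
    The driver term is the mean of the driver's samples over the lagged
    sampling window [t − lag, t − lag + driver_window_h): counts accrue
    over the whole slot, so the rate responds to the driver over the
    matching lagged window, not to one instant. ``driver_window_h = 0``
    falls back to the sample at or before t − lag. Windows reaching
    before the driver record clamp to its first value.
    """
    t = np.asarray(t_hours_since_midnight, dtype=float)
    step = np.arange(1, len(t) + 1, dtype=float)
    lam = (
        rhythm.mesor_level
        + rhythm.amplitude
        * np.cos(2 * np.pi * (t - rhythm.acrophase_h) / rhythm.period_h)
        + rhythm.trend_slope * step
    )
    if coupling is not None and driver is not None:
        if driver_midnight is None:
            driver_midnight = driver.timestamps[0].normalize()
        d_hours = (driver.timestamps.asi8 - driver_midnight.value) / 3.6e12
        d_vals = np.asarray(driver.values, dtype=float)
        lagged_t = t - coupling.lag_h
        if driver_window_h > 0:
            csum = np.concatenate([[0.0], np.cumsum(d_vals)])
            lo = np.searchsorted(d_hours, lagged_t - 1e-9, side="left")
            hi = np.searchsorted(d_hours, lagged_t + driver_window_h - 1e-9,
                                 side="left")
            lo = np.clip(lo, 0, len(d_vals) - 1)
            hi = np.clip(hi, lo + 1, len(d_vals))
            term = (csum[hi] - csum[lo]) / (hi - lo)
        else:
            idx = np.clip(
                np.searchsorted(d_hours, lagged_t + 1e-9, side="right") - 1,
                0, len(d_hours) - 1,
            )
            term = d_vals[idx]
        lam = lam + coupling.gain * term
    return np.clip(lam, 0.0, None)


def gen_count_series(
    rhythm: RhythmSpec,
    sampling: SamplingSpec,
    coupling: CouplingSpec | None = None,
    driver: EnvSeries | None = None,
    taxon: str = "taxon",
    rng: np.random.Generator | None = None,
) -> list[TransectRecord]:
    """Generate the transect-pair records of one taxon's campaign.

    Per 4-h slot, two legs ("out", "back") of
    ``footage_minutes_per_leg`` usable minutes each; each leg's count is
    Poisson(λ·minutes/10), so the pooled pair count is
    Poisson(λ·total/10) and the normalized slot value estimates λ.
    """
    if rng is None:
        rng = _substream(sampling.rng_seed, f"bio:{taxon}")
    if sampling.footage_minutes_per_leg < 0:
        raise ValueError("footage duration must be non-negative")
    grid = sampling.bio_grid()
    midnight = sampling.start_time.normalize()
    t_h = (grid.asi8 - midnight.value) / 3.6e12
    lam = rate_at(
        rhythm, t_h, coupling, driver, driver_midnight=midnight,
        driver_window_h=sampling.bio_interval_h,
    )
    records: list[TransectRecord] = []
    for ts, rate in zip(grid, lam):
        for leg in ("out", "back"):
            minutes = sampling.footage_minutes_per_leg
            if sampling.footage_jitter_minutes > 0:
                minutes = max(
                    0.0, minutes + rng.normal(0.0, sampling.footage_jitter_minutes)
                )
            count = int(rng.poisson(rate * minutes / 10.0))
            records.append(
                TransectRecord(
                    timestamp=ts, leg_id=leg, usable_minutes=minutes,
                    counts={taxon: count},
                )
            )
    return records


@dataclass
class MonthConfig:
    label: str
    start_time: pd.Timestamp
    season: str = "summer"  # controls the night window used downstream


@dataclass
class TaxonConfig:
    name: str
    rhythm: RhythmSpec
    coupling: CouplingSpec | None = None
    with_trend: bool = False  # fit the trend model for this taxon


@dataclass
class StudyConfig:
    """Full synthetic-study description: months, taxa, drivers, layout."""

    months: list[MonthConfig]
    taxa: list[TaxonConfig]
    env_specs: list[EnvDriverSpec]
    flow_mag_spec: EnvDriverSpec
    flow_dir_deg: float = 30.0
    sampling: SamplingSpec = field(default_factory=SamplingSpec)
    rng_seed: int = 0


@dataclass
class StudyBundle:
    """Generated study: per-month transect and hourly-environment tables
    plus a manifest of the true generating parameters (for recovery
    tests)."""

    transects: dict[str, pd.DataFrame]
    env_hourly: dict[str, pd.DataFrame]
    manifest: dict

    def write(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for month, df in self.transects.items():
            p = outdir / f"transects_{month}.tsv"
            df.to_csv(p, sep="\t", index=False)
            written.append(p)
        for month, df in self.env_hourly.items():
            p = outdir / f"env_hourly_{month}.tsv"
            df.to_csv(p, sep="\t", index=False)
            written.append(p)
        p = outdir / "manifest.json"
        p.write_text(json.dumps(self.manifest, indent=2, default=str))
        written.append(p)
        return written


def gen_study(config: StudyConfig) -> StudyBundle:
    """Generate every month of a study deterministically from one seed."""
    names = [s.variable_name for s in config.env_specs] + [
        config.flow_mag_spec.variable_name
    ]
    if len(set(names)) != len(names):
        raise ValueError(f"clashing environmental variable names: {sorted(names)}")

    transects: dict[str, pd.DataFrame] = {}
    env_tables: dict[str, pd.DataFrame] = {}
    for month in config.months:
        sampling = SamplingSpec(
            start_time=month.start_time,
            n_days=config.sampling.n_days,
            bio_interval_h=config.sampling.bio_interval_h,
            env_interval_h=config.sampling.env_interval_h,
            footage_minutes_per_leg=config.sampling.footage_minutes_per_leg,
            footage_jitter_minutes=config.sampling.footage_jitter_minutes,
            rng_seed=config.rng_seed,
        )
        ns, ew = gen_flow_components(
            config.flow_mag_spec, config.flow_dir_deg, sampling,
            rng=_substream(config.rng_seed, f"{month.label}:flow"),
        )
        env_cols = {"timestamp": ns.timestamps}
        env_cols["ns_velocity"] = ns.values
        env_cols["ew_velocity"] = ew.values
        env_series: dict[str, EnvSeries] = {}
        for spec in config.env_specs:
            s = gen_env_series(
                spec, sampling,
                rng=_substream(config.rng_seed, f"{month.label}:env:{spec.variable_name}"),
            )
            env_series[spec.variable_name] = s
            env_cols[spec.variable_name] = s.values
        env_tables[month.label] = pd.DataFrame(env_cols)

        # reconstruct flow magnitude as the coupling driver where needed
        mag = EnvSeries(
            config.flow_mag_spec.variable_name,
            pd.Series(np.hypot(ns.values, ew.values), index=ns.timestamps),
            units="m/s", interval_h=sampling.env_interval_h,
        )
        env_series[config.flow_mag_spec.variable_name] = mag

        all_records: dict[pd.Timestamp, dict[str, TransectRecord]] = {}
        rows = []
        taxa_records = {}
        for taxon in config.taxa:
            driver = (
                env_series.get(taxon.coupling.driver) if taxon.coupling else None
            )
            if taxon.coupling is not None and driver is None:
                raise ValueError(
                    f"taxon {taxon.name} couples to unknown driver "
                    f"{taxon.coupling.driver!r}"
                )
            taxa_records[taxon.name] = gen_count_series(
                taxon.rhythm, sampling, taxon.coupling, driver,
                taxon=taxon.name,
                rng=_substream(config.rng_seed, f"{month.label}:bio:{taxon.name}"),
            )
        # one row per (slot, leg); counts of all taxa side by side
        n_rows = len(taxa_records[config.taxa[0].name])
        for i in range(n_rows):
            first = taxa_records[config.taxa[0].name][i]
            row = {
                "timestamp": first.timestamp,
                "leg_id": first.leg_id,
                "usable_minutes": round(first.usable_minutes, 3),
            }
            for taxon in config.taxa:
                rec = taxa_records[taxon.name][i]
                row[taxon.name] = rec.counts[taxon.name]
            rows.append(row)
        transects[month.label] = pd.DataFrame(rows)

    manifest = {
        "rng_seed": config.rng_seed,
        "months": [asdict(m) for m in config.months],
        "taxa": [asdict(t) for t in config.taxa],
        "env_specs": [asdict(s) for s in config.env_specs],
        "flow_mag_spec": asdict(config.flow_mag_spec),
        "flow_dir_deg": config.flow_dir_deg,
        "sampling": asdict(config.sampling),
        "count_noise_model": "independent Poisson per leg, rate proportional to leg footage",
        "leg_split_rule": "two independent Poisson legs; pooled pair count is Poisson(lambda * pair_minutes / 10)",
    }
    return StudyBundle(transects=transects, env_hourly=env_tables, manifest=manifest)


def default_study_config(seed: int = 0) -> StudyConfig:
    """The stated-world default study.

    Three months (June, July, December 2013-like), three taxa patterned
    on the site's community: a diurnal swimmer with an ascending trend
    coupled to flow magnitude, a crepuscular (dawn) burrower coupled to
    chlorophyll, and a nocturnal walker coupled to oxygen; all couplings
    lag the environment by 12 h. Environmental baselines approximate an
    890-m NE-Pacific canyon: weak near-bottom flow (~0.1 m/s) with diel
    and M2 tidal components, ~3.5 °C, hypoxic oxygen (~0.4 ml/l), low
    chlorophyll, sigma-density near 27.6 kg/m³.
    """
    env_specs = [
        EnvDriverSpec("temperature", baseline=3.5,
                      components=[(24.0, 0.05, 0.0), (M2_PERIOD_H, 0.08, 1.0)],
                      noise_sd=0.02, units="degC"),
        EnvDriverSpec("oxygen", baseline=0.40,
                      components=[(24.0, 0.06, np.pi)],  # minimum near mid-day start
                      noise_sd=0.01, units="ml/l"),
        EnvDriverSpec("chlorophyll", baseline=0.25,
                      components=[(24.0, 0.08, np.pi / 2)],
                      noise_sd=0.02, units="ug/l"),
        EnvDriverSpec("density", baseline=27.6,
                      components=[(M2_PERIOD_H, 0.02, 0.5)],
                      noise_sd=0.005, units="kg/m3"),
    ]
    flow_mag = EnvDriverSpec(
        "flow_magnitude", baseline=0.10,
        components=[(24.0, 0.05, np.pi), (M2_PERIOD_H, 0.02, 0.0)],
        noise_sd=0.01, units="m/s",
    )
    taxa = [
        TaxonConfig(
            "swimmer",
            RhythmSpec(period_h=24.0, amplitude=4.0, mesor_level=6.0,
                       acrophase_h=11.0, trend_slope=0.1),
            CouplingSpec(driver="flow_magnitude", lag_h=12.0, gain=10.0),
            with_trend=True,
        ),
        TaxonConfig(
            "burrower",
            RhythmSpec(period_h=24.0, amplitude=3.0, mesor_level=4.0,
                       acrophase_h=6.0),
            CouplingSpec(driver="chlorophyll", lag_h=12.0, gain=8.0),
        ),
        TaxonConfig(
            "walker",
            RhythmSpec(period_h=24.0, amplitude=1.5, mesor_level=2.0,
                       acrophase_h=22.0),
            CouplingSpec(driver="oxygen", lag_h=12.0, gain=10.0),
        ),
    ]
    months = [
        MonthConfig("june", pd.Timestamp("2013-06-01 00:00"), season="summer"),
        MonthConfig("july", pd.Timestamp("2013-07-01 00:00"), season="summer"),
        MonthConfig("december", pd.Timestamp("2013-12-01 00:00"), season="winter"),
    ]
    return StudyConfig(
        months=months, taxa=taxa, env_specs=env_specs,
        flow_mag_spec=flow_mag, flow_dir_deg=30.0,
        sampling=SamplingSpec(rng_seed=seed), rng_seed=seed,
    )
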