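"""Raw transect records and sensor streams -> regular analysis series.

The preprocessing contract, in pipeline order:

1. :func:`pair_and_normalize` — pool the two legs of each 4-h transect
   pair and normalize the pooled count to individuals per 10 min of
   usable footage.
2. :func:`zero_inflation_filter` — discard taxa whose series is zero in
   strictly more than one third of the observations (short zero-inflated
   series defeat periodicity detection).
3. :func:`bin_hourly` — average raw sensor samples into clock-hour bins
   (vector mean for circular variables).
4. :func:`flow_vector_to_polar` — N-S/E-W velocity components to flow
   magnitude and direction (degrees clockwise from North, direction the
   flow moves TOWARD — the oceanographic ADCP convention).
5. :func:`average_4h` — hourly environmental series onto the 4-h
   biological grid.
6. :func:`zscore` — center and scale (sample sd, n−1) before RDA.

4-h slots are anchored at local midnight, giving the six time-of-day
bins per day the waveform stage expects; a record belongs to the slot
containing its timestamp. Missing slots stay NaN on the grid.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .series import CountSeries, EnvSeries
from .synthetic import TransectRecord

__all__ = [
    "TransectRecord",
    "CountSeries",
    "EnvSeries",
    "pair_and_normalize",
    "zero_inflation_filter",
    "bin_hourly",
    "average_4h",
    "flow_vector_to_polar",
    "zscore",
]


def _slot_start(ts: pd.Timestamp, slot_h: float, anchor_h: float) -> pd.Timestamp:
    """Start of the slot containing ts, for slots of slot_h hours
    anchored at anchor_h o'clock local."""
    day = ts.normalize() + pd.Timedelta(hours=anchor_h)
    if ts < day:
        day -= pd.Timedelta(days=1)
    k = int((ts - day) / pd.Timedelta(hours=slot_h))
    return day + pd.Timedelta(hours=k * slot_h)


def pair_and_normalize(
    records: list[TransectRecord],
    taxon: str,
    slot_h: float = 4.0,
    slot_anchor_h: float = 0.0,
    nominal_pair_minutes: float = 20.0,
    single_leg: str = "normalize",
) -> CountSeries:
    """Pool each back-and-forth transect pair and normalize to ind/10 min.

    Slot value = (sum of the pair's counts) × 10 / (sum of the pair's
    usable minutes). When a record carries no usable duration (NaN), the
    nominal pair duration split evenly across legs stands in. A slot
    with a single leg is normalized by that leg's footage alone (with a
    warning) when ``single_leg="normalize"``, or left missing when
    ``single_leg="drop"``. A slot with zero total usable minutes is
    missing.
    """
    if single_leg not in ("normalize", "drop"):
        raise ValueError("single_leg must be 'normalize' or 'drop'")
    by_slot: dict[pd.Timestamp, list[TransectRecord]] = {}
    for rec in records:
        if taxon not in rec.counts:
            raise KeyError(f"taxon {taxon!r} absent from record at {rec.timestamp}")
        slot = _slot_start(pd.Timestamp(rec.timestamp), slot_h, slot_anchor_h)
        by_slot.setdefault(slot, []).append(rec)

    if not by_slot:
        raise ValueError("no records to normalize")
    slots = sorted(by_slot)
    grid = pd.date_range(slots[0], slots[-1], freq=pd.Timedelta(hours=slot_h))
    values = np.full(len(grid), np.nan)
    for i, slot in enumerate(grid):
        legs = by_slot.get(slot)
        if not legs:
            continue
        if len(legs) == 1 and single_leg == "drop":
            warnings.warn(f"slot {slot}: single leg, dropped", stacklevel=2)
            continue
        if len(legs) == 1:
            warnings.warn(
                f"slot {slot}: single leg, normalized by one leg's footage",
                stacklevel=2,
            )
        total_count = sum(rec.counts[taxon] for rec in legs)
        minutes = [
            rec.usable_minutes
            if rec.usable_minutes is not None and np.isfinite(rec.usable_minutes)
            else nominal_pair_minutes / 2.0
            for rec in legs
        ]
        total_minutes = float(sum(minutes))
        if total_minutes <= 0:
            continue  # unusable slot -> missing
        values[i] = total_count * 10.0 / total_minutes
    return CountSeries(taxon=taxon, data=pd.Series(values, index=grid), interval_h=slot_h)


def zero_inflation_filter(series: CountSeries, threshold: float = 1.0 / 3.0) -> bool:
    """True if the series should be KEPT.

    Discard iff zeros / observations > threshold, strictly — a series
    with exactly one third zeros is kept. Missing slots are not
    observations.
    """
    vals = series.dropna().values
    n = len(vals)
    if n < 1:
        raise ValueError("series has no observations")
    n_zero = int(np.sum(vals == 0))
    return not (n_zero / n > threshold)


def _circular_mean_deg(deg: np.ndarray) -> float:
    """Unit-vector mean of directions in degrees; NaN (undefined) when
    the mean resultant length is numerically zero (e.g. antipodal
    pairs)."""
    rad = np.deg2rad(deg)
    c, s = np.mean(np.cos(rad)), np.mean(np.sin(rad))
    if np.hypot(c, s) < 1e-9:
        warnings.warn("circular mean undefined (zero resultant)", stacklevel=3)
        return np.nan
    return float(np.mod(np.rad2deg(np.arctan2(s, c)), 360.0))


def bin_hourly(
    timestamps: pd.DatetimeIndex | list,
    values: np.ndarray | list,
    variable: str = "",
    units: str = "",
    is_circular: bool = False,
) -> EnvSeries:
    """Average an irregular sensor stream into clock-hour bins.

    Hours with no samples are missing. Circular variables (degrees) are
    averaged as unit vectors so that e.g. 350° and 10° average to 0°,
    not 180°.
    """
    ts = pd.DatetimeIndex(timestamps)
    vals = np.asarray(values, dtype=float)
    if len(ts) == 0:
        raise ValueError("empty sensor stream")
    s = pd.Series(vals, index=ts).dropna()
    hours = s.index.floor("h")
    grid = pd.date_range(hours.min(), hours.max(), freq="h")
    if is_circular:
        agg = s.groupby(hours).agg(lambda g: _circular_mean_deg(g.values))
    else:
        agg = s.groupby(hours).mean()
    out = agg.reindex(grid)
    return EnvSeries(
        variable=variable, data=out, units=units, interval_h=1.0,
        is_circular=is_circular,
    )


def average_4h(
    series: EnvSeries,
    bio_grid: pd.DatetimeIndex | None = None,
    slot_h: float = 4.0,
    slot_anchor_h: float = 0.0,
) -> EnvSeries:
    """Average an hourly environmental series onto the 4-h biological grid.

    Each slot averages the hourly values whose window starts fall in
    [slot_start, slot_start + 4 h); at least one non-missing hour is
    required, else the slot is missing. Circular series are vector-
    averaged.
    """
    if series.interval_h != 1.0:
        raise ValueError("average_4h expects an hourly series")
    idx = series.timestamps
    starts = pd.DatetimeIndex([_slot_start(t, slot_h, slot_anchor_h) for t in idx])
    if bio_grid is None:
        bio_grid = pd.date_range(starts.min(), starts.max(), freq=pd.Timedelta(hours=slot_h))
    s = pd.Series(series.values, index=starts)
    if series.is_circular:
        agg = s.dropna().groupby(level=0).agg(lambda g: _circular_mean_deg(g.values))
    else:
        agg = s.dropna().groupby(level=0).mean()
    out = agg.reindex(bio_grid)
    return EnvSeries(
        variable=series.variable, data=out, units=series.units,
        interval_h=slot_h, is_circular=series.is_circular,
    )


def flow_vector_to_polar(ns: EnvSeries, ew: EnvSeries) -> tuple[EnvSeries, EnvSeries]:
    """Velocity components -> (magnitude m/s, direction degrees).

    Direction is degrees clockwise from North, the bearing the flow
    moves toward (ADCP convention). Where both components are zero the
    magnitude is 0 and the direction is undefined (NaN).
    """
    if len(ns.timestamps) != len(ew.timestamps) or not (ns.timestamps == ew.timestamps).all():
        raise ValueError("component series must share one grid")
    nsv, ewv = ns.values, ew.values
    mag = np.hypot(nsv, ewv)
    with np.errstate(invalid="ignore"):
        direction = np.mod(np.rad2deg(np.arctan2(ewv, nsv)), 360.0)
    direction = np.where(mag > 0, direction, np.nan)
    mag_s = EnvSeries("flow_magnitude", pd.Series(mag, index=ns.timestamps),
                      units="m/s", interval_h=ns.interval_h)
    dir_s = EnvSeries("flow_direction", pd.Series(direction, index=ns.timestamps),
                      units="deg", interval_h=ns.interval_h, is_circular=True)
    return mag_s, dir_s


def zscore(series: EnvSeries) -> EnvSeries:
    """Center and scale to zero mean, unit sample sd (n−1 denominator).

    Constant series (zero sd) are rejected: a variable with no variance
    carries no information for ordination and would divide by zero.
    """
    vals = series.dropna().values
    if len(vals) < 2:
        raise ValueError("zscore needs at least 2 non-missing values")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"cannot z-score constant series {series.variable!r} (sd = 0)")
    return series.with_values((series.values - mean) / sd, units="z-score")
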