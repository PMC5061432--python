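"""Time-of-day waveform averaging, MESOR and phase classification.

Each series is folded onto the 24-h clock: a 4-h biological series
gives 6 bins per day, an hourly environmental series 24 bins, each bin
averaging the corresponding value across the (typically 5) sampled
days. The MESOR (Midline Estimated Statistic Of Rhythm) is the
re-average of the bin means and serves as the peak threshold: bins
whose mean lies STRICTLY above it form the activity peak.

Phase is classified against a configurable night window (the site's
approximate photoperiod): a peak bin containing a day/night transition
(sunrise or sunset falls inside it) is crepuscular (C); otherwise all
peak bins in daylight is diurnal (D), all in night nocturnal (N), and
anything else mixed.

A robustness variant recomputes the waveform after discarding each
bin's single maximum observation — a cheap check that a peak is not
carried by one lucky transect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import CountSeries, EnvSeries

__all__ = [
    "WaveformResult",
    "NightWindow",
    "DEFAULT_NIGHT_WINDOWS",
    "compute_waveform",
    "compute_mesor",
    "classify_phase",
    "robustness_check",
]


@dataclass
class NightWindow:
    """Local-clock night interval [night_start, night_end), allowed to
    wrap midnight. Hours are decimal clock hours."""

    night_start: float
    night_end: float

    def contains(self, hour: float) -> bool:
        h = np.mod(hour, 24.0)
        span = np.mod(self.night_end - self.night_start, 24.0)
        return bool(np.mod(h - self.night_start, 24.0) < span)


# Approximate photoperiod for a mid-latitude NE-Pacific site;
# summer nights are short (sunset ~21:30, sunrise ~05:30), winter long.
DEFAULT_NIGHT_WINDOWS: dict[str, NightWindow] = {
    "summer": NightWindow(21.5, 5.5),
    "winter": NightWindow(16.75, 8.0),
}


@dataclass
class WaveformResult:
    """Time-of-day waveform: bin means ± sd, MESOR and peak bins.

    ``bin_starts_h`` are the clock hours labelling each bin's start;
    ``peak_bins_h`` are the starts of bins strictly above the MESOR.
    """

    label: str
    bin_starts_h: np.ndarray
    bin_width_h: float
    bin_means: np.ndarray
    bin_sds: np.ndarray
    bin_counts: np.ndarray
    mesor: float

    @property
    def peak_bins_h(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.bin_starts_h[self.bin_means > self.mesor]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start_h": self.bin_starts_h,
                "mean": self.bin_means,
                "sd": self.bin_sds,
                "n": self.bin_counts,
                "above_mesor": self.bin_means > self.mesor,
            }
        )


def compute_mesor(bin_means: np.ndarray) -> float:
    """Re-average the waveform curve: unweighted mean of the
    (non-missing) bin means."""
    means = np.asarray(bin_means, dtype=float)
    finite = means[np.isfinite(means)]
    if len(finite) == 0:
        raise ValueError("no non-missing bin means")
    if len(finite) < len(means):
        warnings.warn("empty waveform bins excluded from the MESOR", stacklevel=3)
    return float(np.mean(finite))


def _clock_bins(series: CountSeries | EnvSeries) -> tuple[np.ndarray, float]:
    width = float(series.interval_h)
    starts = np.arange(0.0, 24.0, width)
    return starts, width


def compute_waveform(series: CountSeries | EnvSeries, label: str | None = None) -> WaveformResult:
    """Fold a regular series onto the clock and average across days.

    Per clock bin: mean and sample sd (n−1; NaN where a bin holds a
    single value) across days, missing slots excluded. Requires at
    least 2 days of data for the cross-day average to mean anything.
    """
    idx = series.timestamps
    span_days = (idx[-1] - idx[0]) / pd.Timedelta(days=1)
    if span_days < 1.0:
        raise ValueError("waveform needs at least 2 days of data")
    starts, width = _clock_bins(series)
    clock = (idx.hour + idx.minute / 60.0).values
    bin_of = (np.floor(clock / width) * width).astype(float)
    vals = series.values
    means = np.full(len(starts), np.nan)
    sds = np.full(len(starts), np.nan)
    counts = np.zeros(len(starts), dtype=int)
    for i, b in enumerate(starts):
        sel = vals[(bin_of == b) & np.isfinite(vals)]
        counts[i] = len(sel)
        if len(sel) >= 1:
            means[i] = np.mean(sel)
        if len(sel) >= 2:
            sds[i] = np.std(sel, ddof=1)
    name = label or getattr(series, "taxon", None) or getattr(series, "variable", "")
    return WaveformResult(
        label=name, bin_starts_h=starts, bin_width_h=width,
        bin_means=means, bin_sds=sds, bin_counts=counts,
        mesor=compute_mesor(means),
    )


def classify_phase(wf: WaveformResult, night: NightWindow) -> str:
    """Classify a waveform's peak against the night window.

    'C' if any peak bin contains a day/night transition; else 'D' if
    every peak bin lies fully in daylight, 'N' if fully in night,
    'mixed' otherwise. Requires a non-empty peak (some bin strictly
    above the MESOR).
    """
    peaks = wf.peak_bins_h
    if len(peaks) == 0:
        raise ValueError("no peak bins: waveform is flat at or below the MESOR")
    w = wf.bin_width_h

    def transition_inside(start: float) -> bool:
        for boundary in (night.night_start, night.night_end):
            off = np.mod(boundary - start, 24.0)
            if 0.0 < off < w:
                return True
        return False

    kinds = []
    for start in peaks:
        if transition_inside(start):
            return "C"
        kinds.append("N" if night.contains(start + w / 2.0) else "D")
    if all(k == "D" for k in kinds):
        return "D"
    if all(k == "N" for k in kinds):
        return "N"
    return "mixed"


def robustness_check(
    series: CountSeries | EnvSeries, label: str | None = None
) -> tuple[WaveformResult, WaveformResult]:
    """Waveform with and without each clock bin's maximum observation.

    Removing the per-bin maximum guards against a single exceptional
    transect carrying the peak; a stable peak keeps the same bins.
    Needs ≥ 3 days so the reduced bins still average ≥ 2 values.
    """
    idx = series.timestamps
    if (idx[-1] - idx[0]) / pd.Timedelta(days=1) < 2.0:
        raise ValueError("robustness check needs at least 3 days of data")
    full = compute_waveform(series, label=label)
    starts, width = _clock_bins(series)
    clock = (idx.hour + idx.minute / 60.0).values
    bin_of = (np.floor(clock / width) * width).astype(float)
    vals = series.values.copy()
    for b in starts:
        members = np.flatnonzero((bin_of == b) & np.isfinite(vals))
        if len(members) >= 2:
            vals[members[np.argmax(vals[members])]] = np.nan
        elif len(members) == 1:
            # dropping the only value would empty the bin -> missing
            vals[members[0]] = np.nan
    reduced = series.with_values(vals)
    return full, compute_waveform(reduced, label=(label or full.label) + "_trimmed")
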