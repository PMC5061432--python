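"""Regular-grid time-series containers shared across the pipeline.

Two containers carry every series through the analysis:

* :class:`CountSeries` — one taxon's normalized visual abundance
  (individuals per 10 min of usable footage) on a regular 4-h grid.
* :class:`EnvSeries` — one environmental variable (flow component,
  flow magnitude/direction, temperature, oxygen, chlorophyll, density)
  on a regular 1-h or 4-h grid.

Both wrap a :class:`pandas.Series` with a naive local-time
``DatetimeIndex`` (timestamps label the START of each sampling window;
local time is PST, UTC−8, throughout). Gaps are kept on the grid as
NaN — downstream statistics drop them pairwise rather than imputing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CountSeries", "EnvSeries", "regular_grid"]


def regular_grid(start: pd.Timestamp, n: int, interval_h: float) -> pd.DatetimeIndex:
    """A regular DatetimeIndex of ``n`` window-start timestamps."""
    return pd.date_range(start=start, periods=n, freq=pd.Timedelta(hours=interval_h))


def _check_regular(index: pd.DatetimeIndex, interval_h: float) -> None:
    if len(index) > 1:
        deltas = np.diff(index.asi8) / 3.6e12  # ns -> hours
        if not np.allclose(deltas, interval_h, rtol=0, atol=1e-9):
            raise ValueError(
                f"index is not a regular {interval_h}-h grid "
                f"(observed steps {np.unique(np.round(deltas, 6))})"
            )


@dataclass
class CountSeries:
    """Per-taxon normalized abundance on a regular 4-h grid.

    ``data`` holds ind/10 min values (NaN for missing slots). ``n`` is
    the number of non-missing observations — the sample size entering
    the ±z/√n cross-correlation bands.
    """

    taxon: str
    data: pd.Series
    interval_h: float = 4.0

    def __post_init__(self) -> None:
        self.data = pd.Series(
            np.asarray(self.data.values, dtype=float), index=self.data.index
        )
        _check_regular(self.data.index, self.interval_h)
        vals = self.data.values
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("normalized counts must be non-negative")

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def values(self) -> np.ndarray:
        return self.data.values

    @property
    def n(self) -> int:
        return int(self.data.notna().sum())

    def dropna(self) -> pd.Series:
        return self.data.dropna()

    def with_values(self, values: np.ndarray, index: pd.DatetimeIndex | None = None) -> "CountSeries":
        idx = self.data.index if index is None else index
        return CountSeries(self.taxon, pd.Series(values, index=idx), self.interval_h)


@dataclass
class EnvSeries:
    """One environmental variable on a regular grid (1-h or 4-h).

    ``is_circular`` marks angular variables (flow direction), stored in
    degrees in [0, 360); those must be averaged as unit vectors, never
    arithmetically.
    """

    variable: str
    data: pd.Series
    units: str = ""
    interval_h: float = 1.0
    is_circular: bool = False

    def __post_init__(self) -> None:
        self.data = pd.Series(
            np.asarray(self.data.values, dtype=float), index=self.data.index
        )
        _check_regular(self.data.index, self.interval_h)
        if self.is_circular:
            vals = self.data.values
            finite = np.isfinite(vals)
            vals[finite] = np.mod(vals[finite], 360.0)
            self.data = pd.Series(vals, index=self.data.index)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def values(self) -> np.ndarray:
        return self.data.values

    @property
    def n(self) -> int:
        return int(self.data.notna().sum())

    def dropna(self) -> pd.Series:
        return self.data.dropna()

    def with_values(
        self,
        values: np.ndarray,
        index: pd.DatetimeIndex | None = None,
        interval_h: float | None = None,
        variable: str | None = None,
        units: str | None = None,
    ) -> "EnvSeries":
        return EnvSeries(
            variable=self.variable if variable is None else variable,
            data=pd.Series(values, index=self.data.index if index is None else index),
            units=self.units if units is None else units,
            interval_h=self.interval_h if interval_h is None else interval_h,
            is_circular=self.is_circular,
        )
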