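import numpy as np
import pandas as pd
import pytest

import dielrhythms as dr
from dielrhythms.series import regular_grid


@pytest.fixture
def grid_4h():
    """30 slots of 4 h — one 5-day campaign."""
    return regular_grid(pd.Timestamp("2013-06-01 00:00"), 30, 4.0)


@pytest.fixture
def grid_1h():
    """120 hourly samples — one 5-day campaign."""
    return regular_grid(pd.Timestamp("2013-06-01 00:00"), 120, 1.0)


@pytest.fixture
def sampling():
    return dr.SamplingSpec(rng_seed=0)


def count_series(values, grid, taxon="taxon"):
    return dr.CountSeries(taxon, pd.Series(np.asarray(values, float), index=grid))


def env_series(values, grid, variable="var", interval_h=None, **kw):
    if interval_h is None:
        interval_h = (grid[1] - grid[0]) / pd.Timedelta(hours=1)
    return dr.EnvSeries(variable, pd.Series(np.asarray(values, float), index=grid),
                        interval_h=float(interval_h), **kw)


@pytest.fixture
def make_rhythmic_counts():
    """Poisson count series around a diel sinusoid, one seed per call."""

    def _make(seed, amplitude=6.0, mesor=6.0, acrophase_h=11.0, period_h=24.0,
              trend=0.0, n_days=5):
        samp = dr.SamplingSpec(rng_seed=seed, n_days=n_days)
        recs = dr.gen_count_series(
            dr.RhythmSpec(period_h=period_h, amplitude=amplitude,
                          mesor_level=mesor, acrophase_h=acrophase_h,
                          trend_slope=trend),
            samp, taxon="taxon",
        )
        return dr.pair_and_normalize(recs, "taxon")

    return _make
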