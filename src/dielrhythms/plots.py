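"""Optional figure helpers (matplotlib; install the ``plots`` extra).

Figures are presentation-only: every number they draw comes from an
analysis result object, never from a private recomputation.
"""

from __future__ import annotations

import numpy as np

from .coupling import CCFResult
from .periodogram import Periodogram
from .waveform import WaveformResult


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_periodogram(pg: Periodogram, ax=None):
    """Power vs period with the α significance line and the peak marked."""
    ax = _axes(ax)
    ax.plot(pg.periods_h, pg.power, lw=1)
    ax.axhline(pg.threshold_power, ls="--", color="0.4",
               label=f"α = {pg.alpha:g}")
    ax.axvline(pg.peak_period_h, ls="--", color="tab:red",
               label=f"peak {pg.peak_period_h:.2f} h (p = {pg.peak_p:.2g})")
    ax.set_xlabel("period (h)")
    ax.set_ylabel("normalized power")
    ax.set_title(pg.variable)
    ax.legend(fontsize="small")
    return ax


def plot_ccf(res: CCFResult, ax=None):
    """Lag stem plot with the ±α bands."""
    ax = _axes(ax)
    ax.stem(res.lags_h, res.ccf)
    for c, color in ((res.crit_05, "tab:blue"), (res.crit_10, "tab:red")):
        ax.axhline(c, ls="--", color=color, lw=0.8)
        ax.axhline(-c, ls="--", color=color, lw=0.8)
    ax.set_xlabel("lag (h)")
    ax.set_ylabel("CCF")
    ax.set_title(f"{res.taxon} ~ {res.env_variable} (n = {res.n})")
    ax.set_ylim(-1, 1)
    return ax


def plot_waveform(wf: WaveformResult, night=None, env_wf: WaveformResult | None = None,
                  ax=None):
    """Waveform ± sd with the MESOR line; optional shaded night window
    and overlaid (rescaled) environmental waveform."""
    ax = _axes(ax)
    x = wf.bin_starts_h + wf.bin_width_h / 2.0
    ax.errorbar(x, wf.bin_means, yerr=wf.bin_sds, fmt="o-", color="k",
                capsize=3, label=wf.label)
    ax.axhline(wf.mesor, ls="--", color="0.4", label="MESOR")
    if night is not None:
        span = np.mod(night.night_end - night.night_start, 24.0)
        start = np.mod(night.night_start, 24.0)
        if start + span <= 24.0:
            ax.axvspan(start, start + span, color="0.85", zorder=0)
        else:
            ax.axvspan(start, 24.0, color="0.85", zorder=0)
            ax.axvspan(0.0, start + span - 24.0, color="0.85", zorder=0)
    if env_wf is not None:
        ax2 = ax.twinx()
        ex = env_wf.bin_starts_h + env_wf.bin_width_h / 2.0
        ax2.plot(ex, env_wf.bin_means, color="tab:red", lw=1, label=env_wf.label)
        ax2.set_ylabel(env_wf.label, color="tab:red")
    ax.set_xlim(0, 24)
    ax.set_xlabel("local time (h)")
    ax.set_ylabel("ind / 10 min")
    ax.legend(fontsize="small")
    return ax
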