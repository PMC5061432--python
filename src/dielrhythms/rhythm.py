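"""Free-period sinusoidal least-squares rhythm models.

A count series y_t on a 4-h grid (t = 1..n integer steps) is fitted by

    y_t = a1 cos(2*pi*t / a4) + a2 sin(2*pi*t / a4) + a3            (+ a5 t)

where a4 is the free period in 4-h steps (reported in hours after
multiplying by the step length) and the optional a5 term is a linear
trend for taxa riding a lower-frequency (e.g. lunar-tidal) signal.
Writing the sinusoid through paired cosine/sine coefficients keeps the
model linear in everything except a4, so the fit is well conditioned:
given a4, (a1, a2, a3[, a5]) have a closed-form harmonic-regression
solution, and the optimizer only has to travel along the period axis.

Coefficient uncertainty is the usual nonlinear-least-squares Wald
machinery: covariance from the Jacobian at the optimum scaled by the
residual variance, two-sided t tests on n − k degrees of freedom. The
period's p-value tests a4 = 0 exactly as a linear-model coefficient
table would; residual autocorrelation is NOT corrected for (documented
caveat — counts on a 4-h grid are short enough that robust variants
are unstable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .series import CountSeries

__all__ = [
    "SinusoidFit",
    "fit_sinusoid",
    "period_significance",
    "residual_diagnostics",
    "harmonic_regression",
    "fit_table",
]


@dataclass
class SinusoidFit:
    """Result of one sinusoidal least-squares fit.

    Coefficients are in observation units (ind/10 min) except ``a4``
    (period, 4-h steps). ``period_h`` = a4 × step hours. ``params``,
    ``se``, ``tvalues``, ``pvalues`` are aligned dicts keyed
    a1, a2, a3, a4 (and a5 for the trend model).
    """

    taxon: str
    params: dict[str, float]
    se: dict[str, float]
    tvalues: dict[str, float]
    pvalues: dict[str, float]
    step_h: float
    n: int
    dof: int
    sse: float
    converged: bool
    period_pinned: bool
    fitted: pd.Series
    residuals: pd.Series
    t_index: np.ndarray
    with_trend: bool
    start_time: pd.Timestamp
    message: str = ""

    @property
    def period_h(self) -> float:
        return self.params["a4"] * self.step_h

    @property
    def period_se_h(self) -> float:
        return self.se["a4"] * self.step_h

    @property
    def amplitude(self) -> float:
        return float(np.hypot(self.params["a1"], self.params["a2"]))

    @property
    def acrophase_h(self) -> float:
        """Local clock hour of the first fitted maximum.

        The sinusoid a1 cos(w t) + a2 sin(w t) peaks where
        w t = atan2(a2, a1); t is then mapped through the series start
        time onto a [0, 24) clock."""
        if self.amplitude == 0:
            return float("nan")
        phi = np.arctan2(self.params["a2"], self.params["a1"])
        t_peak = np.mod(phi, 2 * np.pi) / (2 * np.pi) * self.params["a4"]  # steps
        # t = 1 corresponds to the first slot; t = 0 is one step before it
        clock0 = self.start_time.hour + self.start_time.minute / 60.0 - self.step_h
        return float(np.mod(clock0 + t_peak * self.step_h, 24.0))


def _design(t: np.ndarray, period_steps: float, with_trend: bool) -> np.ndarray:
    w = 2 * np.pi / period_steps
    cols = [np.cos(w * t), np.sin(w * t), np.ones_like(t)]
    if with_trend:
        cols.append(t)
    return np.column_stack(cols)


def harmonic_regression(
    y: np.ndarray, t: np.ndarray, period_steps: float, with_trend: bool = False
) -> np.ndarray:
    """Closed-form least squares at a FIXED period: (a1, a2, a3[, a5])."""
    X = _design(np.asarray(t, float), period_steps, with_trend)
    beta, *_ = np.linalg.lstsq(X, np.asarray(y, float), rcond=None)
    return beta


def _model(t: np.ndarray, a1, a2, a3, a4, a5=0.0) -> np.ndarray:
    w = 2 * np.pi / a4
    return a1 * np.cos(w * t) + a2 * np.sin(w * t) + a3 + a5 * t


def fit_sinusoid(
    series: CountSeries,
    with_trend: bool = False,
    init_period_h: float = 24.0,
    period_band_h: tuple[float, float] = (16.0, 32.0),
    fix_period_h: float | None = None,
) -> SinusoidFit:
    """Fit the free-period sinusoid to a 4-h count series.

    Missing slots are dropped but t keeps its calendar spacing (slot
    index on the full grid). Initialization: a4 at ``init_period_h``
    (24 h, the diel hypothesis), the linear coefficients from harmonic
    regression at that period. The period is box-bounded to
    ``period_band_h`` to keep the optimizer on the diel branch and off
    tidal harmonics; a solution pinned at a band edge is flagged.

    ``fix_period_h`` switches to pure harmonic regression at that
    period (used for oracle comparisons and fast scans); a4 then has
    zero-width uncertainty by construction and its se/p are NaN.

    Non-convergence never raises: the result carries
    ``converged=False`` and the optimizer message.
    """
    obs = series.data
    mask = obs.notna().values
    n = int(mask.sum())
    k = 5 if with_trend else 4
    if fix_period_h is None and n < 8:
        raise ValueError(f"need >= 8 non-missing slots, got {n}")
    t_all = np.arange(1, len(obs) + 1, dtype=float)
    t = t_all[mask]
    y = obs.values[mask]
    step_h = series.interval_h

    names = ["a1", "a2", "a3", "a4"] + (["a5"] if with_trend else [])

    if fix_period_h is not None:
        p_steps = fix_period_h / step_h
        beta = harmonic_regression(y, t, p_steps, with_trend)
        X = _design(t, p_steps, with_trend)
        fitted_vals = X @ beta
        resid = y - fitted_vals
        k_lin = X.shape[1]
        dof = n - k_lin
        sse = float(resid @ resid)
        s2 = sse / dof if dof > 0 else np.nan
        cov = s2 * np.linalg.pinv(X.T @ X)
        se_lin = np.sqrt(np.diag(cov))
        lin_names = ["a1", "a2", "a3"] + (["a5"] if with_trend else [])
        params = dict(zip(lin_names, map(float, beta)))
        params["a4"] = float(p_steps)
        se = dict(zip(lin_names, map(float, se_lin)))
        se["a4"] = float("nan")
        return _assemble(
            series, params, se, names, step_h, n, dof, sse, True, False,
            fitted_vals, resid, t, obs, t_all, mask, with_trend, "fixed period",
        )

    band = (period_band_h[0] / step_h, period_band_h[1] / step_h)
    if not (band[0] <= init_period_h / step_h <= band[1]):
        raise ValueError("init_period_h outside the period search band")

    p0_steps = init_period_h / step_h
    beta0 = harmonic_regression(y, t, p0_steps, with_trend)
    if with_trend:
        x0 = [beta0[0], beta0[1], beta0[2], p0_steps, beta0[3]]
        lb = [-np.inf, -np.inf, -np.inf, band[0], -np.inf]
        ub = [np.inf, np.inf, np.inf, band[1], np.inf]
    else:
        x0 = [beta0[0], beta0[1], beta0[2], p0_steps]
        lb = [-np.inf, -np.inf, -np.inf, band[0]]
        ub = [np.inf, np.inf, np.inf, band[1]]

    def resid_fn(p):
        return _model(t, *p) - y

    sol = optimize.least_squares(
        resid_fn, x0, bounds=(lb, ub), method="trf",
        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=5000,
    )
    params_vec = sol.x
    resid = -sol.fun  # y - model
    fitted_vals = y - resid
    sse = float(resid @ resid)
    dof = n - k
    s2 = sse / dof if dof > 0 else np.nan

    J = sol.jac
    JtJ = J.T @ J
    try:
        cov = s2 * np.linalg.inv(JtJ)
        se_vec = np.sqrt(np.clip(np.diag(cov), 0, None))
        singular = False
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
        se_vec = np.full(k, np.nan)
        singular = True

    pinned = bool(
        params_vec[3] <= band[0] + 1e-6 or params_vec[3] >= band[1] - 1e-6
    )
    if pinned:
        warnings.warn(
            f"fitted period pinned at search-band edge "
            f"({params_vec[3] * step_h:.2f} h)", stacklevel=2,
        )
    converged = bool(sol.success) and not singular

    params = dict(zip(names, map(float, params_vec)))
    se = dict(zip(names, map(float, se_vec)))
    return _assemble(
        series, params, se, names, step_h, n, dof, sse, converged, pinned,
        fitted_vals, resid, t, obs, t_all, mask, with_trend, sol.message,
    )


def _assemble(
    series, params, se, names, step_h, n, dof, sse, converged, pinned,
    fitted_vals, resid, t, obs, t_all, mask, with_trend, message,
) -> SinusoidFit:
    tvalues, pvalues = {}, {}
    for name in names:
        s = se.get(name, float("nan"))
        if np.isfinite(s) and s > 0 and dof > 0:
            tv = params[name] / s
            tvalues[name] = float(tv)
            pvalues[name] = float(2 * stats.t.sf(abs(tv), dof))
        elif np.isfinite(s) and s == 0 and params[name] != 0:
            tvalues[name] = float("inf")
            pvalues[name] = 0.0
        else:
            tvalues[name] = float("nan")
            pvalues[name] = float("nan")
    fitted = pd.Series(np.nan, index=obs.index)
    residuals = pd.Series(np.nan, index=obs.index)
    fitted.iloc[np.flatnonzero(mask)] = fitted_vals
    residuals.iloc[np.flatnonzero(mask)] = resid
    return SinusoidFit(
        taxon=series.taxon, params=params, se=se, tvalues=tvalues,
        pvalues=pvalues, step_h=step_h, n=n, dof=dof, sse=sse,
        converged=converged, period_pinned=pinned, fitted=fitted,
        residuals=residuals, t_index=t, with_trend=with_trend,
        start_time=series.timestamps[0], message=str(message),
    )


def period_significance(fit: SinusoidFit) -> float:
    """Two-sided Wald p-value for the period coefficient a4.

    t = a4 / se(a4) on n − k residual degrees of freedom. Undefined
    (NaN) when the covariance was singular or the fit did not converge.
    """
    if not fit.converged:
        warnings.warn("period p-value from a non-converged fit is undefined",
                      stacklevel=2)
        return float("nan")
    return fit.pvalues["a4"]


@dataclass
class ResidualDiagnostics:
    """Plotting-ready residual summaries (residual-vs-fitted pairs and
    a residual histogram)."""

    fitted: np.ndarray
    residuals: np.ndarray
    hist_counts: np.ndarray
    hist_edges: np.ndarray


def residual_diagnostics(fit: SinusoidFit, bins: int = 10) -> ResidualDiagnostics:
    """Residual-vs-fitted pairs plus a residual histogram whose counts
    sum to the number of residuals."""
    resid = fit.residuals.dropna().values
    fitted = fit.fitted.dropna().values
    # numerically-perfect fits collapse to a single bin
    if np.ptp(resid) <= 1e-10 * max(1.0, float(np.max(np.abs(fitted)))):
        counts, edges = np.array([len(resid)]), np.array([resid[0] - 0.5, resid[0] + 0.5])
    else:
        counts, edges = np.histogram(resid, bins=bins)
    return ResidualDiagnostics(
        fitted=fitted, residuals=resid, hist_counts=counts, hist_edges=edges
    )


def fit_table(fits: list[SinusoidFit], labels: list[str] | None = None) -> pd.DataFrame:
    """Flat summary table, one row per fit: coefficients, standard
    errors, p-values and the period in hours."""
    rows = []
    for i, fit in enumerate(fits):
        row = {
            "label": labels[i] if labels else fit.taxon,
            "taxon": fit.taxon,
            "n": fit.n,
            "period_h": fit.period_h,
            "period_se_h": fit.period_se_h,
            "period_p": fit.pvalues["a4"],
            "amplitude": fit.amplitude,
            "acrophase_h": fit.acrophase_h,
            "converged": fit.converged,
            "period_pinned": fit.period_pinned,
        }
        for name, val in fit.params.items():
            row[name] = val
            row[f"se_{name}"] = fit.se[name]
            row[f"p_{name}"] = fit.pvalues[name]
        rows.append(row)
    return pd.DataFrame(rows)
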