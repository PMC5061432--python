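"""Lagged biology-environment association: CCF and RDA.

Cross-correlation uses the standard time-series sample CCF — overall
means and (divisor-n) standard deviations held fixed across lags —
which is the convention under which ±z_{1−α/2}/√n is the white-noise
significance band. Only non-negative lags (environment leading
biology) are computed: animal abundance cannot drive the oceanography,
so negative lags are physically meaningless here. Both the α = 0.05
and α = 0.10 bands are carried, since weak couplings can be
significant only at the laxer level.

Redundancy analysis (RDA) is the constrained ordination of a species
matrix on z-scored environmental predictors: multivariate linear
regression followed by an eigendecomposition (SVD) of the fitted
values. Species and site scores follow the correlation-biplot
(scaling 2) convention; environmental biplot scores are the Pearson
correlations of each predictor with each axis's constrained site
scores, hence always in [−1, 1]. Axis signs (arbitrary in any
eigendecomposition) are canonicalized by forcing the predictor with
the largest |biplot score| positive on each axis. The biological
matrix is lagged (default 12 h) before ordination, so the RDA reads
"environment at t against biology at t + lag".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .series import CountSeries, EnvSeries

__all__ = [
    "CCFResult",
    "RDAResult",
    "cross_correlation",
    "ccf_critical_value",
    "lag_series",
    "rda_fit",
    "rda_report",
]


@dataclass
class CCFResult:
    """Positive-lag cross-correlation of one (environment, taxon) pair."""

    env_variable: str
    taxon: str
    lags_h: np.ndarray
    ccf: np.ndarray
    n: int
    crit_05: float
    crit_10: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag_h": self.lags_h,
                "ccf": self.ccf,
                "crit05": self.crit_05,
                "crit10": self.crit_10,
            }
        )

    @property
    def argmax_lag_h(self) -> float:
        return float(self.lags_h[np.nanargmax(self.ccf)])


def ccf_critical_value(n: int, alpha: float = 0.05) -> float:
    """White-noise CCF significance bound z_{1−α/2}/√n.

    Rounding (2 decimals) is a display concern only; the full-precision
    value is returned.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    return float(stats.norm.ppf(1 - alpha / 2) / np.sqrt(n))


def cross_correlation(
    env: EnvSeries,
    bio: CountSeries,
    max_lag_steps: int = 6,
) -> CCFResult:
    """Sample CCF of environment (leading) against biology for lags
    k = 0..max_lag_steps (reported in hours, k × step).

    ccf(k) = Σ_t (x_t − x̄)(y_{t+k} − ȳ) / (n · s_x · s_y) over the
    common grid, with x̄, ȳ, s_x, s_y the overall (lag-independent)
    moments of the aligned series and divisor-n standard deviations —
    the estimator whose lag-0 value is exactly the Pearson correlation.
    Pairs with a missing member are dropped from the lag-k sum.
    """
    if env.interval_h != bio.interval_h:
        raise ValueError("environment and biology must share the sampling interval")
    step_h = bio.interval_h
    joint = pd.DataFrame({"x": env.data, "y": bio.data}).dropna()
    n = len(joint)
    if n - max_lag_steps < 10:
        raise ValueError(
            f"need >= 10 aligned pairs at the maximum lag; have {n} pairs "
            f"for max lag {max_lag_steps} steps"
        )
    x = joint["x"].values
    y = joint["y"].values
    sx = float(np.std(x, ddof=0))
    sy = float(np.std(y, ddof=0))
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance input series")
    xc = x - x.mean()
    yc = y - y.mean()
    ccf = np.empty(max_lag_steps + 1)
    for k in range(max_lag_steps + 1):
        if k == 0:
            ccf[k] = np.sum(xc * yc) / (n * sx * sy)
        else:
            ccf[k] = np.sum(xc[:-k] * yc[k:]) / (n * sx * sy)
    return CCFResult(
        env_variable=env.variable,
        taxon=bio.taxon,
        lags_h=np.arange(max_lag_steps + 1) * step_h,
        ccf=ccf,
        n=n,
        crit_05=ccf_critical_value(n, 0.05),
        crit_10=ccf_critical_value(n, 0.10),
    )


def lag_series(bio: CountSeries, lag_h: float) -> CountSeries:
    """Re-index biology so that its value observed at t + lag aligns
    with environment at t.

    The lag must sit on the 4-h grid. Composition holds:
    lagging 4 h twice equals lagging 8 h once.
    """
    steps = lag_h / bio.interval_h
    if abs(steps - round(steps)) > 1e-9:
        raise ValueError(
            f"lag {lag_h} h is not a multiple of the {bio.interval_h}-h grid"
        )
    shifted = pd.Series(
        bio.data.values, index=bio.data.index - pd.Timedelta(hours=lag_h)
    )
    return CountSeries(taxon=bio.taxon, data=shifted, interval_h=bio.interval_h)


@dataclass
class RDAResult:
    """Constrained-ordination result.

    ``eigenvalues`` are the constrained-axis variances (non-increasing);
    ``proportion_explained`` divides them by the TOTAL response
    variance, so their sum is the fraction of community variance the
    predictors explain. Scores are DataFrames indexed by site / taxon /
    predictor with columns RDA1, RDA2, ...
    """

    eigenvalues: np.ndarray
    total_variance: float
    proportion_explained: np.ndarray
    site_scores: pd.DataFrame
    species_scores: pd.DataFrame
    biplot_scores: pd.DataFrame
    lag_h: float
    dropped_predictors: list[str]

    @property
    def constrained_variance(self) -> float:
        return float(np.sum(self.eigenvalues))


def _drop_collinear(X: pd.DataFrame, tol: float = 1e-10) -> tuple[pd.DataFrame, list[str]]:
    """Greedily drop predictors until the design has full column rank."""
    dropped: list[str] = []
    cols = list(X.columns)
    while cols:
        M = X[cols].values
        if np.linalg.matrix_rank(M, tol=tol * max(1.0, np.abs(M).max())) == len(cols):
            break
        # drop the predictor whose removal best restores conditioning
        _, sv, vt = np.linalg.svd(M, full_matrices=False)
        worst = cols[int(np.argmax(np.abs(vt[-1])))]
        cols.remove(worst)
        dropped.append(worst)
        warnings.warn(f"dropping collinear predictor {worst!r}", stacklevel=3)
    return X[cols], dropped


def rda_fit(
    bio_matrix: pd.DataFrame,
    env_matrix: pd.DataFrame,
    lag_h: float = 0.0,
    n_axes: int | None = None,
) -> RDAResult:
    """Redundancy analysis of a (slots × taxa) response matrix on a
    (slots × predictors) z-scored environmental matrix.

    Rows are matched on index and reduced to complete cases. The
    response is centered (not scaled: abundance units are shared across
    taxa). Fitted values Ŷ = X(XᵀX)⁻¹XᵀY are decomposed by SVD;
    eigenvalues are the fitted-value variances per axis (divisor n−1).

    Scaling-2 (correlation biplot) scores: species scores are the
    response loadings scaled by each axis's singular value — the
    weighting that makes angles between species vectors approximate
    their correlations; site scores are the unit-variance constrained
    coordinates; biplot scores are predictor-axis correlations.
    """
    joint = bio_matrix.join(env_matrix, how="inner", lsuffix="", rsuffix="_env")
    joint = joint.dropna()
    taxa = list(bio_matrix.columns)
    Y = joint[taxa].astype(float)
    Xdf = joint[[c for c in joint.columns if c not in taxa]].astype(float)
    n, q = Xdf.shape
    if n <= q + 1:
        raise ValueError(f"need more complete slots ({n}) than predictors ({q})")
    Xdf, dropped = _drop_collinear(Xdf)
    X = Xdf.values - Xdf.values.mean(axis=0)
    Yc = Y.values - Y.values.mean(axis=0)
    total_variance = float(np.sum(np.var(Yc, axis=0, ddof=1)))

    beta, *_ = np.linalg.lstsq(X, Yc, rcond=None)
    Yhat = X @ beta
    U, S, Vt = np.linalg.svd(Yhat, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-12)) if S.size and S[0] > 0 else 0
    max_axes = min(rank, X.shape[1], Yc.shape[1])
    if n_axes is None:
        n_axes = max_axes
    n_axes = min(n_axes, max_axes)
    if n_axes == 0:
        # response orthogonal to all predictors: no constrained structure
        axes: list[str] = []
        eig = np.zeros(0)
    else:
        axes = [f"RDA{i + 1}" for i in range(n_axes)]
        eig = (S[:n_axes] ** 2) / (n - 1)

    U = U[:, :n_axes]
    S_ax = S[:n_axes]
    V = Vt[:n_axes].T

    # site scores: unit-variance constrained coordinates (scaling 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        site = U * np.sqrt(n - 1)
    # species scores: loadings weighted by the axis singular value
    species = V * (S_ax / np.sqrt(n - 1))
    # biplot scores: predictor-axis correlations
    biplot = np.zeros((X.shape[1], n_axes))
    for j in range(X.shape[1]):
        for a in range(n_axes):
            sd_x = np.std(X[:, j], ddof=0)
            sd_u = np.std(U[:, a], ddof=0)
            if sd_x > 0 and sd_u > 0:
                biplot[j, a] = np.corrcoef(X[:, j], U[:, a])[0, 1]

    # canonicalize axis signs: largest-|loading| predictor positive
    for a in range(n_axes):
        if biplot.shape[0] == 0:
            break
        lead = int(np.argmax(np.abs(biplot[:, a])))
        if biplot[lead, a] < 0:
            biplot[:, a] *= -1
            site[:, a] *= -1
            species[:, a] *= -1

    return RDAResult(
        eigenvalues=eig,
        total_variance=total_variance,
        proportion_explained=(eig / total_variance if total_variance > 0 else eig * 0),
        site_scores=pd.DataFrame(site, index=joint.index, columns=axes),
        species_scores=pd.DataFrame(species, index=taxa, columns=axes),
        biplot_scores=pd.DataFrame(biplot, index=list(Xdf.columns), columns=axes),
        lag_h=lag_h,
        dropped_predictors=dropped,
    )


def rda_report(res: RDAResult, n_axes: int = 2) -> pd.DataFrame:
    """Flat score table (taxa then predictors) on the first axes."""
    axes = list(res.species_scores.columns[:n_axes])
    rows = []
    for taxon, row in res.species_scores.iterrows():
        rows.append({"entity": taxon, "type": "species",
                     **{a: row[a] for a in axes}})
    for var, row in res.biplot_scores.iterrows():
        rows.append({"entity": var, "type": "env",
                     **{a: row[a] for a in axes}})
    return pd.DataFrame(rows)
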