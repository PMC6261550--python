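"""Spatial regression: OLS baseline, LM diagnostics, ML lag/error models.

The modelling sequence mirrors the classical spatial-econometrics workflow
for areal health indicators:

1. OLS, ``y = alpha + X beta + eps``, assuming i.i.d. disturbances;
2. Moran's I on the OLS residuals plus Lagrange-multiplier score tests
   (LM-lag, LM-error and their robust variants) to detect which form of
   spatial dependence the residuals carry;
3. the spatial lag model (SLM), ``y = rho W y + X beta + eps``, and the
   spatial error model (SEM), ``y = X beta + u, u = lambda W u + zeta``,
   both estimated by maximum likelihood with the log-Jacobian
   ``ln|I - rho W|`` evaluated through the eigenvalues of the
   row-standardized weight matrix;
4. AIC comparison to select the final model.

Likelihoods are concentrated: for a candidate spatial parameter the
regression coefficients and the error variance have closed forms, leaving a
one-dimensional bounded (Brent) search over the open interval
``(1/omega_min, 1/omega_max)`` defined by the extreme eigenvalues of W.
Standard errors come from the numeric Hessian of the full log-likelihood at
the optimum.

AIC uses k = number of regression coefficients (intercept included) plus
one for the spatial parameter; the error variance is excluded consistently
across all three models, so only relative comparisons are meaningful —
which is all model selection needs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.sparse.linalg import spsolve

from .esda import MoranResult, moran_global
from .geoweights import SpatialWeights

__all__ = [
    "OLSResult",
    "DiagnosticsResult",
    "SpatialModelResult",
    "ModelComparison",
    "fit_ols",
    "residual_moran",
    "lm_diagnostics",
    "fit_spatial_lag",
    "fit_spatial_error",
    "compare_models",
]

# feasible interval for rho/lambda is shrunk by this margin at both ends
_INTERVAL_MARGIN = 1e-5
_BRENT_XATOL = 1e-8
_HESS_STEP = 1e-5


class RankDeficiencyError(ValueError):
    """Design matrix is collinear; names the offending columns."""


class ConvergenceError(RuntimeError):
    """Optimizer failed; carries the last iterate."""

    def __init__(self, msg: str, last: float | None = None):
        super().__init__(msg)
        self.last = last


@dataclass
class OLSResult:
    terms: list[str]  # "intercept" + predictor names
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    residuals: np.ndarray
    fitted: np.ndarray
    sigma2: float  # ML variance e'e/n
    r2: float
    adj_r2: float
    loglik: float
    aic: float
    n: int
    k: int  # number of coefficients incl. intercept
    X: np.ndarray = field(repr=False, default=None)  # design incl. intercept
    y: np.ndarray = field(repr=False, default=None)


@dataclass
class DiagnosticsResult:
    residual_moran: MoranResult
    lm_lag: float
    lm_lag_p: float
    lm_error: float
    lm_error_p: float
    robust_lm_lag: float
    robust_lm_lag_p: float
    robust_lm_error: float
    robust_lm_error_p: float


@dataclass
class SpatialModelResult:
    kind: str  # "lag" or "error"
    spatial_param: float  # rho or lambda
    spatial_se: float
    spatial_z: float
    spatial_p: float
    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    sigma2: float
    loglik: float
    aic: float
    pseudo_r2: float
    n: int
    k: int  # coefficients + 1 spatial parameter
    interval: tuple[float, float]
    iterations: int
    converged: bool
    fitted: np.ndarray = field(repr=False, default=None)
    residuals: np.ndarray = field(repr=False, default=None)


@dataclass
class ModelComparison:
    aic: dict[str, float]
    fit_measure: dict[str, float]  # adjusted R2 (OLS) / pseudo R2 (spatial)
    selected: str


def _design(X, names: list[str] | None) -> tuple[np.ndarray, list[str]]:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < X.shape[1] and X.shape[0] == 1:
        X = X.T
    names = list(names) if names else [f"x{j + 1}" for j in range(X.shape[1])]
    if len(names) != X.shape[1]:
        raise ValueError("number of names does not match number of predictors")
    Xd = np.column_stack([np.ones(X.shape[0]), X])
    return Xd, ["intercept"] + names


def _check_rank(Xd: np.ndarray, terms: list[str]) -> None:
    rank = np.linalg.matrix_rank(Xd)
    if rank < Xd.shape[1]:
        # flag columns whose removal restores full rank
        bad = []
        for j in range(Xd.shape[1]):
            keep = [c for c in range(Xd.shape[1]) if c != j]
            if np.linalg.matrix_rank(Xd[:, keep]) == rank:
                bad.append(terms[j])
        raise RankDeficiencyError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_ols(y, X, names: list[str] | None = None) -> OLSResult:
    """Ordinary least squares with the Gaussian log-likelihood at the ML
    variance, so the AIC is comparable with the spatial models'."""
    y = np.asarray(y, dtype=float).ravel()
    Xd, terms = _design(X, names)
    n, k = Xd.shape
    if n <= k + 1:
        raise ValueError(f"n={n} too small for k={k} coefficients")
    _check_rank(Xd, terms)
    fit = sm.OLS(y, Xd).fit()
    resid = y - fit.fittedvalues
    sigma2 = float(resid @ resid / n)
    loglik = float(fit.llf)  # Gaussian log-likelihood at sigma2 = RSS/n
    return OLSResult(
        terms=terms,
        beta=np.asarray(fit.params),
        se=np.asarray(fit.bse),
        t=np.asarray(fit.tvalues),
        p=np.asarray(fit.pvalues),
        residuals=resid,
        fitted=np.asarray(fit.fittedvalues),
        sigma2=sigma2,
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        loglik=loglik,
        aic=2 * k - 2 * loglik,
        n=n,
        k=k,
        X=Xd,
        y=y,
    )


def residual_moran(
    ols: OLSResult, w: SpatialWeights, permutations: int = 999, seed: int | None = None
) -> MoranResult:
    """Moran's I of the OLS residuals — the spatial-endogeneity check that
    motivates moving from OLS to an autoregressive specification."""
    return moran_global(ols.residuals, w, permutations=permutations, seed=seed)


def lm_diagnostics(
    ols: OLSResult,
    w: SpatialWeights,
    permutations: int = 999,
    seed: int | None = None,
) -> DiagnosticsResult:
    """Lagrange-multiplier score tests for spatial lag and error dependence.

    Standard forms: with e the OLS residuals, sigma2 = e'e/n,
    ``T = tr(W'W + WW)`` and ``J = [(WXb)'M(WXb) + T sigma2] / sigma2``,

        LM_lag       = (e'Wy / sigma2)^2 / J
        LM_error     = (e'We / sigma2)^2 / T
        robust forms adjust each statistic for the other alternative.

    All four are compared to chi-square(1).
    """
    if w.standardized != "row":
        raise ValueError("LM diagnostics require row-standardized weights")
    if len(w.islands) == w.n:
        raise ValueError("all units are islands")
    e, Xd, y = ols.residuals, ols.X, ols.y
    n = ols.n
    W = w.to_sparse()
    Wd = W.toarray()
    sigma2 = ols.sigma2
    T = float(np.sum(Wd * Wd.T) + np.sum(Wd * Wd))
    d_rho = float(e @ (W @ y)) / sigma2
    d_lam = float(e @ (W @ e)) / sigma2
    WXb = W @ ols.fitted
    XtX_inv = np.linalg.inv(Xd.T @ Xd)
    MWXb = WXb - Xd @ (XtX_inv @ (Xd.T @ WXb))
    J = (float(WXb @ MWXb) + T * sigma2) / sigma2
    lm_lag = d_rho**2 / J
    lm_err = d_lam**2 / T
    r_lag = (d_rho - d_lam) ** 2 / (J - T)
    r_err = (d_lam - (T / J) * d_rho) ** 2 / (T - T**2 / J)
    chi2 = stats.chi2(1)
    rm = moran_global(e, w, permutations=permutations, seed=seed)
    return DiagnosticsResult(
        residual_moran=rm,
        lm_lag=float(lm_lag),
        lm_lag_p=float(chi2.sf(lm_lag)),
        lm_error=float(lm_err),
        lm_error_p=float(chi2.sf(lm_err)),
        robust_lm_lag=float(r_lag),
        robust_lm_lag_p=float(chi2.sf(r_lag)),
        robust_lm_error=float(r_err),
        robust_lm_error_p=float(chi2.sf(r_err)),
    )


def _prepare_spatial(y, X, w: SpatialWeights, names):
    y = np.asarray(y, dtype=float).ravel()
    Xd, terms = _design(X, names)
    if w.standardized != "row":
        raise ValueError("spatial models require row-standardized weights")
    if w.islands:
        warnings.warn(f"dropping {len(w.islands)} island unit(s) from the estimation set")
        keep = [u for u in w.ids if u not in set(w.islands)]
        mask = ~w.island_mask()
        y, Xd = y[mask], Xd[mask]
        w = w.subset(keep)
    _check_rank(Xd, terms)
    omega = w.eigenvalues()
    lo = 1.0 / omega.min() + _INTERVAL_MARGIN
    hi = 1.0 / omega.max() - _INTERVAL_MARGIN
    return y, Xd, terms, w, omega, (lo, hi)


def _log_jacobian(param: float, omega: np.ndarray) -> float:
    return float(np.sum(np.log(1.0 - param * omega)))


def _numeric_hessian(f, theta: np.ndarray) -> np.ndarray:
    """Central-difference Hessian with step 1e-5 * (1 + |theta_i|)."""
    m = theta.size
    h = _HESS_STEP * (1.0 + np.abs(theta))
    H = np.empty((m, m))
    for i in range(m):
        for j in range(i, m):
            ei = np.zeros(m)
            ej = np.zeros(m)
            ei[i], ej[j] = h[i], h[j]
            if i == j:
                H[i, i] = (f(theta + ei) - 2 * f(theta) + f(theta - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(theta + ei + ej) - f(theta + ei - ej) - f(theta - ei + ej) + f(theta - ei - ej)
                ) / (4 * h[i] * h[j])
    return H


def _wald(est: np.ndarray, cov: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = est / se
    p = 2 * stats.norm.sf(np.abs(z))
    return se, z, p


def fit_spatial_lag(y, X, w: SpatialWeights, names: list[str] | None = None) -> SpatialModelResult:
    """ML spatial lag model: y = rho W y + X beta + eps.

    The log-likelihood is concentrated over rho using the residuals of y and
    Wy on X; ``ln|I - rho W|`` comes from the eigenvalues of W.
    """
    y, Xd, terms, w, omega, (lo, hi) = _prepare_spatial(y, X, w, names)
    n, p = Xd.shape
    W = w.to_sparse()
    Wy = W @ y
    XtX_inv = np.linalg.inv(Xd.T @ Xd)
    b0 = XtX_inv @ (Xd.T @ y)
    bL = XtX_inv @ (Xd.T @ Wy)
    e0 = y - Xd @ b0
    eL = Wy - Xd @ bL
    const = -n / 2 * (np.log(2 * np.pi) + 1)

    def conc_negll(rho: float) -> float:
        u = e0 - rho * eL
        return -(const + _log_jacobian(rho, omega) - n / 2 * np.log(u @ u / n))

    res = optimize.minimize_scalar(conc_negll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": _BRENT_XATOL, "maxiter": 500})
    if not res.success:
        raise ConvergenceError(f"SLM likelihood search failed: {res.message}", last=float(res.x))
    rho = float(res.x)
    beta = b0 - rho * bL
    u = e0 - rho * eL
    sigma2 = float(u @ u / n)
    loglik = -float(res.fun)

    def full_ll(theta: np.ndarray) -> float:
        b, r, s2 = theta[:p], theta[p], theta[p + 1]
        if s2 <= 0 or not (1 / omega.min() < r < 1 / omega.max()):
            return -np.inf
        resid = y - r * Wy - Xd @ b
        return (
            _log_jacobian(r, omega)
            - n / 2 * np.log(2 * np.pi * s2)
            - float(resid @ resid) / (2 * s2)
        )

    theta = np.concatenate([beta, [rho, sigma2]])
    H = _numeric_hessian(lambda t: -full_ll(t), theta)
    cov = np.linalg.pinv(H)
    se_all, z_all, p_all = _wald(theta, cov)
    # reduced-form predictions: y_hat = (I - rho W)^-1 X beta
    A = sp.eye(n, format="csc") - rho * W.tocsc()
    fitted = spsolve(A, Xd @ beta)
    resid = y - fitted
    ssy = float(((y - y.mean()) ** 2).sum())
    pseudo_r2 = float(np.corrcoef(y, fitted)[0, 1] ** 2) if ssy > 0 else np.nan
    return SpatialModelResult(
        kind="lag",
        spatial_param=rho,
        spatial_se=float(se_all[p]),
        spatial_z=float(z_all[p]),
        spatial_p=float(p_all[p]),
        terms=terms,
        beta=beta,
        se=se_all[:p],
        z=z_all[:p],
        p=p_all[:p],
        sigma2=sigma2,
        loglik=loglik,
        aic=2 * (p + 1) - 2 * loglik,
        pseudo_r2=pseudo_r2,
        n=n,
        k=p + 1,
        interval=(lo, hi),
        iterations=int(res.nit),
        converged=bool(res.success),
        fitted=fitted,
        residuals=resid,
    )


def fit_spatial_error(y, X, w: SpatialWeights, names: list[str] | None = None) -> SpatialModelResult:
    """ML spatial error model: y = X beta + u, u = lambda W u + zeta.

    For a candidate lambda the model is a spatially filtered (GLS)
    regression of ``y - lambda W y`` on ``X - lambda W X``; the concentrated
    log-likelihood is searched over lambda with Brent.
    """
    y, Xd, terms, w, omega, (lo, hi) = _prepare_spatial(y, X, w, names)
    n, p = Xd.shape
    W = w.to_sparse()
    Wy = W @ y
    WX = W @ Xd
    const = -n / 2 * (np.log(2 * np.pi) + 1)

    def filtered_beta(lam: float) -> tuple[np.ndarray, np.ndarray]:
        ys = y - lam * Wy
        Xs = Xd - lam * WX
        b, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        return b, ys - Xs @ b

    def conc_negll(lam: float) -> float:
        _, u = filtered_beta(lam)
        return -(const + _log_jacobian(lam, omega) - n / 2 * np.log(u @ u / n))

    res = optimize.minimize_scalar(conc_negll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": _BRENT_XATOL, "maxiter": 500})
    if not res.success:
        raise ConvergenceError(f"SEM likelihood search failed: {res.message}", last=float(res.x))
    lam = float(res.x)
    beta, u = filtered_beta(lam)
    sigma2 = float(u @ u / n)
    loglik = -float(res.fun)

    def full_ll(theta: np.ndarray) -> float:
        b, l, s2 = theta[:p], theta[p], theta[p + 1]
        if s2 <= 0 or not (1 / omega.min() < l < 1 / omega.max()):
            return -np.inf
        r = y - Xd @ b
        zeta = r - l * (W @ r)
        return (
            _log_jacobian(l, omega)
            - n / 2 * np.log(2 * np.pi * s2)
            - float(zeta @ zeta) / (2 * s2)
        )

    theta = np.concatenate([beta, [lam, sigma2]])
    H = _numeric_hessian(lambda t: -full_ll(t), theta)
    cov = np.linalg.pinv(H)
    se_all, z_all, p_all = _wald(theta, cov)
    fitted = Xd @ beta
    resid = y - fitted
    ssy = float(((y - y.mean()) ** 2).sum())
    pseudo_r2 = float(np.corrcoef(y, fitted)[0, 1] ** 2) if ssy > 0 else np.nan
    return SpatialModelResult(
        kind="error",
        spatial_param=lam,
        spatial_se=float(se_all[p]),
        spatial_z=float(z_all[p]),
        spatial_p=float(p_all[p]),
        terms=terms,
        beta=beta,
        se=se_all[:p],
        z=z_all[:p],
        p=p_all[:p],
        sigma2=sigma2,
        loglik=loglik,
        aic=2 * (p + 1) - 2 * loglik,
        pseudo_r2=pseudo_r2,
        n=n,
        k=p + 1,
        interval=(lo, hi),
        iterations=int(res.nit),
        converged=bool(res.success),
        fitted=fitted,
        residuals=resid,
    )


def compare_models(
    ols: OLSResult, slm: SpatialModelResult, sem: SpatialModelResult
) -> ModelComparison:
    """AIC table and argmin selection across OLS, SLM and SEM.

    Ties are broken toward the simpler model in the order OLS, SLM, SEM.
    The fit measure reported alongside is the adjusted R2 for OLS and the
    pseudo R2 (squared correlation of y and y-hat) for the spatial models.
    """
    if not (ols.n == slm.n == sem.n):
        raise ValueError(f"models fitted on different n: {ols.n}, {slm.n}, {sem.n}")
    aic = {"OLS": ols.aic, "SLM": slm.aic, "SEM": sem.aic}
    fit = {"OLS": ols.adj_r2, "SLM": slm.pseudo_r2, "SEM": sem.pseudo_r2}
    selected = min(aic, key=lambda m: (aic[m], ["OLS", "SLM", "SEM"].index(m)))
    return ModelComparison(aic=aic, fit_measure=fit, selected=selected)
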