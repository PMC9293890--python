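"""Log-scale linear mixed model with AR(1) within-group residual correlation.

Model, per province block i:

    y_i = X_i beta + Z_i b_i + eps_i,
    b_i ~ N(0, G),          2x2 (random intercept, random slope per day)
    eps_i ~ N(0, sigma2 * R_i(rho)),   R_i[s, t] = rho ** |day_s - day_t|

The marginal covariance V_i = Z_i G Z_i' + sigma2 R_i is never formed
densely.  Each block is whitened with the bidiagonal AR(1) transform
(which maps R_i to the identity, including across day gaps), after which
V_i* = sigma2 I + B_i B_i' with B_i = W_i Z_i L and G = L L'; the Woodbury
identity and the matrix determinant lemma then give O(n) likelihood
evaluations per block.

Fitting maximizes the (restricted) likelihood over (atanh rho, log sigma2,
log-Cholesky of G) with beta profiled out by GLS at each step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import FitError, ValidationError

__all__ = [
    "VarianceComponents",
    "FitResult",
    "ResidualDiagnostics",
    "ar1_corr",
    "marginal_loglik",
    "fit",
    "information_criteria",
    "residual_diagnostics",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class VarianceComponents:
    """sigma2: marginal residual variance; rho: AR(1) parameter;
    G: 2x2 PSD covariance of (random intercept, random slope)."""

    sigma2: float
    rho: float
    G: np.ndarray

    def __post_init__(self) -> None:
        if not self.sigma2 > 0:
            raise ValidationError(f"sigma2 must be > 0, got {self.sigma2}")
        if not abs(self.rho) < 1:
            raise ValidationError(f"|rho| must be < 1, got {self.rho}")
        G = np.asarray(self.G, dtype=float)
        if G.shape != (2, 2) or not np.allclose(G, G.T):
            raise ValidationError("G must be a symmetric 2x2 matrix")
        if np.min(np.linalg.eigvalsh(G)) < -1e-10:
            raise ValidationError("G must be positive semidefinite")
        object.__setattr__(self, "G", G)

    def chol_G(self) -> np.ndarray:
        """Lower-triangular factor L with G = L L' (PSD-safe)."""
        G = self.G + 1e-14 * np.eye(2)
        try:
            return np.linalg.cholesky(G)
        except np.linalg.LinAlgError:
            w, v = np.linalg.eigh(self.G)
            w = np.clip(w, 0.0, None)
            return v @ np.diag(np.sqrt(w))


@dataclass
class FitResult:
    beta: pd.Series
    cov_beta: pd.DataFrame
    vc: VarianceComponents
    loglik: float
    aic: float
    bic: float
    n_obs: int
    n_params: int
    converged: bool
    method: str = "ml"
    hdi_mode: str = "categorical"
    optimizer_trace: dict = field(default_factory=dict)

    def se(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.cov_beta.to_numpy())), index=self.beta.index
        )


def ar1_corr(n: int, rho: float, gaps: Sequence[float] | None = None) -> np.ndarray:
    """Dense AR(1) correlation matrix; entry (s, t) = rho ** |day_s - day_t|.

    ``gaps`` gives the day offset of each observation (defaults to 0..n-1).
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if not abs(rho) < 1:
        raise ValidationError(f"|rho| must be < 1, got {rho}")
    days = np.arange(n, dtype=float) if gaps is None else np.asarray(gaps, dtype=float)
    if days.shape != (n,):
        raise ValidationError(f"gaps must have length {n}")
    lag = np.abs(days[:, None] - days[None, :])
    if rho == 0.0:
        return np.eye(n)
    return np.sign(rho) ** lag * np.abs(rho) ** lag if rho < 0 else rho**lag


def _block_slices(groups: np.ndarray) -> list[np.ndarray]:
    """Row indices per group, in first-appearance order."""
    groups = np.asarray(groups)
    out = []
    for g in pd.unique(groups):
        out.append(np.flatnonzero(groups == g))
    return out


def _whiten(mat: np.ndarray, rho: float, deltas: np.ndarray) -> tuple[np.ndarray, float]:
    """Apply the AR(1) whitening transform row-wise.

    ``deltas[k]`` is the day gap between row k and row k-1 (deltas[0]
    unused). Returns the whitened copy and log|R|.
    """
    out = mat.astype(float).copy()
    if len(out) <= 1 or rho == 0.0:
        return out, 0.0
    phi = np.sign(rho) ** deltas[1:] * np.abs(rho) ** deltas[1:] if rho < 0 else rho ** deltas[1:]
    denom = np.sqrt(1.0 - phi**2)
    out[1:] = (out[1:] - phi[:, None] * out[:-1]) / denom[:, None]
    return out, float(np.sum(np.log1p(-(phi**2))))


def _suffstats(
    X: np.ndarray,
    Z: np.ndarray,
    y: np.ndarray,
    blocks: list[np.ndarray],
    times: np.ndarray,
    sigma2: float,
    rho: float,
    L: np.ndarray,
):
    """Accumulate A = X'V^-1 X, b = X'V^-1 y, q = y'V^-1 y and log|V|."""
    p = X.shape[1]
    A = np.zeros((p, p))
    bvec = np.zeros(p)
    q = 0.0
    logdet = 0.0
    for idx in blocks:
        n = len(idx)
        stack = np.column_stack([y[idx], X[idx]])
        deltas = np.diff(times[idx], prepend=times[idx][0])
        stackw, logdetR = _whiten(stack, rho, deltas)
        Zw, _ = _whiten(Z[idx], rho, deltas)
        B = Zw @ L  # n x 2
        M = sigma2 * np.eye(2) + B.T @ B
        BtS = B.T @ stackw  # 2 x (1+p)
        sol = np.linalg.solve(M, BtS)
        # S' V^-1 S = (S'S - (B'S)' M^-1 (B'S)) / sigma2
        StVS = (stackw.T @ stackw - BtS.T @ sol) / sigma2
        q += StVS[0, 0]
        bvec += StVS[0, 1:]
        A += StVS[1:, 1:]
        sign, logdetM = np.linalg.slogdet(M)
        if sign <= 0:
            raise FitError("non-positive-definite marginal covariance encountered")
        logdet += n * np.log(sigma2) + logdetM - 2.0 * np.log(sigma2) + logdetR
    return A, bvec, q, logdet


def marginal_loglik(
    beta: np.ndarray,
    vc: VarianceComponents,
    X: np.ndarray,
    Z: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    times: np.ndarray | None = None,
) -> float:
    """Marginal log-likelihood at fixed parameters (sum over province
    blocks of MVN log-densities with covariance V_i = Z_i G Z_i' + sigma2 R_i)."""
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if times is None:
        times = _default_times(groups)
    blocks = _block_slices(np.asarray(groups))
    r = y - X @ beta
    L = vc.chol_G()
    # reuse _suffstats with the residual in place of y and an empty X
    A, b, q, logdet = _suffstats(
        np.zeros((len(y), 0)), Z, r, blocks, np.asarray(times, float), vc.sigma2, vc.rho, L
    )
    n = len(y)
    return -0.5 * (n * _LOG2PI + logdet + q)


def _default_times(groups) -> np.ndarray:
    """Consecutive within-block day offsets when none are supplied."""
    groups = np.asarray(groups)
    times = np.empty(len(groups), dtype=float)
    for idx in _block_slices(groups):
        times[idx] = np.arange(len(idx), dtype=float)
    return times


def information_criteria(loglik: float, n_params: int, n_obs: int) -> tuple[float, float]:
    if n_obs < 1:
        raise ValidationError("n_obs must be >= 1")
    aic = -2.0 * loglik + 2.0 * n_params
    bic = -2.0 * loglik + n_params * np.log(n_obs)
    return float(aic), float(bic)


def _unpack(theta: np.ndarray, estimate_rho: bool, estimate_G: bool):
    k = 0
    if estimate_rho:
        # clamp so tanh never saturates to exactly +-1 in floating point
        rho = float(np.tanh(np.clip(theta[k], -6.0, 6.0)))
        k += 1
    else:
        rho = 0.0
    sigma2 = float(np.exp(np.clip(theta[k], -40.0, 40.0)))
    k += 1
    if estimate_G:
        l11 = np.exp(np.clip(theta[k], -40.0, 40.0))
        l21 = theta[k + 1]
        l22 = np.exp(np.clip(theta[k + 2], -40.0, 40.0))
        L = np.array([[l11, 0.0], [l21, l22]])
    else:
        L = np.zeros((2, 2))
    return rho, sigma2, L


def _profiled_nll(
    theta, X, Z, y, blocks, times, estimate_rho, estimate_G, reml
) -> float:
    rho, sigma2, L = _unpack(theta, estimate_rho, estimate_G)
    try:
        A, b, q, logdet = _suffstats(X, Z, y, blocks, times, sigma2, rho, L)
        cho = np.linalg.cholesky(A)
        beta = np.linalg.solve(A, b)
    except (np.linalg.LinAlgError, FitError):
        return 1e12
    quad = q - b @ beta
    n, p = X.shape
    ll = -0.5 * (n * _LOG2PI + logdet + quad)
    if reml:
        ll += -float(np.sum(np.log(np.diag(cho)))) + 0.5 * p * _LOG2PI
    if not np.isfinite(ll):
        return 1e12
    return -ll


def fit(
    X,
    Z,
    y,
    groups,
    method: str = "ml",
    *,
    times: np.ndarray | None = None,
    estimate_rho: bool = True,
    estimate_G: bool = True,
    n_starts: int = 3,
    maxiter: int = 500,
    hdi_mode: str = "categorical",
) -> FitResult:
    """Maximum-likelihood fit of the AR(1) linear mixed model.

    Parameters
    ----------
    X : fixed-effect design (DataFrame for named coefficients, or array).
    Z : per-row random-effect design with columns (intercept, day offset).
    y : response on the log scale.
    groups : province label per row; rows of one province must be
        date-ordered.
    method : ``ml`` (default, valid for AIC/BIC comparison of fixed-effect
        structures) or ``reml``.
    times : day offset per row; consecutive days assumed when omitted
        (gaps enter the AR(1) correlation as rho ** gap).
    estimate_rho, estimate_G : fix rho=0 / G=0 instead of estimating.
    n_starts : number of optimizer starting points.
    """
    if method not in ("ml", "reml"):
        raise ValidationError(f"method must be 'ml' or 'reml', got {method!r}")
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{j}" for j in range(np.asarray(X).shape[1])
    ]
    Xa = np.asarray(X, dtype=float)
    Za = np.asarray(Z, dtype=float)
    ya = np.asarray(y, dtype=float)
    ga = np.asarray(groups)
    n, p = Xa.shape

    rank = np.linalg.matrix_rank(Xa)
    if rank < p:
        # name a maximal set of columns dependent on the preceding ones
        _, R = np.linalg.qr(Xa)
        dep = [names[j] for j in range(p) if abs(R[j, j]) < 1e-8 * abs(R[0, 0])]
        raise ValidationError(
            f"design matrix is rank deficient (rank {rank} < {p}); "
            f"suspect columns: {dep}"
        )
    blocks = _block_slices(ga)
    if estimate_G and len(blocks) < 2:
        raise ValidationError("random-effect estimation requires >= 2 provinces")
    ta = _default_times(ga) if times is None else np.asarray(times, dtype=float)

    # data-driven starting values from OLS residuals
    beta_ols, *_ = np.linalg.lstsq(Xa, ya, rcond=None)
    resid = ya - Xa @ beta_ols
    s2_0 = max(float(np.var(resid)), 1e-8)
    t_span = max(float(np.ptp(ta)), 1.0)
    sd0 = np.sqrt(s2_0)

    start_grid = [
        (0.3, 0.6 * s2_0, 0.5 * sd0, 0.05 * sd0 / t_span),
        (0.0, s2_0, 0.1 * sd0, 0.01 * sd0 / t_span),
        (0.8, 0.3 * s2_0, 1.0 * sd0, 0.2 * sd0 / t_span),
        (-0.3, s2_0, 0.3 * sd0, 0.1 * sd0 / t_span),
    ]
    starts = []
    for rho0, s20, l110, l220 in start_grid[: max(1, n_starts)]:
        th = []
        if estimate_rho:
            th.append(np.arctanh(rho0))
        th.append(np.log(s20))
        if estimate_G:
            th.extend([np.log(l110), 0.0, np.log(l220)])
        starts.append(np.array(th))

    args = (Xa, Za, ya, blocks, ta, estimate_rho, estimate_G, method == "reml")
    best = None
    trace = {"starts": []}
    for th0 in starts:
        res = optimize.minimize(
            _profiled_nll,
            th0,
            args=args,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-6},
        )
        trace["starts"].append(
            {"x0": th0.tolist(), "nll": float(res.fun), "success": bool(res.success)}
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None

    converged = bool(best.success)
    if not converged:
        # L-BFGS-B line searches can fail on the nearly-flat log-Cholesky
        # directions of G; polish with a derivative-free pass
        polish = optimize.minimize(
            _profiled_nll,
            best.x,
            args=args,
            method="Nelder-Mead",
            options={"maxiter": 4000, "fatol": 1e-7, "xatol": 1e-6},
        )
        trace["polish"] = {"nll": float(polish.fun), "success": bool(polish.success)}
        if polish.fun <= best.fun:
            best = polish
            converged = bool(polish.success)

    rho, sigma2, L = _unpack(best.x, estimate_rho, estimate_G)
    vc = VarianceComponents(sigma2=sigma2, rho=rho, G=L @ L.T)
    A, b, q, logdet = _suffstats(Xa, Za, ya, blocks, ta, sigma2, rho, L)
    beta = np.linalg.solve(A, b)
    cov_beta = np.linalg.inv(A)
    quad = q - b @ beta
    loglik = -0.5 * (n * _LOG2PI + logdet + quad)
    if method == "reml":
        sign, logdetA = np.linalg.slogdet(A)
        loglik += -0.5 * logdetA + 0.5 * p * _LOG2PI

    n_params = p + 1 + (1 if estimate_rho else 0) + (3 if estimate_G else 0)
    aic, bic = information_criteria(loglik, n_params, n)
    if not converged:
        warnings.warn("optimizer did not report convergence; result returned as-is")

    return FitResult(
        beta=pd.Series(beta, index=names),
        cov_beta=pd.DataFrame(cov_beta, index=names, columns=names),
        vc=vc,
        loglik=float(loglik),
        aic=aic,
        bic=bic,
        n_obs=n,
        n_params=n_params,
        converged=converged,
        method=method,
        hdi_mode=hdi_mode,
        optimizer_trace=trace,
    )


@dataclass
class ResidualDiagnostics:
    std_residuals: np.ndarray
    fitted: np.ndarray
    lag1_raw: float
    lag1_whitened: float
    skewness: float
    excess_kurtosis: float
    variance_slope: float
    variance_slope_z: float


def _lag1_acf(values: np.ndarray, groups: np.ndarray, times: np.ndarray) -> float:
    """Lag-1 autocorrelation over consecutive-day pairs within blocks."""
    a, b = [], []
    for idx in _block_slices(groups):
        v = values[idx]
        dt = np.diff(times[idx])
        ok = np.isclose(dt, 1.0)
        a.append(v[:-1][ok])
        b.append(v[1:][ok])
    a = np.concatenate(a)
    b = np.concatenate(b)
    if len(a) < 2:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def residual_diagnostics(fit_result: FitResult, X, Z, y, groups, times=None) -> ResidualDiagnostics:
    """Residual checks for the fitted model.

    Returns standardized marginal residuals, the lag-1 autocorrelation of
    conditional (BLUP-subtracted) residuals before and after AR(1)
    whitening at the fitted rho, moment-based normality statistics, and the
    slope of squared standardized residuals on fitted values (a
    heteroscedasticity probe) with its Wald z.
    """
    Xa = np.asarray(X, dtype=float)
    Za = np.asarray(Z, dtype=float)
    ya = np.asarray(y, dtype=float)
    ga = np.asarray(groups)
    ta = _default_times(ga) if times is None else np.asarray(times, dtype=float)

    vc = fit_result.vc
    L = vc.chol_G()
    beta = fit_result.beta.to_numpy()
    fitted = Xa @ beta
    r = ya - fitted

    # BLUPs and conditional residuals, per block via the whitened Woodbury solve
    e = np.empty_like(r)
    for idx in _block_slices(ga):
        deltas = np.diff(ta[idx], prepend=ta[idx][0])
        rw, _ = _whiten(r[idx][:, None], vc.rho, deltas)
        Zw, _ = _whiten(Za[idx], vc.rho, deltas)
        B = Zw @ L
        M = vc.sigma2 * np.eye(2) + B.T @ B
        Vinv_r = (rw[:, 0] - B @ np.linalg.solve(M, B.T @ rw[:, 0])) / vc.sigma2
        b_hat = L @ (B.T @ Vinv_r)
        e[idx] = r[idx] - Za[idx] @ b_hat

    marg_var = vc.sigma2 + np.einsum("ij,jk,ik->i", Za, vc.G, Za)
    std_resid = r / np.sqrt(marg_var)

    lag1_raw = _lag1_acf(e, ga, ta)
    ew = np.empty_like(e)
    for idx in _block_slices(ga):
        deltas = np.diff(ta[idx], prepend=ta[idx][0])
        w, _ = _whiten(e[idx][:, None], vc.rho, deltas)
        ew[idx] = w[:, 0]
    lag1_white = _lag1_acf(ew, ga, ta)

    skew = float(stats.skew(std_resid))
    kurt = float(stats.kurtosis(std_resid))

    # OLS of squared standardized residuals on centered fitted values
    f = fitted - fitted.mean()
    denom = float(f @ f)
    if denom > 0:
        slope = float(f @ (std_resid**2)) / denom
        resid2 = std_resid**2 - (std_resid**2).mean() - slope * f
        se = np.sqrt(float(resid2 @ resid2) / max(len(f) - 2, 1) / denom)
        z = slope / se if se > 0 else float("inf")
    else:
        slope, z = 0.0, 0.0

    return ResidualDiagnostics(
        std_residuals=std_resid,
        fitted=fitted,
        lag1_raw=lag1_raw,
        lag1_whitened=lag1_white,
        skewness=skew,
        excess_kurtosis=kurt,
        variance_slope=slope,
        variance_slope_z=float(z),
    )
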