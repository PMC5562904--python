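"""Reduced-rank regression for the vector error correction model (VECM).

The model fitted to an unwrapped phase series phi_1, ..., phi_N is

    Delta phi_n = P phi_{n-1} + mu + eps_n,      eps_n ~ N(0, Omega),

with P = alpha beta' of reduced rank r.  Estimation follows the classical
likelihood procedure: concentrate out the constant (demeaning), form the
product-moment matrices S00, S01, S11, and solve the generalized eigenvalue
problem

    det(lambda S11 - S10 S00^{-1} S01) = 0,

whose ordered eigenvalues 1 > lambda_1 >= ... >= lambda_p >= 0 are squared
canonical correlations between the differences and the lagged levels.  The
rank-r estimate of beta is given by the leading r eigenvectors, normalized
so that its top r x r block is the identity; alpha, mu and Omega follow by
least squares given beta.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.linalg

from .sim import PhaseTrajectory

__all__ = [
    "DegenerateDataError",
    "ProductMoments",
    "VECMFit",
    "concentrate",
    "solve_rrr",
    "trace_stat",
    "fit_vecm",
    "i1_conditions",
]


class DegenerateDataError(ValueError):
    """Raised when the product-moment matrices are (numerically) singular."""


def _as_levels(data) -> np.ndarray:
    if isinstance(data, PhaseTrajectory):
        return data.phi
    phi = np.atleast_2d(np.asarray(data, dtype=float))
    if phi.ndim != 2:
        raise ValueError("levels must be a 2-D array (time x channels)")
    return phi


@dataclass
class ProductMoments:
    """Cross-moment matrices of demeaned differences and lagged levels."""

    S00: np.ndarray
    S01: np.ndarray
    S11: np.ndarray
    T_eff: int
    mean_diff: np.ndarray
    mean_lag: np.ndarray
    Z0c: np.ndarray = field(repr=False)  # demeaned differences, T_eff x p
    Z1c: np.ndarray = field(repr=False)  # demeaned lagged levels, T_eff x p

    @property
    def p(self) -> int:
        return self.S00.shape[0]


def _check_pd(S: np.ndarray, name: str, rcond: float = 1e-12) -> None:
    w = scipy.linalg.eigvalsh(S)
    if w[0] <= rcond * max(w[-1], np.finfo(float).tiny):
        raise DegenerateDataError(
            f"{name} is numerically singular (constant or duplicated channels?)"
        )


def concentrate(data) -> ProductMoments:
    """Form the product moments of the VECM with an unrestricted constant.

    One observation is lost to differencing: T_eff = N - 1.  Both the
    differences and the lagged levels are sample-mean centred, which
    concentrates the constant term out of the likelihood.
    """
    phi = _as_levels(data)
    N, p = phi.shape
    if N < p + 2:
        raise ValueError(f"need at least p + 2 = {p + 2} observations, got {N}")
    Z0 = np.diff(phi, axis=0)
    Z1 = phi[:-1]
    m0 = Z0.mean(axis=0)
    m1 = Z1.mean(axis=0)
    Z0c = Z0 - m0
    Z1c = Z1 - m1
    T = N - 1
    S00 = Z0c.T @ Z0c / T
    S01 = Z0c.T @ Z1c / T
    S11 = Z1c.T @ Z1c / T
    _check_pd(S00, "S00")
    _check_pd(S11, "S11")
    return ProductMoments(S00=S00, S01=S01, S11=S11, T_eff=T,
                          mean_diff=m0, mean_lag=m1, Z0c=Z0c, Z1c=Z1c)


def _rrr_eig(S00, S01, S11):
    """Eigenvalues/vectors of det(lambda S11 - S10 S00^{-1} S01) = 0.

    Solved as a symmetric problem in the Cholesky-whitened coordinates of
    S11; returns eigenvalues in descending order and eigenvectors V with
    V' S11 V = I, each column's first non-negligible entry made positive.
    """
    L = scipy.linalg.cholesky(S11, lower=True)
    # W = L^{-1} S10 S00^{-1} S01 L^{-T}, symmetric PSD
    X = scipy.linalg.solve_triangular(L, S01.T, lower=True)  # L^{-1} S10
    C = scipy.linalg.cho_factor(S00, lower=True)
    Y = scipy.linalg.cho_solve(C, X.T)  # S00^{-1} S01 L^{-T}
    W = X @ Y
    W = 0.5 * (W + W.T)
    lams, U = scipy.linalg.eigh(W)
    order = np.argsort(lams)[::-1]
    lams = np.clip(lams[order], 0.0, 1.0 - 1e-15)
    V = scipy.linalg.solve_triangular(L, U[:, order], trans="T", lower=True)
    # deterministic sign convention
    for j in range(V.shape[1]):
        col = V[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12 * np.abs(col).max())[0]
        if nz.size and col[nz[0]] < 0:
            V[:, j] = -col
    return lams, V


def solve_rrr(moments: ProductMoments):
    """Solve the reduced-rank-regression eigenvalue problem.

    Returns ``(eigenvalues, V)`` with eigenvalues descending in [0, 1) and
    eigenvectors satisfying V' S11 V = I.
    """
    return _rrr_eig(moments.S00, moments.S01, moments.S11)


def trace_stat(eigenvalues, r: int, T_eff: int) -> float:
    """Trace statistic -T sum_{i>r} log(1 - lambda_i) for H_r against H_p."""
    lams = np.asarray(eigenvalues, dtype=float)
    p = lams.shape[0]
    if not 0 <= r <= p:
        raise ValueError(f"rank must be in [0, {p}]")
    if np.any(lams >= 1.0):
        raise ValueError("eigenvalues must be < 1")
    return float(-T_eff * np.sum(np.log1p(-lams[r:])))


@dataclass
class VECMFit:
    """Maximum-likelihood fit of the VECM at a given cointegration rank."""

    r: int
    eigenvalues: np.ndarray
    alpha_hat: np.ndarray
    beta_hat: np.ndarray
    mu_hat: np.ndarray
    Omega_hat: np.ndarray
    loglik: float
    residuals: np.ndarray = field(repr=False)
    alpha_se: Optional[np.ndarray] = None
    mu_se: Optional[np.ndarray] = None
    T_eff: int = 0
    normalization_permutation: Optional[np.ndarray] = None
    # eigenvalues of a restricted problem (set by the restriction module)
    lambda_star: Optional[np.ndarray] = None
    n_iter: Optional[int] = None
    converged: Optional[bool] = None
    loglik_history: Optional[np.ndarray] = None

    @property
    def p(self) -> int:
        return self.mu_hat.shape[0]

    @property
    def P_hat(self) -> np.ndarray:
        """Level-coefficient matrix alpha beta' (zero matrix when r = 0)."""
        if self.r == 0:
            return np.zeros((self.p, self.p))
        return self.alpha_hat @ self.beta_hat.T


def normalize_beta(beta_raw: np.ndarray):
    """Normalize beta so its top r x r block is the identity.

    Uses c = (I_r, 0)'; if the top block is singular a row permutation
    moving an invertible block on top is applied instead, and the chosen
    permutation is returned for reporting.
    """
    p, r = beta_raw.shape
    if r == 0:
        return beta_raw.copy(), None
    top = beta_raw[:r, :]
    if np.linalg.matrix_rank(top, tol=1e-10) == r:
        return beta_raw @ np.linalg.inv(top), None
    # pivot rows via QR with column pivoting on beta'
    _, _, piv = scipy.linalg.qr(beta_raw.T, pivoting=True)
    perm = np.concatenate([piv[:r], np.setdiff1d(np.arange(p), piv[:r])])
    top = beta_raw[perm[:r], :]
    if np.linalg.matrix_rank(top, tol=1e-10) < r:
        raise DegenerateDataError("beta is rank deficient; cannot normalize")
    return beta_raw @ np.linalg.inv(top), perm


def _gaussian_loglik(Omega: np.ndarray, T_eff: int) -> float:
    p = Omega.shape[0]
    sign, logdet = np.linalg.slogdet(Omega)
    if sign <= 0:
        raise DegenerateDataError("residual covariance is singular")
    return float(-0.5 * T_eff * (logdet + p * (1.0 + np.log(2.0 * np.pi))))


def _ls_given_beta(moments: ProductMoments, beta: np.ndarray):
    """alpha, mu, Omega, residuals and standard errors given a known beta.

    Conditional least squares: regress Delta phi_n on (beta' phi_{n-1}, 1).
    Standard errors use the ML covariance estimate.
    """
    T = moments.T_eff
    p = moments.p
    r = beta.shape[1]
    Sb1 = moments.S11 @ beta
    Sbb = beta.T @ Sb1
    alpha = np.linalg.solve(Sbb, (moments.S01 @ beta).T).T  # p x r
    resid = moments.Z0c - moments.Z1c @ beta @ alpha.T
    Omega = resid.T @ resid / T
    mu = moments.mean_diff - alpha @ (beta.T @ moments.mean_lag)
    # (X'X)^{-1} for X = (beta'phi_{n-1}, 1), uncentered
    w_mean = beta.T @ moments.mean_lag
    XtX = np.empty((r + 1, r + 1))
    XtX[:r, :r] = T * (Sbb + np.outer(w_mean, w_mean))
    XtX[:r, r] = T * w_mean
    XtX[r, :r] = T * w_mean
    XtX[r, r] = T
    XtX_inv = np.linalg.inv(XtX)
    d = np.sqrt(np.clip(np.diag(XtX_inv), 0.0, None))
    omega_d = np.sqrt(np.diag(Omega))
    alpha_se = np.outer(omega_d, d[:r])
    mu_se = omega_d * d[r]
    return alpha, mu, Omega, resid, alpha_se, mu_se


def fit_vecm(data, r: int, moments: Optional[ProductMoments] = None) -> VECMFit:
    """Fit the VECM with cointegration rank r by reduced-rank regression.

    r = p reproduces the unrestricted (OLS) model; r = 0 is the model with
    no levels term.  ``beta_hat`` is normalized so its top block is I_r.
    """
    if moments is None:
        moments = concentrate(data)
    p, T = moments.p, moments.T_eff
    if not 0 <= r <= p:
        raise ValueError(f"rank must be in [0, {p}]")
    lams, V = _rrr_eig(moments.S00, moments.S01, moments.S11)
    if r == 0:
        Omega = moments.S00
        return VECMFit(
            r=0, eigenvalues=lams, alpha_hat=np.zeros((p, 0)),
            beta_hat=np.zeros((p, 0)), mu_hat=moments.mean_diff.copy(),
            Omega_hat=Omega, loglik=_gaussian_loglik(Omega, T),
            residuals=moments.Z0c.copy(),
            alpha_se=np.zeros((p, 0)),
            mu_se=np.sqrt(np.diag(Omega) / T), T_eff=T,
        )
    beta, perm = normalize_beta(V[:, :r])
    alpha, mu, Omega, resid, alpha_se, mu_se = _ls_given_beta(moments, beta)
    return VECMFit(
        r=r, eigenvalues=lams, alpha_hat=alpha, beta_hat=beta, mu_hat=mu,
        Omega_hat=Omega, loglik=_gaussian_loglik(Omega, T), residuals=resid,
        alpha_se=alpha_se, mu_se=mu_se, T_eff=T,
        normalization_permutation=perm,
    )


def _orth_complement(M: np.ndarray) -> np.ndarray:
    p, r = M.shape
    if r == 0:
        return np.eye(p)
    return scipy.linalg.null_space(M.T)


def i1_conditions(alpha: np.ndarray, beta: np.ndarray, tol: float = 1e-10) -> dict:
    """Check the I(1) conditions for P = alpha beta'.

    The process is I(1) with r stationary relations beta'phi when the
    spectral radius of I_r + beta'alpha is below one and the orthogonal
    complements satisfy det(alpha_perp' beta_perp) != 0.
    """
    alpha = np.atleast_2d(np.asarray(alpha, dtype=float))
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    if alpha.shape != beta.shape:
        raise ValueError("alpha and beta must have the same shape")
    p, r = alpha.shape
    for name, M in (("alpha", alpha), ("beta", beta)):
        if r > 0 and np.linalg.matrix_rank(M, tol=tol) < r:
            raise ValueError(f"{name} must have full column rank")
    if r == 0:
        rho = 0.0
    else:
        rho = float(np.max(np.abs(np.linalg.eigvals(np.eye(r) + beta.T @ alpha))))
    a_perp = _orth_complement(alpha)
    b_perp = _orth_complement(beta)
    if a_perp.shape[1] == 0:
        det = 1.0
    else:
        det = float(np.linalg.det(a_perp.T @ b_perp))
    return {
        "spectral_radius": rho,
        "spectral_radius_ok": rho < 1.0 - tol,
        "orth_complement_det": det,
        "orth_complement_ok": abs(det) > tol,
    }
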