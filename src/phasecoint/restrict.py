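"""Linear restrictions on the loadings and the cointegration vectors.

Hypotheses of the form

    H_alpha:      alpha = A psi         (A known p x m,  psi m x r free)
    H_beta:       beta  = B xi          (B known p x s,  xi  s x r free)
    H_alpha_beta: both simultaneously

encode statements about the coupling network: zero rows of alpha say an
oscillator receives no feedback, and the columns of B pin the coupling
scheme (e.g. (1, -1, 0)' for a 1:1 phase relation).  Each hypothesis is
tested against the unrestricted rank-r model with a likelihood ratio
statistic that is asymptotically chi-squared with

    r(p - m),  r(p - s)  or  r(p - m) + r(p - s)

degrees of freedom respectively.

Estimation: H_beta alone is a reduced-rank regression on the transformed
levels B'phi; H_alpha alone is solved exactly by conditioning the
A-directions of the differences on the A-perp directions (whose mean is
zero under the hypothesis) and running the reduced-rank regression in the
conditional model.  The combined hypothesis has no closed form and is
estimated by an alternating switching algorithm in which each half-step is
the exact conditional MLE given the other side, so the likelihood is
non-decreasing across iterations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.linalg
import scipy.stats

from . import johansen
from .johansen import ProductMoments, VECMFit

__all__ = [
    "RestrictionHypothesis",
    "RestrictionTestResult",
    "estimate_restricted",
    "restriction_df",
    "lrt_restriction",
    "chi2_pvalue",
    "test_restriction",
]


@dataclass
class RestrictionHypothesis:
    """Known restriction matrices for the loadings and/or cointegration vectors."""

    r: int
    A: Optional[np.ndarray] = None
    B: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.A is not None:
            self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
            if self.A.ndim != 2:
                raise ValueError("A must be a p x m matrix")
        if self.B is not None:
            self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        if self.A is None and self.B is None:
            raise ValueError("at least one of A, B must be given")

    def validate(self, p: int) -> None:
        for name, M in (("A", self.A), ("B", self.B)):
            if M is None:
                continue
            if M.shape[0] != p:
                # allow column-vector input written as 1 x p
                if M.shape == (1, p):
                    M = M.T
                    setattr(self, name, M)
                else:
                    raise ValueError(f"{name} must have {p} rows, got {M.shape}")
            cols = M.shape[1]
            if np.linalg.matrix_rank(M, tol=1e-10) < cols:
                raise ValueError(f"{name} must have full column rank")
            if cols < self.r:
                raise ValueError(
                    f"{name} has {cols} columns but the rank is {self.r}; "
                    "the restricted space cannot hold r directions"
                )

    @property
    def m(self) -> Optional[int]:
        return None if self.A is None else self.A.shape[1]

    @property
    def s(self) -> Optional[int]:
        return None if self.B is None else self.B.shape[1]


@dataclass
class RestrictionTestResult:
    stat: float
    df: int
    pvalue: float
    restricted_fit: VECMFit
    unrestricted_fit: VECMFit


def restriction_df(r: int, p: int, m: Optional[int] = None, s: Optional[int] = None,
                   which: str = "both") -> int:
    """Degrees of freedom of the restriction LRT: r(p-m), r(p-s) or their sum."""
    if which == "alpha":
        if m is None:
            raise ValueError("m is required for which='alpha'")
        df = r * (p - m)
    elif which == "beta":
        if s is None:
            raise ValueError("s is required for which='beta'")
        df = r * (p - s)
    elif which == "both":
        if m is None or s is None:
            raise ValueError("m and s are required for which='both'")
        df = r * (p - m) + r * (p - s)
    else:
        raise ValueError("which must be 'alpha', 'beta' or 'both'")
    if df < 0:
        raise ValueError("invalid dimensions: negative degrees of freedom")
    return df


def chi2_pvalue(stat: float, df: int) -> float:
    """Upper-tail probability of the chi-squared distribution."""
    if stat < 0:
        raise ValueError("statistic must be non-negative")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(scipy.stats.chi2.sf(stat, df))


def _finalize(moments: ProductMoments, alpha: np.ndarray, beta: np.ndarray,
              lams_full: np.ndarray, lambda_star=None, n_iter=None,
              converged=None) -> VECMFit:
    """Build a VECMFit from restricted (alpha, beta), normalizing beta.

    The normalization beta -> beta (c'beta)^{-1} rescales alpha by the
    inverse transpose so alpha beta' is unchanged; because the rescaling is
    applied to psi/xi coordinates implicitly, the restricted forms
    alpha = A psi, beta = B xi are preserved.
    """
    T = moments.T_eff
    beta_n, perm = johansen.normalize_beta(beta)
    r = beta.shape[1]
    if r > 0:
        if perm is None:
            trans = beta[:r, :]
        else:
            trans = beta[perm[:r], :]
        alpha_n = alpha @ trans.T
    else:
        alpha_n = alpha
    alpha_n, mu, Omega, resid, alpha_se, mu_se = _ls_given_beta_restricted(
        moments, beta_n, alpha_n)
    return VECMFit(
        r=r, eigenvalues=lams_full, alpha_hat=alpha_n, beta_hat=beta_n,
        mu_hat=mu, Omega_hat=Omega,
        loglik=johansen._gaussian_loglik(Omega, T), residuals=resid,
        alpha_se=alpha_se, mu_se=mu_se, T_eff=T,
        normalization_permutation=perm, lambda_star=lambda_star,
        n_iter=n_iter, converged=converged,
    )


def _ls_given_beta_restricted(moments: ProductMoments, beta: np.ndarray,
                              alpha: np.ndarray):
    """Residuals, covariance, mu and standard errors for fixed (alpha, beta).

    alpha is kept as passed (it already satisfies its restriction); the
    standard errors are the conditional least-squares ones given beta,
    evaluated at the restricted point.
    """
    T, p, r = moments.T_eff, moments.p, beta.shape[1]
    resid = moments.Z0c - moments.Z1c @ beta @ alpha.T
    Omega = resid.T @ resid / T
    mu = moments.mean_diff - alpha @ (beta.T @ moments.mean_lag)
    if r > 0:
        Sbb = beta.T @ moments.S11 @ beta
        w_mean = beta.T @ moments.mean_lag
        XtX = np.empty((r + 1, r + 1))
        XtX[:r, :r] = T * (Sbb + np.outer(w_mean, w_mean))
        XtX[:r, r] = T * w_mean
        XtX[r, :r] = T * w_mean
        XtX[r, r] = T
        d = np.sqrt(np.clip(np.diag(np.linalg.inv(XtX)), 0.0, None))
        omega_d = np.sqrt(np.diag(Omega))
        alpha_se = np.outer(omega_d, d[:r])
        mu_se = omega_d * d[r]
    else:
        alpha_se = np.zeros((p, 0))
        mu_se = np.sqrt(np.diag(Omega) / T)
    return alpha, mu, Omega, resid, alpha_se, mu_se


def _beta_only(moments: ProductMoments, B: np.ndarray, r: int):
    """Exact MLE under beta = B xi: RRR on the transformed levels B'phi."""
    S00, S01, S11 = moments.S00, moments.S01 @ B, B.T @ moments.S11 @ B
    johansen._check_pd(S11, "B'S11B")
    lams, V = johansen._rrr_eig(S00, S01, S11)
    xi = V[:, :r]
    beta = B @ xi
    Sbb = beta.T @ moments.S11 @ beta
    alpha = np.linalg.solve(Sbb, (moments.S01 @ beta).T).T
    return alpha, beta, lams


def _alpha_only(moments: ProductMoments, A: np.ndarray, r: int,
                beta_fixed: Optional[np.ndarray] = None):
    """Exact MLE under alpha = A psi by conditioning on the A-perp directions.

    With u = Abar' Dphi and v = Aperp' Dphi, the hypothesis implies
    E[v | levels] = 0, so v is ancillary for (psi, beta) and the conditional
    model u = psi beta' phi_{lag} + omega v + err carries all information.
    When ``beta_fixed`` is given, psi follows by OLS in the conditional
    model; otherwise (psi, beta) come from the conditional RRR.
    """
    p, m = A.shape
    Abar = A @ np.linalg.inv(A.T @ A)
    Aperp = scipy.linalg.null_space(A.T)
    Z0, Z1, T = moments.Z0c, moments.Z1c, moments.T_eff
    u = Z0 @ Abar
    if Aperp.shape[1] == 0:
        # A spans R^p: restriction vacuous given free psi
        u_res, Z1_res = u, Z1
    else:
        v = Z0 @ Aperp
        G = np.linalg.solve(v.T @ v, np.column_stack([v.T @ u, v.T @ Z1]))
        u_res = u - v @ G[:, :m]
        Z1_res = Z1 - v @ G[:, m:]
    Suu = u_res.T @ u_res / T
    Su1 = u_res.T @ Z1_res / T
    S11 = Z1_res.T @ Z1_res / T
    if beta_fixed is not None:
        W = Z1_res @ beta_fixed
        psi = np.linalg.solve(W.T @ W, W.T @ u_res).T  # m x r
        return A @ psi, beta_fixed, None
    johansen._check_pd(Suu, "conditional Suu")
    lams, V = johansen._rrr_eig(Suu, Su1, S11)
    beta = V[:, :r]
    psi = (Su1 @ beta) @ np.linalg.inv(beta.T @ S11 @ beta)
    return A @ psi, beta, lams


def _xi_given_alpha(moments: ProductMoments, B: np.ndarray, alpha: np.ndarray):
    """Exact conditional MLE of xi (beta = B xi) for fixed alpha.

    Mirror image of the psi-step: condition w = alphabar' Dphi on
    q = alphaperp' Dphi (mean zero for fixed alpha) and regress on B'phi.
    """
    abar = alpha @ np.linalg.inv(alpha.T @ alpha)
    aperp = scipy.linalg.null_space(alpha.T)
    Z0, Z1 = moments.Z0c, moments.Z1c
    w = Z0 @ abar
    ZB = Z1 @ B
    if aperp.shape[1] > 0:
        q = Z0 @ aperp
        G = np.linalg.solve(q.T @ q, np.column_stack([q.T @ w, q.T @ ZB]))
        w = w - q @ G[:, :w.shape[1]]
        ZB = ZB - q @ G[:, w.shape[1]:]
    xi = np.linalg.solve(ZB.T @ ZB, ZB.T @ w)  # s x r
    return B @ xi


def estimate_restricted(data, hyp: RestrictionHypothesis,
                        tol: float = 1e-10, max_iter: int = 1000) -> VECMFit:
    """Maximum-likelihood VECM fit under the given linear restrictions.

    Returns a :class:`VECMFit` whose ``lambda_star`` field carries the
    restricted eigenvalues when the hypothesis admits an eigenvalue
    formulation (H_alpha or H_beta alone).
    """
    moments = johansen.concentrate(data)
    p = moments.p
    r = hyp.r
    if not 0 < r <= p:
        raise ValueError(f"rank must be in [1, {p}]")
    hyp.validate(p)
    lams_full, _ = johansen._rrr_eig(moments.S00, moments.S01, moments.S11)

    if hyp.B is not None and hyp.A is None:
        alpha, beta, lam_star = _beta_only(moments, hyp.B, r)
        return _finalize(moments, alpha, beta, lams_full, lambda_star=lam_star)

    if hyp.A is not None and hyp.B is None:
        alpha, beta, lam_star = _alpha_only(moments, hyp.A, r)
        return _finalize(moments, alpha, beta, lams_full, lambda_star=lam_star)

    # combined hypothesis: alternating exact conditional-MLE steps
    A, B = hyp.A, hyp.B
    _, beta, _ = _beta_only(moments, B, r)  # initialization
    T = moments.T_eff

    def _ll(alpha, beta):
        resid = moments.Z0c - moments.Z1c @ beta @ alpha.T
        return johansen._gaussian_loglik(resid.T @ resid / T, T), resid

    alpha, _, _ = _alpha_only(moments, A, r, beta_fixed=beta)
    ll_prev, _ = _ll(alpha, beta)
    converged = False
    history = [ll_prev]
    for it in range(1, max_iter + 1):
        beta = _xi_given_alpha(moments, B, alpha)
        alpha, _, _ = _alpha_only(moments, A, r, beta_fixed=beta)
        ll, _ = _ll(alpha, beta)
        history.append(ll)
        if abs(ll - ll_prev) < tol:
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
    if not converged:
        import warnings
        warnings.warn(
            f"switching algorithm did not converge in {max_iter} iterations "
            f"(last log-likelihood changes: {np.diff(history[-5:])})",
            RuntimeWarning, stacklevel=2,
        )
    fit = _finalize(moments, alpha, beta, lams_full, n_iter=it, converged=converged)
    fit.loglik_history = np.asarray(history)
    return fit


def lrt_restriction(unres: VECMFit, res: VECMFit, df: int) -> RestrictionTestResult:
    """Likelihood ratio test of a restricted fit against the unrestricted one.

    The statistic 2 (loglik_unres - loglik_res) equals
    T sum_{i<=r} log((1 - lambda*_i)/(1 - lambda_i)) when the restricted
    problem has an eigenvalue formulation.  Slightly negative values from
    numerical round-off are clipped to zero; a clearly negative value means
    the restricted optimum exceeded the unrestricted one and is an error.
    """
    if unres.r != res.r:
        raise ValueError("fits must share the same rank")
    stat = 2.0 * (unres.loglik - res.loglik)
    if stat < -1e-6 * max(1.0, abs(unres.loglik)):
        raise ValueError(
            f"restricted log-likelihood exceeds unrestricted ({stat=}); numerical failure"
        )
    stat = max(stat, 0.0)
    return RestrictionTestResult(
        stat=stat, df=df, pvalue=chi2_pvalue(stat, df) if df >= 1 else 1.0,
        restricted_fit=res, unrestricted_fit=unres,
    )


def test_restriction(data, hyp: RestrictionHypothesis) -> RestrictionTestResult:
    """Convenience wrapper: fit unrestricted and restricted models and test."""
    unres = johansen.fit_vecm(data, hyp.r)
    res = estimate_restricted(data, hyp)
    p = unres.p
    if hyp.A is not None and hyp.B is not None:
        df = restriction_df(hyp.r, p, m=hyp.m, s=hyp.s, which="both")
    elif hyp.A is not None:
        df = restriction_df(hyp.r, p, m=hyp.m, which="alpha")
    else:
        df = restriction_df(hyp.r, p, s=hyp.s, which="beta")
    return lrt_restriction(unres, res, df)
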