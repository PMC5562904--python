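"""Continuous-time / discrete-time correspondence for the phase model.

A continuous-time Ornstein-Uhlenbeck phase process with drift matrix Pi
observed every ``delta`` time units is an exact Gaussian VAR(1) whose
error-correction coefficient is

    P = delta^{-1} (exp(delta Pi) - I_p),

with innovation covariance Omega = int_0^delta e^{s Pi} Sigma Sigma' e^{s Pi'} ds.
Recovering Pi from an estimate of P requires the principal matrix logarithm
of delta P + I_p.  This inverse exists and is real iff delta P + I_p is
nonsingular with no eigenvalue on the closed negative real axis -- the
*embedding* conditions; when they fail the multivariate logarithm is either
undefined or non-real/non-unique and the returned result is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = ["EmbeddingResult", "p_from_pi", "pi_from_p", "omega_from_sigma", "xi_matrix"]


@dataclass
class EmbeddingResult:
    """Continuous-time drift estimate with embedding diagnostics."""

    Pi_hat: np.ndarray
    ok: bool
    diagnostics: dict


def p_from_pi(Pi, delta: float) -> np.ndarray:
    """Discrete-time error-correction matrix P = (exp(delta Pi) - I)/delta."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    Pi = np.atleast_2d(np.asarray(Pi, dtype=float))
    p = Pi.shape[0]
    return (scipy.linalg.expm(delta * Pi) - np.eye(p)) / delta


def pi_from_p(P, delta: float, imag_tol: float = 1e-10) -> EmbeddingResult:
    """Principal-branch inverse Pi = log(delta P + I)/delta with diagnostics.

    The result is flagged ``ok`` iff delta P + I is nonsingular and has no
    eigenvalue on the closed negative real axis (where the principal
    logarithm is undefined or non-real).  A flagged result is still
    returned -- with the real part of the principal logarithm -- so the
    caller can inspect the diagnostics.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    P = np.atleast_2d(np.asarray(P, dtype=float))
    p = P.shape[0]
    M = delta * P + np.eye(p)
    eigs = np.linalg.eigvals(M)
    scale = max(1.0, float(np.abs(eigs).max()))
    nonsingular = bool(np.abs(eigs).min() > 1e-14 * scale)
    if not nonsingular:
        raise np.linalg.LinAlgError("delta P + I is singular; no continuous-time drift exists")
    on_neg_axis = bool(np.any((eigs.real < 1e-14 * scale) & (np.abs(eigs.imag) < 1e-14 * scale)))
    logM = scipy.linalg.logm(M)
    max_imag = float(np.abs(np.imag(logM)).max()) if np.iscomplexobj(logM) else 0.0
    ok = nonsingular and not on_neg_axis and max_imag <= imag_tol
    return EmbeddingResult(
        Pi_hat=np.real(logM) / delta,
        ok=ok,
        diagnostics={
            "eigenvalues": eigs,
            "nonsingular": nonsingular,
            "negative_real_axis": on_neg_axis,
            "max_imag_log": max_imag,
        },
    )


def omega_from_sigma(Pi, Sigma, delta: float) -> np.ndarray:
    """Innovation covariance Omega = int_0^delta e^{s Pi} Sigma Sigma' e^{s Pi'} ds.

    Evaluated exactly with the Van Loan augmented-matrix-exponential
    identity: for C = [[-Pi, Sigma Sigma'], [0, Pi']],
    expm(delta C) = [[*, G], [0, F]] gives Omega = F' G.
    ``Sigma`` may be a vector of diagonal scales or a full matrix.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    Pi = np.atleast_2d(np.asarray(Pi, dtype=float))
    p = Pi.shape[0]
    Sigma = np.asarray(Sigma, dtype=float)
    if Sigma.ndim < 2:
        Sigma = np.diag(np.broadcast_to(Sigma, (p,)).astype(float))
    Q = Sigma @ Sigma.T
    C = np.zeros((2 * p, 2 * p))
    C[:p, :p] = -Pi
    C[:p, p:] = Q
    C[p:, p:] = Pi.T
    E = scipy.linalg.expm(delta * C)
    Omega = E[p:, p:].T @ E[:p, p:]
    return 0.5 * (Omega + Omega.T)


def xi_matrix(alpha, beta, delta: float) -> np.ndarray:
    """Scaling xi = (beta'alpha)^{-1} (exp(delta beta'alpha) - I_r).

    Links the continuous-time decomposition Pi = alpha beta' to the
    discrete-time one through exp(delta Pi) - I_p = alpha xi beta', i.e.
    delta P = alpha xi beta'.  The loadings of the discretely observed
    model therefore span sp(alpha) and the cointegration space is shared
    between the two time scales; only the r x r scaling xi separates them.
    """
    alpha = np.atleast_2d(np.asarray(alpha, dtype=float))
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    r = alpha.shape[1]
    ba = beta.T @ alpha
    if np.linalg.matrix_rank(ba, tol=1e-12) < r:
        raise np.linalg.LinAlgError("beta'alpha is singular")
    return np.linalg.solve(ba, scipy.linalg.expm(delta * ba) - np.eye(r))
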