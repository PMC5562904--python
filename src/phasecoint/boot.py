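"""Bootstrap determination of the cointegration rank.

The asymptotic distribution of the trace statistic is non-standard, so
p-values are obtained by a residual bootstrap: fit the rank-r model, build
M recursive sample paths from the fitted error-correction recursion with
i.i.d. resampled centred residuals, recompute the trace statistic on each
path, and compare the observed statistic with the bootstrap distribution.
The sequential procedure tests r = 0, 1, ... and stops at the first
hypothesis that is not rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import johansen
from ._kernels import recursive_var_paths
from .sim import PhaseTrajectory

__all__ = ["RankTestResult", "bootstrap_rank_pvalue", "sequential_rank"]


@dataclass
class RankTestResult:
    """Outcome of the sequential bootstrap trace test."""

    stats: np.ndarray          # trace statistic for each tested hypothesis r=0..p-1
    pvalues: np.ndarray        # bootstrap p-values (NaN where the sequence stopped early)
    selected_rank: int
    level: float
    M: int
    seed: int
    i1_warnings: list = field(default_factory=list)


def _levels(data) -> np.ndarray:
    return data.phi if isinstance(data, PhaseTrajectory) else np.asarray(data, dtype=float)


def _replicate_rng(seed: int, m: int) -> np.random.Generator:
    # stream derived deterministically from (seed, m): results do not depend
    # on scheduling or on how many replicates run before this one
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(int(m),)))


def bootstrap_rank_pvalue(data, r: int, M: int = 500, seed: int = 0,
                          moments: Optional[johansen.ProductMoments] = None,
                          return_details: bool = False):
    """Bootstrap p-value for H_r: rank <= r against the unrestricted model.

    Fits the rank-r model, generates M recursive bootstrap paths
    phi*_n = (I + alpha beta') phi*_{n-1} + mu + eps*_n started at the
    observed initial level, with eps* drawn i.i.d. with replacement from
    the centred residuals, and returns (1 + #{LRT* >= LRT_obs}) / (M + 1).
    """
    phi = _levels(data)
    p = phi.shape[1]
    if not 0 <= r < p:
        raise ValueError(f"r must be in [0, {p})")
    if M < 99:
        raise ValueError("use at least M = 99 bootstrap replicates")
    if moments is None:
        moments = johansen.concentrate(phi)
    T = moments.T_eff
    fit = johansen.fit_vecm(phi, r, moments=moments)
    obs = johansen.trace_stat(fit.eigenvalues, r, T)
    i1_warning = None
    if r > 0:
        cond = johansen.i1_conditions(fit.alpha_hat, fit.beta_hat)
        if not (cond["spectral_radius_ok"] and cond["orth_complement_ok"]):
            i1_warning = cond
            warnings.warn(
                f"fitted H_{r} model violates the I(1) conditions; "
                "bootstrap paths may be explosive", RuntimeWarning, stacklevel=2,
            )
    resid = fit.residuals - fit.residuals.mean(axis=0)
    A = np.eye(p) + fit.P_hat
    mu = fit.mu_hat
    phi0 = phi[0]
    # resample indices per replicate with its own deterministic stream
    idx = np.empty((M, T), dtype=np.int64)
    for m in range(M):
        idx[m] = _replicate_rng(seed, m).integers(0, T, size=T)
    eps = resid[idx]  # (M, T, p)
    paths = recursive_var_paths(A, mu, phi0, eps)
    boot_stats = np.empty(M)
    for m in range(M):
        try:
            mom = johansen.concentrate(paths[m])
            lams, _ = johansen.solve_rrr(mom)
            boot_stats[m] = johansen.trace_stat(lams, r, mom.T_eff)
        except johansen.DegenerateDataError:
            boot_stats[m] = np.inf  # conservative: counts against rejection
    pvalue = (1.0 + float(np.sum(boot_stats >= obs))) / (M + 1.0)
    if return_details:
        return pvalue, {"stat": obs, "boot_stats": boot_stats, "i1_warning": i1_warning}
    return pvalue


def sequential_rank(data, level: float = 0.05, M: int = 500, seed: int = 0) -> RankTestResult:
    """Sequential trace test: first r in 0, 1, ..., p-1 not rejected at ``level``.

    If every hypothesis is rejected the selected rank is p (full rank,
    stationary system).
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    phi = _levels(data)
    p = phi.shape[1]
    moments = johansen.concentrate(phi)
    lams, _ = johansen.solve_rrr(moments)
    stats = np.array([johansen.trace_stat(lams, r, moments.T_eff) for r in range(p)])
    pvalues = np.full(p, np.nan)
    warnings_log = []
    selected = p
    for r in range(p):
        pv, details = bootstrap_rank_pvalue(
            phi, r, M=M, seed=seed + r, moments=moments, return_details=True
        )
        pvalues[r] = pv
        if details["i1_warning"] is not None:
            warnings_log.append((r, details["i1_warning"]))
        if pv > level:
            selected = r
            break
    return RankTestResult(stats=stats, pvalues=pvalues, selected_rank=selected,
                          level=level, M=M, seed=seed, i1_warnings=warnings_log)
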