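"""Seeded replications of the simulation studies, at configurable scale.

Four reference networks of p = 3 Winfree oscillators are built in, named by
their coupling structure:

================  =========================================  ====
model             Pi = alpha beta'                            rank
================  =========================================  ====
independent       0                                            0
unidirectional    alpha = (-0.5, 0, 0)',  beta = (1, -1, 0)'   1
bidirectional     alpha = (-0.5, 0.5, 0)', beta = (1, -1, 0)'  1
full              2-column alpha, beta (Kuramoto-type)         2
================  =========================================  ====

All share kappa = (0.75, 1, 1)', Sigma_phi = I, Sigma_gamma = 0.1 I,
z0 = (1, 0, 0, 1, -1, 0)', delta = 0.1, N = 2000 (T = 200) and a fine
Euler step of 2e-4.

Provided experiment drivers:

* :func:`run_table5` -- rank-conclusion frequencies of the sequential
  bootstrap trace test across replications, per model;
* :func:`run_epsilon_sweep` -- power of the rank test and of the mean
  phase coherence measure as the coupling Pi -> eps * Pi is scaled down;
* :func:`analyze_signals` -- the generic raw-signal pipeline (Hilbert
  phases -> rank test -> fit -> continuous-time embedding -> MPC table).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import boot, ctime, johansen, phase
from .sim import OscillatorSystemSpec, PhaseTrajectory, simulate_winfree

__all__ = [
    "MODELS",
    "ExperimentConfig",
    "winfree_spec",
    "run_table5",
    "run_epsilon_sweep",
    "analyze_signals",
]


def _model_matrices():
    beta1 = np.array([[1.0], [-1.0], [0.0]])
    alpha_full = np.array([[-0.50, 0.25], [0.25, -0.50], [0.25, 0.25]])
    beta_full = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, -1.0]])
    return {
        "independent": (np.zeros((3, 0)), np.zeros((3, 0))),
        "unidirectional": (np.array([[-0.5], [0.0], [0.0]]), beta1),
        "bidirectional": (np.array([[-0.5], [0.5], [0.0]]), beta1),
        "full": (alpha_full, beta_full),
    }


MODELS = _model_matrices()
TRUE_RANK = {"independent": 0, "unidirectional": 1, "bidirectional": 1, "full": 2}

KAPPA = np.array([0.75, 1.0, 1.0])
SIGMA_PHI = np.ones(3)
SIGMA_GAMMA = np.full(3, 0.1)


def winfree_spec(model: str = "independent", epsilon: float = 1.0, seed: int = 0,
                 N: int = 2000, delta: float = 0.1, dt_fine: float = 2e-4
                 ) -> OscillatorSystemSpec:
    """Study-condition spec for one of the reference three-oscillator networks."""
    alpha, beta = MODELS[model]
    Pi = epsilon * (alpha @ beta.T) if alpha.shape[1] else np.zeros((3, 3))
    return OscillatorSystemSpec(
        p=3, Pi=Pi, kappa=KAPPA, sigma_phi=SIGMA_PHI, sigma_gamma=SIGMA_GAMMA,
        dt_fine=dt_fine, dt_obs=delta, T=N * delta, seed=seed,
    )


def independent_pair_spec(kappa_pair=(0.75, 1.0), seed: int = 0, N: int = 2000,
                          delta: float = 0.1, dt_fine: float = 2e-4
                          ) -> OscillatorSystemSpec:
    """Independent two-oscillator null system for mean-phase-coherence calibration.

    Uses the study noise levels and the initial state of the first two
    units of z0 = (1, 0, 0, 1, ...)', i.e. phi0 = (0, pi/2), gamma0 = (1, 1).
    """
    return OscillatorSystemSpec(
        p=2, Pi=np.zeros((2, 2)), kappa=np.asarray(kappa_pair, dtype=float),
        sigma_phi=np.ones(2), sigma_gamma=np.full(2, 0.1),
        dt_fine=dt_fine, dt_obs=delta, T=N * delta, seed=seed,
        phi0=np.array([0.0, np.pi / 2]), gamma0=np.ones(2),
    )


@dataclass
class ExperimentConfig:
    """Scale and seeding of a replication experiment.

    Defaults are desk scale (n_reps = 100, M_bootstrap = 200); the original
    studies used 1000 repetitions with 500 bootstrap samples.
    """

    models: Sequence[str] = ("independent", "unidirectional", "bidirectional", "full")
    n_reps: int = 100
    M_bootstrap: int = 200
    N: int = 2000
    delta: float = 0.1
    dt_fine: float = 2e-4
    level: float = 0.05
    seed: int = 0
    epsilon: float = 1.0

    def rep_seed(self, tag: int, rep: int) -> np.random.SeedSequence:
        return np.random.SeedSequence(entropy=int(self.seed), spawn_key=(int(tag), int(rep)))


def _boot_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def run_table5(config: ExperimentConfig, progress: bool = False):
    """Rank-conclusion percentages of the sequential bootstrap trace test.

    For each model: simulate ``n_reps`` independent trajectories, run the
    sequential rank determination at the configured level and tabulate the
    frequency of each selected rank.  Returns ``(table, selections)`` where
    ``table`` is a DataFrame of percentages (rows = models, columns = the
    concluded rank) and ``selections`` maps model -> array of selected ranks.
    """
    if config.n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rows = {}
    selections = {}
    for tag, model in enumerate(config.models):
        sel = np.empty(config.n_reps, dtype=int)
        for rep in range(config.n_reps):
            ss = config.rep_seed(tag, rep)
            spec = winfree_spec(model, epsilon=config.epsilon, seed=ss,
                                N=config.N, delta=config.delta, dt_fine=config.dt_fine)
            traj = simulate_winfree(spec)
            res = boot.sequential_rank(traj, level=config.level,
                                       M=config.M_bootstrap, seed=_boot_seed(ss))
            sel[rep] = res.selected_rank
            if progress:
                print(f"{model} rep {rep + 1}/{config.n_reps}: rank {sel[rep]}")
        selections[model] = sel
        rows[model] = {f"r={r}": 100.0 * np.mean(sel == r) for r in range(4)}
    table = pd.DataFrame(rows).T
    table["correct"] = [rows[m][f"r={TRUE_RANK[m]}"] for m in config.models]
    return table, selections


def run_epsilon_sweep(config: ExperimentConfig, eps_grid: Sequence[float],
                      progress: bool = False) -> pd.DataFrame:
    """Rank-test p-values and MPC measures as the coupling is scaled down.

    Uses the fully coupled network with Pi -> eps * Pi; eps = 0 is the
    independent model and eps = 1 the full-strength one.  Per grid point:
    ``n_reps`` repetitions of (simulate, bootstrap p-values for
    H_r: r = 0, 1, 2, pairwise R); the returned frame holds the median and
    the 2.5/97.5% envelope of each quantity.
    """
    eps_grid = np.asarray(list(eps_grid), dtype=float)
    if np.any((eps_grid < 0) | (eps_grid > 1)):
        raise ValueError("eps_grid must lie in [0, 1]")
    pairs = list(itertools.combinations(range(3), 2))
    records = []
    for ei, eps in enumerate(eps_grid):
        pvals = np.empty((config.n_reps, 3))
        Rs = np.empty((config.n_reps, len(pairs)))
        for rep in range(config.n_reps):
            ss = config.rep_seed(1000 + ei, rep)
            spec = winfree_spec("full", epsilon=eps, seed=ss, N=config.N,
                                delta=config.delta, dt_fine=config.dt_fine)
            traj = simulate_winfree(spec)
            bseed = _boot_seed(ss)
            moments = johansen.concentrate(traj)
            for r in range(3):
                pvals[rep, r] = boot.bootstrap_rank_pvalue(
                    traj, r, M=config.M_bootstrap, seed=bseed + r, moments=moments)
            for k, (i, j) in enumerate(pairs):
                Rs[rep, k] = phase.mean_phase_coherence(traj.phi[:, i], traj.phi[:, j]).R
        rec = {"eps": eps}
        for r in range(3):
            col = pvals[:, r]
            rec[f"p_r{r}_median"] = np.median(col)
            rec[f"p_r{r}_lo"] = np.quantile(col, 0.025)
            rec[f"p_r{r}_hi"] = np.quantile(col, 0.975)
        for k, (i, j) in enumerate(pairs):
            col = Rs[:, k]
            rec[f"R_{i + 1}{j + 1}_median"] = np.median(col)
            rec[f"R_{i + 1}{j + 1}_lo"] = np.quantile(col, 0.025)
            rec[f"R_{i + 1}{j + 1}_hi"] = np.quantile(col, 0.975)
        records.append(rec)
        if progress:
            print(f"eps={eps:.2f} done")
    return pd.DataFrame.from_records(records)


@dataclass
class SignalAnalysisReport:
    """Structured output of the raw-signal pipeline."""

    channels: list
    delta: float
    rank_result: boot.RankTestResult
    fit: johansen.VECMFit
    P_hat: np.ndarray               # continuous-time scale: Delta phi = delta P phi + ...
    embedding: ctime.EmbeddingResult
    mpc: pd.DataFrame
    mu_hat_scaled: np.ndarray       # mu-hat / delta, the intrinsic-frequency estimate
    mpc_critical_value: Optional[float] = None


def analyze_signals(data, delta: float, r_max: Optional[int] = None,
                    level: float = 0.05, M: int = 500, seed: int = 0,
                    signals_are_phases: bool = False,
                    mpc_null: Optional[OscillatorSystemSpec] = None,
                    mpc_null_M: int = 200) -> SignalAnalysisReport:
    """Full analysis pipeline for multichannel oscillating signals.

    Steps: instantaneous phases by the Hilbert transform (unless the input
    already holds unwrapped phases) -> sequential bootstrap rank test ->
    VECM fit at the selected rank (capped at ``r_max`` if given) ->
    continuous-time drift via the matrix logarithm with embedding
    diagnostics -> pairwise mean phase coherence table.
    """
    if isinstance(data, pd.DataFrame):
        channels = [str(c) for c in data.columns]
        X = data.to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        channels = [f"ch{i + 1}" for i in range(X.shape[1])]
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D array with at least 2 channels")
    p = X.shape[1]
    if signals_are_phases:
        phi = X
    else:
        phi = np.column_stack([phase.hilbert_phase(X[:, k]) for k in range(p)])
    try:
        rank_res = boot.sequential_rank(phi, level=level, M=M, seed=seed)
    except johansen.DegenerateDataError as exc:
        dup = _duplicate_channels(X, channels)
        if dup:
            raise johansen.DegenerateDataError(
                f"degenerate channels {dup}: {exc}") from exc
        raise
    r = rank_res.selected_rank if r_max is None else min(rank_res.selected_rank, r_max)
    fit = johansen.fit_vecm(phi, r)
    P_hat = fit.P_hat / delta
    embedding = ctime.pi_from_p(P_hat, delta)
    crit = None
    if mpc_null is not None:
        crit = phase.mpc_null_quantile(mpc_null, M=mpc_null_M, level=0.95, seed=seed)
    mpc = pd.DataFrame(np.eye(p), index=channels, columns=channels)
    for i in range(p):
        for j in range(i + 1, p):
            R = phase.mean_phase_coherence(phi[:, i], phi[:, j]).R
            mpc.iloc[i, j] = mpc.iloc[j, i] = R
    return SignalAnalysisReport(
        channels=channels, delta=delta, rank_result=rank_res, fit=fit,
        P_hat=P_hat, embedding=embedding, mpc=mpc,
        mu_hat_scaled=fit.mu_hat / delta, mpc_critical_value=crit,
    )


def _duplicate_channels(X: np.ndarray, channels) -> list:
    dup = []
    for i in range(X.shape[1]):
        for j in range(i + 1, X.shape[1]):
            if np.allclose(X[:, i], X[:, j]):
                dup.append((channels[i], channels[j]))
    return dup
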