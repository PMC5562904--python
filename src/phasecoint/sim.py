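"""Simulators for linearly phase-coupled stochastic oscillators.

The oscillator class is defined in polar coordinates: each unit k has an
unwrapped phase phi_k (monotone on average, so the unit keeps revolving) and
a positive amplitude gamma_k, with interaction entering only through a
linear map of the phases,

    f_k(phi, gamma) = sum_j Pi_kj (phi_j - omega_j) + h(gamma_k).

Three data-generating processes are provided:

* :func:`simulate_winfree` -- the noisy Winfree system, where the amplitude
  follows d(gamma_k) = (kappa_k - gamma_k) gamma_k^2 dt + noise and feeds the
  phase drift (h = identity), integrated by Euler-Maruyama on a fine grid
  and subsampled to the observation grid.
* :func:`simulate_ou_phase_exact` -- the degenerate-amplitude model where
  the phase vector is a multivariate Ornstein-Uhlenbeck process; sampled
  from its exact discrete-time Gaussian transition.
* :func:`simulate_var` -- the discrete-time error-correction recursion
  itself, used for stationarity experiments and bootstrap checks.

The Kuramoto drift and its linearisations around the in-phase state are
included as the canonical nonlinear example that motivates the linear
coupling class.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from ._kernels import euler_linear, euler_winfree, recursive_var_paths

__all__ = [
    "OscillatorSystemSpec",
    "PhaseTrajectory",
    "PlaneTrajectory",
    "simulate_winfree",
    "simulate_ou_phase_exact",
    "simulate_ou_phase_euler",
    "simulate_var",
    "phases_to_plane",
    "plane_to_phases",
    "plane_drift",
    "kuramoto_drift",
    "linearize_kuramoto_pairwise",
    "linearize_kuramoto_uniform",
]


def _as_vector(x, p: int, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.ndim == 0:
        v = np.full(p, float(v))
    if v.shape != (p,):
        raise ValueError(f"{name} must be a length-{p} vector, got shape {v.shape}")
    return v


@dataclass
class OscillatorSystemSpec:
    """Parameters of a coupled-oscillator data-generating process.

    Parameters
    ----------
    Pi
        p x p coupling matrix; row k describes how oscillator k reacts to
        the phases of the others.  ``Pi = 0`` gives an independent system.
    kappa
        Amplitude levels of the Winfree amplitude SDE (one per oscillator).
        Required by :func:`simulate_winfree`.
    mu
        Intrinsic angular frequencies for the degenerate-amplitude model.
    omega
        Phase offsets defining the attracting phase relation (default 0).
    sigma_phi, sigma_gamma
        Diagonal noise scales for phase and amplitude.  Only diagonal noise
        is supported (the polar->Cartesian correspondence is derived under
        diagonal noise); pass vectors, not matrices.
    dt_fine, dt_obs, T
        Fine integration step, observation step delta and total time.
        ``dt_obs`` must be an integer multiple of ``dt_fine``.
    phi0, gamma0
        Initial conditions.  Default for p = 3 is the configuration used in
        all the simulation studies, z0 = (1,0, 0,1, -1,0)', i.e.
        phi0 = (0, pi/2, pi), gamma0 = (1, 1, 1); otherwise phi0 defaults
        to zeros and gamma0 to kappa.
    degeneracy_policy
        What to do when an Euler step drives an amplitude to <= 0:
        ``"record"`` (count and continue, the default -- at the study noise
        level the event is essentially impossible) or ``"reflect"``.
    """

    p: int
    Pi: np.ndarray
    kappa: Optional[np.ndarray] = None
    mu: Optional[np.ndarray] = None
    omega: np.ndarray = None
    sigma_phi: np.ndarray = 0.0
    sigma_gamma: np.ndarray = 0.0
    dt_fine: float = 2e-4
    dt_obs: float = 0.1
    T: float = 200.0
    seed: int = 0
    phi0: Optional[np.ndarray] = None
    gamma0: Optional[np.ndarray] = None
    degeneracy_policy: str = "record"

    def __post_init__(self):
        p = self.p
        self.Pi = np.asarray(self.Pi, dtype=float)
        if self.Pi.shape != (p, p):
            raise ValueError(f"Pi must be {p}x{p}, got {self.Pi.shape}")
        for name in ("sigma_phi", "sigma_gamma"):
            v = getattr(self, name)
            if np.ndim(v) == 2:
                raise ValueError(f"{name} must be a diagonal (vector) noise scale; "
                                 "full noise matrices are not supported")
            setattr(self, name, _as_vector(v, p, name))
        if np.any(self.sigma_phi < 0) or np.any(self.sigma_gamma < 0):
            raise ValueError("noise scales must be non-negative")
        self.omega = _as_vector(0.0 if self.omega is None else self.omega, p, "omega")
        if self.kappa is not None:
            self.kappa = _as_vector(self.kappa, p, "kappa")
            if np.any(self.kappa <= 0):
                raise ValueError("kappa must be positive elementwise")
        if self.mu is not None:
            self.mu = _as_vector(self.mu, p, "mu")
        if self.dt_fine <= 0 or self.dt_obs <= 0:
            raise ValueError("step sizes must be positive")
        ratio = self.dt_obs / self.dt_fine
        if abs(ratio - round(ratio)) > 1e-8:
            raise ValueError("dt_obs must be an integer multiple of dt_fine")
        if self.phi0 is None:
            if p == 3:
                self.phi0 = np.array([0.0, np.pi / 2, np.pi])
            else:
                self.phi0 = np.zeros(p)
        else:
            self.phi0 = _as_vector(self.phi0, p, "phi0")
        if self.gamma0 is None:
            if p == 3:
                self.gamma0 = np.ones(3)
            elif self.kappa is not None:
                self.gamma0 = self.kappa.copy()
        else:
            self.gamma0 = _as_vector(self.gamma0, p, "gamma0")
        if self.degeneracy_policy not in ("record", "reflect"):
            raise ValueError("degeneracy_policy must be 'record' or 'reflect'")

    @property
    def n_sub(self) -> int:
        return int(round(self.dt_obs / self.dt_fine))

    @property
    def n_obs(self) -> int:
        return int(round(self.T / self.dt_obs))

    def with_seed(self, seed: int) -> "OscillatorSystemSpec":
        return replace(self, seed=seed)


@dataclass
class PhaseTrajectory:
    """Equidistant multivariate unwrapped phase series (optionally with amplitudes)."""

    phi: np.ndarray
    delta: float
    gamma: Optional[np.ndarray] = None
    t0: float = 0.0
    nonpositive_amplitude_events: int = 0

    def __post_init__(self):
        self.phi = np.atleast_2d(np.asarray(self.phi, dtype=float))
        if self.phi.shape[0] < 2:
            raise ValueError("a trajectory needs at least 2 observations")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if not np.all(np.isfinite(self.phi)):
            raise ValueError("phases must be finite")
        if self.gamma is not None:
            self.gamma = np.asarray(self.gamma, dtype=float)
            if self.gamma.shape != self.phi.shape:
                raise ValueError("gamma must have the same shape as phi")

    @property
    def n_obs(self) -> int:
        return self.phi.shape[0]

    @property
    def p(self) -> int:
        return self.phi.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.delta * np.arange(self.n_obs)


@dataclass
class PlaneTrajectory:
    """Cartesian-coordinate view of an oscillating system, (x_k, y_k) interleaved."""

    xy: np.ndarray
    delta: float
    t0: float = 0.0

    @property
    def p(self) -> int:
        return self.xy.shape[1] // 2


def _noise_normals(rng, n, p, scale_vec):
    """Draw standard normals only for channels with positive noise scale."""
    out = np.zeros((n, p))
    active = scale_vec > 0
    if active.any():
        out[:, active] = rng.standard_normal((n, int(active.sum())))
    return out


def simulate_winfree(spec: OscillatorSystemSpec) -> PhaseTrajectory:
    """Simulate the noisy Winfree system by Euler-Maruyama at ``dt_fine``.

    Wiener increments for phase and amplitude are drawn from a single
    seeded generator (phases first, then amplitudes), so a polar and a
    Cartesian integration can share the same noise path.  Observations are
    recorded every ``dt_obs/dt_fine`` fine steps, N = T/dt_obs points
    covering [t0, t0+T).
    """
    if spec.kappa is None:
        raise ValueError("simulate_winfree requires kappa")
    if spec.gamma0 is None or np.any(spec.gamma0 <= 0):
        raise ValueError("gamma0 must be positive for the Winfree system")
    n_sub, n_obs = spec.n_sub, spec.n_obs
    n_fine = (n_obs - 1) * n_sub
    rng = np.random.default_rng(spec.seed)
    dWphi = _noise_normals(rng, n_fine, spec.p, spec.sigma_phi)
    dWgamma = _noise_normals(rng, n_fine, spec.p, spec.sigma_gamma)
    phi, gamma, neg = euler_winfree(
        spec.Pi, spec.omega, spec.kappa, spec.sigma_phi, spec.sigma_gamma,
        spec.dt_fine, n_sub, n_obs, spec.phi0.copy(), spec.gamma0.copy(),
        dWphi, dWgamma, spec.degeneracy_policy == "reflect",
    )
    if neg > 0 and spec.degeneracy_policy == "record":
        # static message so the default warning filter deduplicates; the
        # per-trajectory count is on the returned object
        warnings.warn(
            "amplitude reached a non-positive value during integration "
            "(see PhaseTrajectory.nonpositive_amplitude_events)",
            RuntimeWarning, stacklevel=2,
        )
    return PhaseTrajectory(phi=phi, gamma=gamma, delta=spec.dt_obs,
                           nonpositive_amplitude_events=int(neg))


def simulate_ou_phase_exact(Pi, mu, Sigma_phi, delta, N, phi0, seed=0) -> PhaseTrajectory:
    """Sample the degenerate-amplitude phase model from its exact transition.

    The continuous-time model d(phi) = (Pi phi + mu) dt + Sigma dW observed
    every ``delta`` time units is the Gaussian VAR(1)

        phi_n = exp(delta Pi) phi_{n-1} + delta mu + eps_n,
        eps_n ~ N(0, Omega),   Omega = int_0^delta e^{s Pi} Sigma Sigma' e^{s Pi'} ds.

    ``Sigma_phi`` may be a vector (diagonal scales) or a full p x p matrix.
    """
    from . import ctime  # local import to avoid a cycle at import time

    Pi = np.atleast_2d(np.asarray(Pi, dtype=float))
    p = Pi.shape[0]
    if Pi.shape != (p, p) or not np.all(np.isfinite(Pi)):
        raise ValueError("Pi must be a finite square matrix")
    mu = _as_vector(mu, p, "mu")
    phi0 = _as_vector(phi0, p, "phi0")
    Sigma = np.asarray(Sigma_phi, dtype=float)
    if Sigma.ndim < 2:
        Sigma = np.diag(_as_vector(Sigma, p, "Sigma_phi"))
    if not np.all(np.isfinite(Sigma)) or not np.all(np.isfinite(mu)):
        raise ValueError("parameters must be finite")
    from scipy.linalg import expm

    A = expm(delta * Pi)
    Omega = ctime.omega_from_sigma(Pi, Sigma, delta)
    # PSD square root via eigendecomposition (Omega may be singular when
    # some channels are noise-free)
    w, U = np.linalg.eigh(Omega)
    L = U * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((N - 1, p)) @ L.T
    paths = recursive_var_paths(A, delta * mu, phi0, eps[None, :, :])
    return PhaseTrajectory(phi=paths[0], delta=float(delta))


def simulate_ou_phase_euler(Pi, mu, sigma_phi, dt_fine, delta, N, phi0, seed=0) -> PhaseTrajectory:
    """Euler-Maruyama integration of the degenerate-amplitude phase model.

    Companion to :func:`simulate_ou_phase_exact`; mainly useful to quantify
    the discretisation error of the Euler scheme.  ``sigma_phi`` must be a
    vector of diagonal noise scales.
    """
    Pi = np.atleast_2d(np.asarray(Pi, dtype=float))
    p = Pi.shape[0]
    mu = _as_vector(mu, p, "mu")
    phi0 = _as_vector(phi0, p, "phi0")
    sphi = _as_vector(sigma_phi, p, "sigma_phi")
    n_sub = int(round(delta / dt_fine))
    if abs(delta / dt_fine - n_sub) > 1e-8 or n_sub < 1:
        raise ValueError("delta must be an integer multiple of dt_fine")
    rng = np.random.default_rng(seed)
    dW = _noise_normals(rng, (N - 1) * n_sub, p, sphi)
    phi = euler_linear(Pi, np.zeros(p), mu, sphi, dt_fine, n_sub, N, phi0.copy(), dW)
    return PhaseTrajectory(phi=phi, delta=float(delta))


def simulate_var(P, mu, Omega, N, phi0, seed=0, delta=1.0) -> PhaseTrajectory:
    """Simulate the discrete-time error-correction recursion directly.

    phi_n = phi_{n-1} + P phi_{n-1} + mu + eps_n with eps_n ~ N(0, Omega).
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    p = P.shape[0]
    mu = _as_vector(mu, p, "mu")
    phi0 = _as_vector(phi0, p, "phi0")
    Omega = np.atleast_2d(np.asarray(Omega, dtype=float))
    w, U = np.linalg.eigh(Omega)
    L = U * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((N - 1, p)) @ L.T
    paths = recursive_var_paths(np.eye(p) + P, mu, phi0, eps[None, :, :])
    return PhaseTrajectory(phi=paths[0], delta=float(delta))


# ---------------------------------------------------------------------------
# polar <-> Cartesian


def phases_to_plane(traj: PhaseTrajectory, amplitude=None) -> PlaneTrajectory:
    """Map (gamma, phi) to Cartesian coordinates x = gamma cos(phi), y = gamma sin(phi)."""
    if traj.gamma is not None:
        gamma = traj.gamma
    elif amplitude is not None:
        gamma = np.broadcast_to(np.asarray(amplitude, dtype=float), traj.phi.shape)
    else:
        raise ValueError("trajectory has no amplitudes and no constant amplitude was given")
    xy = np.empty((traj.n_obs, 2 * traj.p))
    xy[:, 0::2] = gamma * np.cos(traj.phi)
    xy[:, 1::2] = gamma * np.sin(traj.phi)
    return PlaneTrajectory(xy=xy, delta=traj.delta, t0=traj.t0)


def plane_to_phases(plane: PlaneTrajectory) -> PhaseTrajectory:
    """Inverse of :func:`phases_to_plane`; phases are wrapped to (-pi, pi]."""
    x = plane.xy[:, 0::2]
    y = plane.xy[:, 1::2]
    return PhaseTrajectory(phi=np.arctan2(y, x), gamma=np.hypot(x, y),
                           delta=plane.delta, t0=plane.t0)


def plane_drift(xk, yk, f_k, g_k, sigma_phi_k, sigma_gamma_k, cross_correction=True):
    """Drift and diffusion coefficients of the Cartesian DGP at one point.

    For a single oscillator at (x, y) with phase drift f_k, amplitude drift
    g_k and diagonal noise, the Cartesian dynamics are

        dz = [rotation(f_k) - (sigma_phi^2/2) I] z dt
             + (g_k + sigma_gamma sigma_phi)/r * z dt
             + sigma_phi J z dW_phi + (sigma_gamma / r) z dW_gamma,

    with r = sqrt(x^2+y^2) and J the 90-degree rotation.  Returns
    ``(drift, b_phi, b_gamma)`` where the b's are the coefficient vectors of
    the two Wiener increments.  Used as a consistency oracle against the
    polar-coordinate simulation.

    The default evaluates the form above including the radial
    sigma_gamma*sigma_phi/r correction.  The Ito image of the polar system
    driven by *independent* phase and amplitude Wiener processes has no such
    cross term (the quadratic covariation of phi and gamma vanishes);
    ``cross_correction=False`` drops it, which is the variant that agrees
    pathwise with the polar Euler scheme as the step size shrinks.
    """
    r = math.hypot(xk, yk)
    if r == 0.0:
        raise ValueError("plane drift is undefined at the origin")
    z = np.array([xk, yk], dtype=float)
    cross = sigma_gamma_k * sigma_phi_k if cross_correction else 0.0
    drift = (
        np.array([
            [-0.5 * sigma_phi_k**2, -f_k],
            [f_k, -0.5 * sigma_phi_k**2],
        ]) @ z
        + (g_k + cross) / r * z
    )
    b_phi = sigma_phi_k * np.array([-yk, xk])
    b_gamma = (sigma_gamma_k / r) * z
    return drift, b_phi, b_gamma


# ---------------------------------------------------------------------------
# Kuramoto drift and linearisations


def kuramoto_drift(phi, K, mu):
    """Kuramoto phase drift f_k = (1/p) sum_j K_kj sin(phi_j - phi_k) + mu_k."""
    phi = np.asarray(phi, dtype=float)
    p = phi.shape[0]
    if p < 2:
        raise ValueError("the Kuramoto model needs at least two oscillators")
    K = np.asarray(K, dtype=float)
    if K.ndim == 0:
        K = np.full((p, p), float(K))
    if K.shape != (p, p):
        raise ValueError(f"K must be scalar or {p}x{p}")
    mu = _as_vector(mu, p, "mu")
    diffs = np.sin(phi[None, :] - phi[:, None])  # (k, j) -> sin(phi_j - phi_k)
    return (K * diffs).sum(axis=1) / p + mu


def linearize_kuramoto_pairwise(alpha1, alpha2) -> np.ndarray:
    """Linearisation of the two-oscillator Kuramoto coupling around the in-phase state."""
    return 0.5 * np.array([[-alpha1, alpha1], [alpha2, -alpha2]], dtype=float)


def linearize_kuramoto_uniform(K, p) -> np.ndarray:
    """Linearisation of uniform all-to-all Kuramoto coupling: (K/p)(ones - p I)."""
    if p < 2:
        raise ValueError("p must be >= 2")
    return (K / p) * (np.ones((p, p)) - p * np.eye(p))
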