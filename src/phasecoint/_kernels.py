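"""Numba kernels for the tight inner loops.

Two loops dominate the runtime of every experiment: the Euler-Maruyama
integration of the oscillator SDEs (10^6 fine steps per trajectory) and the
recursive generation of bootstrap sample paths (M x N steps per rank test).
Both are plain per-step recursions that cannot be vectorised over time, so
they are compiled with numba.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def euler_winfree(
    Pi, omega, kappa, sphi, sgamma, dt, n_sub, n_obs, phi0, gamma0, dWphi, dWgamma, reflect
):
    """Euler-Maruyama integration of the noisy Winfree system.

    d(gamma_k) = (kappa_k - gamma_k) gamma_k^2 dt + sigma_k^gamma dW^gamma
    d(phi_k)   = (sum_j Pi_kj (phi_j - omega_j) + gamma_k) dt + sigma_k^phi dW^phi

    The state is advanced ``n_sub`` fine steps of size ``dt`` between
    consecutive recorded observations; ``dWphi``/``dWgamma`` are standard
    normal draws of shape ((n_obs-1)*n_sub, p).  Returns the recorded phase
    and amplitude arrays plus the count of fine steps on which an amplitude
    was driven to a non-positive value.
    """
    p = phi0.shape[0]
    phi = phi0.copy()
    gamma = gamma0.copy()
    out_phi = np.empty((n_obs, p))
    out_gamma = np.empty((n_obs, p))
    out_phi[0] = phi
    out_gamma[0] = gamma
    sdt = np.sqrt(dt)
    neg = 0
    idx = 0
    drift = np.empty(p)
    for n in range(1, n_obs):
        for _ in range(n_sub):
            for k in range(p):
                acc = gamma[k]
                for j in range(p):
                    acc += Pi[k, j] * (phi[j] - omega[j])
                drift[k] = acc
            for k in range(p):
                phi[k] = phi[k] + drift[k] * dt + sphi[k] * sdt * dWphi[idx, k]
                g = gamma[k]
                g = g + (kappa[k] - g) * g * g * dt + sgamma[k] * sdt * dWgamma[idx, k]
                if g <= 0.0:
                    neg += 1
                    if reflect:
                        g = abs(g)
                gamma[k] = g
            idx += 1
        out_phi[n] = phi
        out_gamma[n] = gamma
    return out_phi, out_gamma, neg


@njit(cache=True, fastmath=True)
def euler_linear(Pi, omega, mu, sphi, dt, n_sub, n_obs, phi0, dWphi):
    """Euler-Maruyama integration of the degenerate-amplitude phase model.

    d(phi) = (Pi (phi - omega) + mu) dt + diag(sigma^phi) dW
    """
    p = phi0.shape[0]
    phi = phi0.copy()
    out = np.empty((n_obs, p))
    out[0] = phi
    sdt = np.sqrt(dt)
    idx = 0
    drift = np.empty(p)
    for n in range(1, n_obs):
        for _ in range(n_sub):
            for k in range(p):
                acc = mu[k]
                for j in range(p):
                    acc += Pi[k, j] * (phi[j] - omega[j])
                drift[k] = acc
            for k in range(p):
                phi[k] = phi[k] + drift[k] * dt + sphi[k] * sdt * dWphi[idx, k]
            idx += 1
        out[n] = phi
    return out


@njit(cache=True, fastmath=True)
def recursive_var_paths(A, mu, phi0, eps):
    """Generate M recursive VAR(1) paths phi_n = A phi_{n-1} + mu + eps_n.

    ``eps`` has shape (M, T, p); each path starts at ``phi0`` and has T+1
    points.  Used for the residual bootstrap of the trace test.
    """
    M, T, p = eps.shape
    out = np.empty((M, T + 1, p))
    for m in range(M):
        out[m, 0] = phi0
        for n in range(T):
            out[m, n + 1] = A @ out[m, n] + mu + eps[m, n]
    return out
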