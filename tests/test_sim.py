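import numpy as np
import pytest
import scipy.stats

import phasecoint as pc
from phasecoint.experiments import winfree_spec
from phasecoint.sim import (
    OscillatorSystemSpec,
    linearize_kuramoto_pairwise,
    linearize_kuramoto_uniform,
    phases_to_plane,
    plane_drift,
    plane_to_phases,
    simulate_ou_phase_euler,
    simulate_var,
)


def _spec(**kw):
    base = dict(p=3, Pi=np.zeros((3, 3)), kappa=[0.75, 1.0, 1.0],
                sigma_phi=1.0, sigma_gamma=0.1, dt_fine=2e-4, dt_obs=0.1,
                T=20.0, seed=0)
    base.update(kw)
    return OscillatorSystemSpec(**base)


class TestWinfree:
    def test_noise_free_zero_coupling_is_linear_in_time(self):
        spec = _spec(sigma_phi=0.0, sigma_gamma=0.0, gamma0=[0.75, 1.0, 1.0])
        traj = pc.simulate_winfree(spec)
        t = traj.times[:, None]
        expected = spec.phi0[None, :] + np.array([0.75, 1.0, 1.0]) * t
        assert np.allclose(traj.phi, expected, atol=1e-9)
        assert np.allclose(traj.gamma, [0.75, 1.0, 1.0])

    def test_seed_fixes_trajectory_bitwise(self):
        a = pc.simulate_winfree(_spec(seed=5))
        b = pc.simulate_winfree(_spec(seed=5))
        assert np.array_equal(a.phi, b.phi) and np.array_equal(a.gamma, b.gamma)
        c = pc.simulate_winfree(_spec(seed=6))
        assert not np.array_equal(a.phi, c.phi)

    def test_increment_mean_matches_intrinsic_frequency(self, indep_traj):
        # independent system: E[dphi_k/dt] = E[gamma_k] ~ kappa_k
        inc = np.diff(indep_traj.phi, axis=0) / indep_traj.delta
        se = inc.std(axis=0, ddof=1) / np.sqrt(inc.shape[0])
        assert np.all(np.abs(inc.mean(axis=0) - [0.75, 1.0, 1.0]) < 3 * se)

    def test_default_initial_state_matches_study_configuration(self):
        spec = winfree_spec("independent")
        assert np.allclose(spec.phi0, [0.0, np.pi / 2, np.pi])
        assert np.allclose(spec.gamma0, 1.0)

    def test_coupled_difference_bounded_uncoupled_difference_grows(self):
        # phi1 - phi2 is a stationary relation under uni-directional coupling,
        # phi2 - phi3 is a random walk: its variance keeps growing with the window
        ratios_coupled, ratios_free = [], []
        for seed in range(20):
            traj = pc.simulate_winfree(winfree_spec("unidirectional", seed=seed))
            t = traj.times
            d12 = traj.phi[:, 0] - traj.phi[:, 1]
            d23 = traj.phi[:, 1] - traj.phi[:, 2]
            ratios_coupled.append(
                np.var(d12[(t >= 50)]) / np.var(d12[(t >= 50) & (t < 100)]))
            ratios_free.append(np.var(d23) / np.var(d23[t < 100]))
        assert np.mean(ratios_free) > 1.5
        assert np.mean(ratios_coupled) < 1.5

    def test_step_validation(self):
        with pytest.raises(ValueError, match="positive"):
            _spec(dt_fine=-1e-4)
        with pytest.raises(ValueError, match="multiple"):
            _spec(dt_fine=3e-4)
        with pytest.raises(ValueError, match="diagonal"):
            _spec(sigma_phi=np.eye(3))

    def test_degeneracy_policies(self):
        # large amplitude noise forces gamma through zero
        spec = _spec(sigma_gamma=1.0, T=50.0, seed=3)
        with pytest.warns(RuntimeWarning, match="non-positive"):
            traj = pc.simulate_winfree(spec)
        assert traj.nonpositive_amplitude_events > 0
        refl = pc.simulate_winfree(_spec(sigma_gamma=1.0, T=50.0, seed=3,
                                         degeneracy_policy="reflect"))
        assert refl.gamma.min() >= 0.0


class TestExactOU:
    def test_zero_drift_matrix_gives_random_walk_increments(self):
        mu = np.array([0.3, -0.2])
        sig = np.array([0.5, 1.5])
        traj = pc.simulate_ou_phase_exact(np.zeros((2, 2)), mu, sig, 0.1, 20000,
                                          [0.0, 0.0], seed=8)
        inc = np.diff(traj.phi, axis=0)
        assert np.allclose(inc.mean(axis=0), 0.1 * mu, atol=4 * sig * np.sqrt(0.1 / 20000))
        assert np.allclose(np.cov(inc.T), 0.1 * np.diag(sig**2), rtol=0.05, atol=5e-3)

    def test_scalar_innovation_variance_closed_form(self):
        # Pi = -1, sigma = 1, delta = 0.1: Omega = (1 - e^{-0.2})/2
        traj = pc.simulate_ou_phase_exact(-1.0, 0.0, 1.0, 0.1, 60000, 0.0, seed=9)
        resid = traj.phi[1:, 0] - np.exp(-0.1) * traj.phi[:-1, 0]
        target = (1 - np.exp(-0.2)) / 2
        assert np.isclose(resid.var(ddof=1), target, rtol=0.03)

    def test_exact_transition_agrees_with_fine_euler(self):
        # 400 independent scalar channels, one observation step each:
        # two-sample KS on the arrival values at alpha = 0.01
        p = 400
        Pi = -np.eye(p)
        mu = np.zeros(p)
        phi0 = np.full(p, 0.7)
        exact = pc.simulate_ou_phase_exact(Pi, mu, np.ones(p), 0.1, 2, phi0, seed=21)
        euler = simulate_ou_phase_euler(Pi, mu, np.ones(p), 1e-4, 0.1, 2, phi0, seed=22)
        stat = scipy.stats.ks_2samp(exact.phi[1], euler.phi[1])
        assert stat.pvalue > 0.01

    def test_nonfinite_parameters_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            pc.simulate_ou_phase_exact(np.array([[np.nan]]), 0.0, 1.0, 0.1, 10, 0.0)


class TestPlane:
    def test_polar_cartesian_map_points(self):
        traj = pc.PhaseTrajectory(phi=[[0.0], [np.pi / 2]], gamma=[[1.0], [2.0]], delta=1.0)
        plane = phases_to_plane(traj)
        assert np.allclose(plane.xy[0], [1.0, 0.0], atol=1e-15)
        assert np.allclose(plane.xy[1], [0.0, 2.0], atol=1e-15)

    def test_round_trip_recovers_polar_coordinates(self):
        rng = np.random.default_rng(0)
        phi = rng.uniform(0, 2 * np.pi, size=(50, 3))
        gamma = rng.uniform(0.5, 2.0, size=(50, 3))
        back = plane_to_phases(phases_to_plane(pc.PhaseTrajectory(phi=phi, gamma=gamma, delta=1.0)))
        assert np.allclose(back.gamma, gamma, atol=1e-12)
        assert np.allclose(np.mod(back.phi, 2 * np.pi) % (2 * np.pi),
                           phi % (2 * np.pi), atol=1e-10)

    def test_missing_amplitude_requires_constant(self):
        traj = pc.PhaseTrajectory(phi=np.zeros((5, 2)), delta=1.0)
        with pytest.raises(ValueError, match="amplitude"):
            phases_to_plane(traj)
        plane = phases_to_plane(traj, amplitude=1.0)
        assert np.allclose(plane.xy[:, 0::2], 1.0)

    def test_noise_free_drift_is_pure_rotation(self):
        drift, b_phi, b_gamma = plane_drift(0.3, 0.4, f_k=2.0, g_k=0.0,
                                            sigma_phi_k=0.0, sigma_gamma_k=0.0)
        assert np.allclose(drift, [-2.0 * 0.4, 2.0 * 0.3])
        assert np.allclose(b_phi, 0) and np.allclose(b_gamma, 0)

    def test_winfree_drift_at_equilibrium_amplitude(self):
        # at gamma = kappa the radial amplitude drift vanishes and only the
        # sigma_gamma*sigma_phi/gamma correction of the printed form remains
        kappa, sp, sg = 1.0, 0.3, 0.1
        drift, _, _ = plane_drift(kappa, 0.0, f_k=kappa, g_k=0.0,
                                  sigma_phi_k=sp, sigma_gamma_k=sg)
        radial = drift[0]  # at (kappa, 0) the x-component is radial
        assert np.isclose(radial, (-0.5 * sp**2 + sg * sp / kappa) * kappa)

    def test_origin_rejected(self):
        with pytest.raises(ValueError, match="origin"):
            plane_drift(0.0, 0.0, 1.0, 0.0, 0.1, 0.1)

    def test_plane_euler_converges_pathwise_to_polar_euler(self):
        # same Wiener path on both sides; the Ito-consistent drift variant is
        # used so the discrepancy is pure discretisation error
        kappa, sp, sg, T, fine = 1.0, 0.3, 0.3, 1.0, 1.25e-4

        def both(dt, dW1, dW2):
            phi, gam, x, y = 0.0, 1.0, 1.0, 0.0
            sdt = np.sqrt(dt)
            for i in range(dW1.shape[0]):
                f, g = gam, (kappa - gam) * gam**2
                r = np.hypot(x, y)
                drift, b1, b2 = plane_drift(x, y, f_k=r, g_k=(kappa - r) * r**2,
                                            sigma_phi_k=sp, sigma_gamma_k=sg,
                                            cross_correction=False)
                x, y = (x + drift[0] * dt + (b1[0] * dW1[i] + b2[0] * dW2[i]) * sdt,
                        y + drift[1] * dt + (b1[1] * dW1[i] + b2[1] * dW2[i]) * sdt)
                phi, gam = phi + f * dt + sp * sdt * dW1[i], gam + g * dt + sg * sdt * dW2[i]
            return np.hypot(gam * np.cos(phi) - x, gam * np.sin(phi) - y)

        errs = {}
        for dt in (2e-3, 5e-4):
            n, m = int(T / dt), int(dt / fine)
            per_path = []
            for path in range(8):
                rng = np.random.default_rng(100 + path)
                W1 = rng.standard_normal(int(T / fine))
                W2 = rng.standard_normal(int(T / fine))
                per_path.append(both(dt, W1.reshape(n, m).sum(axis=1) / np.sqrt(m),
                                     W2.reshape(n, m).sum(axis=1) / np.sqrt(m)))
            errs[dt] = np.mean(per_path)
        # quartering the step should at least halve the mean discrepancy
        assert errs[2e-3] / errs[5e-4] >= 2.0


class TestKuramoto:
    def test_equal_phases_drift_is_intrinsic_frequency(self):
        mu = np.array([0.5, 1.0, 1.5])
        assert np.allclose(pc.kuramoto_drift(np.full(3, 2.2), 1.3, mu), mu)

    def test_uniform_linearization_matrix(self):
        expected = np.array([[-2.0, 1.0, 1.0], [1.0, -2.0, 1.0], [1.0, 1.0, -2.0]]) / 3
        assert np.allclose(linearize_kuramoto_uniform(1.0, 3), expected)
        pair = linearize_kuramoto_pairwise(0.8, 0.6)
        assert np.allclose(pair, 0.5 * np.array([[-0.8, 0.8], [0.6, -0.6]]))

    def test_linearization_error_is_cubic_in_phase_spread(self):
        mu = np.zeros(3)
        Pi = linearize_kuramoto_uniform(1.0, 3)
        v = np.array([1.0, -0.3, 0.2])
        spreads = np.array([1e-3, 1e-2, 1e-1])
        ratios = []
        for s in spreads:
            phi = s * v
            err = np.linalg.norm(pc.kuramoto_drift(phi, 1.0, mu) - Pi @ phi)
            ratios.append(err / s**3)
        ratios = np.array(ratios)
        # cubic remainder: err/s^3 stable across two decades of spread
        assert ratios.max() / ratios.min() < 1.5

    def test_dimension_errors(self):
        with pytest.raises(ValueError):
            pc.kuramoto_drift(np.zeros(3), np.eye(2), np.zeros(3))
        with pytest.raises(ValueError):
            pc.kuramoto_drift(np.zeros(1), 1.0, np.zeros(1))


class TestDiscreteStationarity:
    @pytest.mark.parametrize("strength,bounded", [(0.5, True), (1.9, True), (2.5, False)])
    def test_two_oscillator_variance_boundary(self, strength, bounded):
        # P = a b' with a = (-a1, a2)', b = (1, -1)': the phase difference is
        # stationary iff 0 < a1 + a2 < 2 (discrete-time I(1) condition)
        a1 = a2 = strength / 2
        P = np.array([[-a1], [a2]]) @ np.array([[1.0, -1.0]])
        growth = []
        for seed in range(10):
            traj = simulate_var(P, [0.1, 0.1], 0.01 * np.eye(2), 400, [0.0, 0.0], seed=seed)
            d = traj.phi[:, 0] - traj.phi[:, 1]
            growth.append(np.var(d[200:]) / max(np.var(d[:200]), 1e-300))
        if bounded:
            assert np.median(growth) < 10
        else:
            assert np.median(growth) > 1e3
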