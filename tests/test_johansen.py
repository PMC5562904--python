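import numpy as np
import pytest
import scipy.linalg

import phasecoint as pc
from phasecoint import johansen
from phasecoint.johansen import DegenerateDataError

# small fixed integer dataset for oracle comparisons
TINY = np.array([
    [0.0, 1.0],
    [2.0, -1.0],
    [1.0, 3.0],
    [4.0, 2.0],
    [3.0, 5.0],
    [6.0, 4.0],
])


class TestConcentrate:
    def test_translation_leaves_moments_unchanged(self):
        m1 = johansen.concentrate(TINY)
        m2 = johansen.concentrate(TINY + np.array([7.0, -3.0]))
        for a, b in [(m1.S00, m2.S00), (m1.S01, m2.S01), (m1.S11, m2.S11)]:
            assert np.allclose(a, b, atol=1e-12)
        assert m1.T_eff == TINY.shape[0] - 1

    def test_constant_channel_is_degenerate(self):
        bad = TINY.copy()
        bad[:, 1] = 2.5
        with pytest.raises(DegenerateDataError):
            johansen.concentrate(bad)

    def test_duplicated_channel_is_degenerate(self):
        bad = np.column_stack([TINY[:, 0], TINY[:, 0]])
        with pytest.raises(DegenerateDataError):
            johansen.concentrate(bad)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="observations"):
            johansen.concentrate(TINY[:3])


class TestSolveRRR:
    def test_matches_dense_generalized_eigenproblem(self):
        m = johansen.concentrate(TINY)
        lams, V = johansen.solve_rrr(m)
        # brute-force oracle: eig of S10 S00^{-1} S01 against S11
        Mmat = m.S01.T @ np.linalg.solve(m.S00, m.S01)
        brute = np.sort(scipy.linalg.eig(Mmat, m.S11)[0].real)[::-1]
        assert np.allclose(lams, brute, atol=1e-12)
        assert np.allclose(V.T @ m.S11 @ V, np.eye(2), atol=1e-10)
        assert np.all((lams >= 0) & (lams < 1))

    def test_scalar_case_is_squared_correlation(self):
        rng = np.random.default_rng(11)
        phi = rng.standard_normal((300, 1))  # white noise in levels
        m = johansen.concentrate(phi)
        lams, _ = johansen.solve_rrr(m)
        d = np.diff(phi[:, 0])
        lag = phi[:-1, 0]
        rho = np.corrcoef(d - d.mean(), lag - lag.mean())[0, 1]
        assert np.isclose(lams[0], rho**2, atol=1e-12)


class TestTraceStat:
    def test_closed_forms_and_monotonicity(self):
        assert pc.trace_stat([0.0, 0.0], 0, 100) == 0.0
        assert np.isclose(pc.trace_stat([0.5], 0, 2), -2 * np.log(0.5))
        lams = np.array([0.3, 0.2, 0.05])
        stats = [pc.trace_stat(lams, r, 50) for r in range(4)]
        assert stats[-1] == 0.0
        assert np.all(np.diff(stats) <= 0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            pc.trace_stat([0.5], 2, 10)
        with pytest.raises(ValueError):
            pc.trace_stat([1.0], 0, 10)


class TestFitVECM:
    def test_full_rank_equals_ols(self, ou_uni_traj):
        m = johansen.concentrate(ou_uni_traj)
        fit = pc.fit_vecm(ou_uni_traj, 3)
        P_ols = np.linalg.lstsq(m.Z1c, m.Z0c, rcond=None)[0].T
        assert np.allclose(fit.P_hat, P_ols, atol=1e-10)

    def test_beta_top_block_is_identity(self, ou_uni_traj):
        for r in (1, 2):
            fit = pc.fit_vecm(ou_uni_traj, r)
            assert np.allclose(fit.beta_hat[:r, :], np.eye(r), atol=1e-12)
            assert np.linalg.matrix_rank(fit.P_hat, tol=1e-8) == r

    def test_loglik_gap_equals_trace_stat(self, ou_uni_traj):
        m = johansen.concentrate(ou_uni_traj)
        full = pc.fit_vecm(ou_uni_traj, 3, moments=m)
        for r in range(3):
            fit = pc.fit_vecm(ou_uni_traj, r, moments=m)
            gap = 2 * (full.loglik - fit.loglik)
            assert np.isclose(gap, pc.trace_stat(fit.eigenvalues, r, m.T_eff), atol=1e-8)
            assert fit.loglik <= full.loglik + 1e-10

    def test_estimates_invariant_under_translation(self, ou_uni_traj):
        c = np.array([5.0, -2.0, 1.0])
        a = pc.fit_vecm(ou_uni_traj, 1)
        b = pc.fit_vecm(ou_uni_traj.phi + c, 1)
        assert np.allclose(a.eigenvalues, b.eigenvalues, atol=1e-12)
        assert np.allclose(a.alpha_hat, b.alpha_hat, atol=1e-10)
        assert np.allclose(a.beta_hat, b.beta_hat, atol=1e-10)
        # the constant absorbs the shift of the equilibrium relation
        shift = a.alpha_hat @ (a.beta_hat.T @ c)
        assert np.allclose(b.mu_hat, a.mu_hat - shift, atol=1e-10)

    def test_recovers_unidirectional_coupling_parameters(self):
        # across seeds the normalized cointegration vector tends to (1, -1, 0)'
        # and the loadings of the two driving oscillators vanish
        from phasecoint.experiments import winfree_spec
        b2, b3, a2, a3 = [], [], [], []
        for seed in range(30):
            traj = pc.simulate_winfree(winfree_spec("unidirectional", seed=1000 + seed))
            f = pc.fit_vecm(traj, 1)
            b2.append(f.beta_hat[1, 0])
            b3.append(f.beta_hat[2, 0])
            a2.append(f.alpha_hat[1, 0] / traj.delta)
            a3.append(f.alpha_hat[2, 0] / traj.delta)
        assert abs(np.mean(b2) - (-1.0)) < 0.05
        assert abs(np.mean(b3)) < 0.05
        assert abs(np.mean(a2)) < 0.05 and abs(np.mean(a3)) < 0.05

    def test_rank_zero_model(self, ou_uni_traj):
        fit = pc.fit_vecm(ou_uni_traj, 0)
        assert fit.alpha_hat.shape == (3, 0)
        assert np.allclose(fit.P_hat, 0.0)
        assert np.allclose(fit.mu_hat, np.diff(ou_uni_traj.phi, axis=0).mean(axis=0))


class TestI1Conditions:
    def test_unidirectional_parameters_pass(self):
        res = pc.i1_conditions([[-0.5], [0.0], [0.0]], [[1.0], [-1.0], [0.0]])
        assert res["spectral_radius_ok"] and res["orth_complement_ok"]
        assert np.isclose(res["spectral_radius"], 0.5)

    @pytest.mark.parametrize("s,ok", [(-0.1, False), (0.1, True), (1.9, True), (2.1, False)])
    def test_two_oscillator_boundary(self, s, ok):
        a1 = a2 = s / 2
        res = pc.i1_conditions([[-a1], [a2]], [[1.0], [-1.0]])
        assert res["spectral_radius_ok"] == ok

    def test_explosive_case_fails(self):
        res = pc.i1_conditions([[1.0], [0.0], [0.0]], [[1.0], [0.0], [0.0]])
        assert not res["spectral_radius_ok"]

    def test_rank_deficient_rejected(self):
        with pytest.raises(ValueError, match="full column rank"):
            pc.i1_conditions(np.zeros((3, 1)), [[1.0], [0.0], [0.0]])
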