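"""The three mean-field systems and their integrator."""

import numpy as np
import pytest

from heteromf.bifurcation import find_equilibrium
from heteromf.heterogeneity import (DistributionSpec, HeterogeneitySpec,
                                    make_beta_grid)
from heteromf.meanfield import (MFI, MFII, MFIICurrent, MFIII,
                                conditional_mean_w, integrate_mf, mfi_rhs,
                                mfii_rhs, mfiii_rhs)
from heteromf.params import nondimensionalize


def _tonic_q(p_table):
    return nondimensionalize(p_table.with_(I_app=4500.0, g_syn=200.0))


class TestMFI:
    def test_pure_decay_when_quiescent(self, q_table):
        """With H < 0 everywhere and b = 0, w and s decay exponentially."""
        q = q_table.with_(I=0.0, g=0.0)
        system = MFI(q)
        sol = integrate_mf(system, [0.2, 0.3], (0.0, 50.0),
                           t_eval=np.linspace(0, 50, 200))
        assert np.allclose(sol.w_mean, 0.2 * np.exp(-q.a * sol.t), atol=1e-6)
        assert np.allclose(sol.s, 0.3 * np.exp(-sol.t / q.tau_s), atol=1e-6)

    def test_equilibrium_residual(self, p_table):
        system = MFI(_tonic_q(p_table))
        eq = find_equilibrium(system)
        assert np.max(np.abs(mfi_rhs(eq.state, system.q))) < 1e-10

    def test_steady_state_balance_relations(self, p_table):
        """At the tonic fixed point w* = tau_w w_jump R* and
        s* = tau_s s_jump R* (b = 0)."""
        q = _tonic_q(p_table)
        system = MFI(q)
        eq = find_equilibrium(system)
        R = system.mean_rate(eq.state)
        assert eq.state[0] == pytest.approx(q.tau_w * q.w_jump * R, abs=1e-8)
        assert eq.state[1] == pytest.approx(q.tau_s * q.s_jump * R, abs=1e-8)

    def test_regimes_match_published_simulations(self, p_table):
        """Fixed point at I_app = 4500 pA, limit cycle at 3500 pA
        (g_syn = 200 nS)."""
        tonic = MFI(_tonic_q(p_table))
        sol = integrate_mf(tonic, [0, 0], (0, 1500),
                           t_eval=np.linspace(1000, 1500, 800))
        assert sol.s.max() - sol.s.min() < 1e-6
        burst = MFI(nondimensionalize(p_table.with_(I_app=3500.0,
                                                    g_syn=200.0)))
        sol = integrate_mf(burst, [0, 0], (0, 1500),
                           t_eval=np.linspace(1000, 1500, 800))
        assert sol.s.max() - sol.s.min() > 0.1
        assert sol.R_mean.min() == 0.0      # bursting: rate vanishes

    def test_warns_for_fast_synapse(self, q_table):
        with pytest.warns(UserWarning, match="tau_s"):
            MFI(q_table.with_(tau_s=0.5))


class TestMFII:
    def test_degenerate_grid_reduces_to_mfi(self, p_table, q_table):
        het = HeterogeneitySpec(
            {"I_app": DistributionSpec("normal", mu=p_table.I_app,
                                       sigma=1e-9)})
        grid = make_beta_grid(het, p_table, 11, mode="deterministic")
        state = np.array([0.05, 0.1])
        assert np.allclose(mfii_rhs(state, grid, q_table),
                           mfi_rhs(state, q_table), atol=1e-10)

    def test_wjump_heterogeneity_is_exactly_mfi(self, p_table, q_table):
        """When only the adaptation jump is heterogeneous the conditional
        rate does not depend on beta, so the two reductions coincide."""
        het = HeterogeneitySpec(
            {"W_jump": DistributionSpec("normal", mu=200.0, sigma=50.0)})
        grid = make_beta_grid(het, p_table, 15, mode="deterministic")
        q = _tonic_q(p_table)
        t_eval = np.linspace(0, 2000, 1500)
        sol_i = integrate_mf(MFI(q), [0, 0], (0, 2000), t_eval=t_eval)
        sol_ii = integrate_mf(MFII(q, grid), [0, 0], (0, 2000), t_eval=t_eval)
        assert np.max(np.abs(sol_i.y - sol_ii.y)) < 1e-6

    def test_gauss_hermite_agrees_with_monte_carlo(self, p_table, q_table):
        het = HeterogeneitySpec(
            {"I_app": DistributionSpec("normal", mu=4500.0, sigma=1000.0)})
        gh = make_beta_grid(het, p_table, 20, mode="deterministic")
        mc = make_beta_grid(het, p_table, 10**5, mode="montecarlo", seed=4)
        state = (0.05, 0.15)
        q = _tonic_q(p_table)
        r_gh = MFII(q, gh).mean_rate(state)
        sys_mc = MFII(q, mc)
        R_j, _ = sys_mc.node_rates_and_v(*state)
        se = R_j.std() / np.sqrt(len(R_j))
        assert abs(r_gh - R_j.mean()) < 3 * se

    def test_smooth_current_variant_matches_dense_trapezoid(self, p_table):
        """The firing-region quadrature reproduces a brute-force trapezoid
        of the rate integral over the current density to near machine
        precision (unlike fixed-node quadrature of the hard-switched
        integrand, whose error decays slowly near the switching point)."""
        from scipy import stats
        from heteromf.core import firing_rate_izh
        q = _tonic_q(p_table)
        mu, sig = 4500.0 / (2.5 * 65**2), 1000.0 / (2.5 * 65**2)
        sc = MFIICurrent(q, mu_I=mu, sigma_I=sig)
        for w, s in ([0.05, 0.1], [0.1, 0.3], [0.3, 0.05]):
            x = (q.alpha + q.g * s) / 2.0
            I_star = w + x * x - q.g * q.e_r * s
            I = np.linspace(I_star + 1e-12, mu + 10 * sig, 2000001)
            ref = np.trapezoid(firing_rate_izh(w, s, I, q)
                               * stats.norm.pdf(I, mu, sig), I)
            assert sc.mean_rate((w, s)) == pytest.approx(ref, abs=1e-9)


class TestMFIII:
    def test_single_node_grid_is_mfi(self, p_table, q_table):
        grid = make_beta_grid(HeterogeneitySpec({}), p_table, 1)
        state = np.array([0.07, 0.12])
        got = mfiii_rhs(np.array([0.07, 0.12]), grid, q_table)
        want = mfi_rhs(state, q_table)
        assert np.allclose(got, want, atol=1e-14)

    def test_homogeneous_nodes_stay_equal(self, p_table):
        """With identical parameters and equal initial conditions, the
        adaptation field remains uniform for all time (symmetry)."""
        from heteromf.heterogeneity import BetaGrid
        q = _tonic_q(p_table)
        grid8 = BetaGrid(values={}, weights=np.full(8, 1 / 8))
        system = MFIII(q, grid8)
        sol = integrate_mf(system, system.uniform_state(0.02, 0.05),
                           (0, 500), t_eval=np.linspace(0, 500, 100))
        w_field = sol.y[:, :-1]
        assert np.max(w_field.std(axis=1)) < 1e-12

    def test_conditional_mean_readout(self, p_table):
        grid = make_beta_grid(
            HeterogeneitySpec({"I_app": DistributionSpec("normal",
                                                         mu=4500.0,
                                                         sigma=500.0)}),
            p_table, 4, mode="deterministic")
        state = np.array([0.0, 1.0, 0.0, 1.0, 0.3])
        w = grid.weights
        assert conditional_mean_w(state, grid) == pytest.approx(
            w[1] + w[3])
        assert conditional_mean_w(np.array([0.4, 0.4, 0.4, 0.4, 0.1]),
                                  grid) == pytest.approx(0.4)

    def test_sigma_to_zero_matches_mfi_trajectory(self, p_table):
        """Tonic regime, 2000-time-unit window: MFII and MFIII collapse
        onto MFI below 1e-4 sup-norm as the current spread vanishes."""
        q = _tonic_q(p_table)
        het = HeterogeneitySpec(
            {"I_app": DistributionSpec("normal", mu=4500.0, sigma=1e-4)})
        grid = make_beta_grid(het, p_table, 11, mode="deterministic")
        t_eval = np.linspace(0, 2000, 1200)
        sol_i = integrate_mf(MFI(q), [0, 0], (0, 2000), t_eval=t_eval)
        sol_ii = integrate_mf(MFII(q, grid), [0, 0], (0, 2000),
                              t_eval=t_eval)
        sys3 = MFIII(q, grid)
        sol_iii = integrate_mf(sys3, sys3.uniform_state(), (0, 2000),
                               t_eval=t_eval)
        assert np.max(np.abs(sol_ii.y - sol_i.y)) < 1e-4
        assert np.max(np.abs(sol_iii.w_mean - sol_i.w_mean)) < 1e-4
        assert np.max(np.abs(sol_iii.s - sol_i.s)) < 1e-4


def test_mfiii_amplitude_beats_mfi_near_rheobase(p_table):
    """Near-rheobase drive with broad current heterogeneity: the
    beta-conditioned reduction tracks the bursting network's adaptation
    amplitude much better than the homogeneous reduction, which only
    sees the mean current."""
    from heteromf.bursting import _rk4_run
    from heteromf.network import NetworkConfig, simulate_network
    p = p_table.with_(I_app=1200.0, g_syn=200.0)
    het = HeterogeneitySpec(
        {"I_app": DistributionSpec("normal", mu=1200.0, sigma=1000.0)})
    q = nondimensionalize(p)
    cfg = NetworkConfig(N=1000, params=p, het=het, T_sim=3000.0, dt=0.05,
                        seed=9)
    _, tr = simulate_network(cfg)
    tail = tr.t > 1500.0
    amp_net = tr.W_mean[tail].max() - tr.W_mean[tail].min()

    def mf_amp(system, wbar_of):
        y = _rk4_run(system, np.zeros(system.dim) if not isinstance(
            system, MFIII) else system.uniform_state(), 1000.0, 0.05)
        _, _, traj = _rk4_run(system, y, 800.0, 0.05, store_every=4)
        w = wbar_of(traj)
        return (w.max() - w.min()) * 2.5 * 65.0**2    # -> pA

    amp_i = mf_amp(MFI(q), lambda tr_: tr_[:, 0])
    grid = make_beta_grid(het, p, 400, mode="montecarlo", seed=2)
    amp_iii = mf_amp(MFIII(q, grid), lambda tr_: tr_[:, :-1] @ grid.weights)
    assert abs(amp_iii - amp_net) < abs(amp_i - amp_net)


class TestIntegrate:
    def test_zero_input_decays_to_origin(self, q_table):
        system = MFI(q_table.with_(I=0.0, g=0.0))
        sol = integrate_mf(system, [0.1, 0.1], (0, 4000))
        assert np.allclose(sol.final_state(), 0.0, atol=1e-6)

    def test_deterministic_and_tolerance_converged(self, p_table):
        """Halving tolerances moves the tonic-regime terminal state by
        less than 1e-6."""
        system = MFI(_tonic_q(p_table))
        a = integrate_mf(system, [0, 0], (0, 800), rtol=1e-8, atol=1e-8)
        b = integrate_mf(system, [0, 0], (0, 800), rtol=1e-8, atol=1e-8)
        c = integrate_mf(system, [0, 0], (0, 800), rtol=5e-9, atol=5e-9)
        assert np.array_equal(a.final_state(), b.final_state())
        assert np.max(np.abs(a.final_state() - c.final_state())) < 1e-6

    def test_rate_trace_nonnegative_and_s_nonnegative(self, p_table):
        system = MFI(nondimensionalize(p_table.with_(I_app=3500.0,
                                                     g_syn=200.0)))
        sol = integrate_mf(system, [0, 0], (0, 1500),
                           t_eval=np.linspace(0, 1500, 2000))
        assert np.all(sol.R_mean >= 0.0)
        # tiny negative excursions are dense-output interpolation wiggle
        assert sol.s.min() > -1e-8
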