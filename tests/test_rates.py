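"""Rate-distribution prediction, inversion, and parameter recovery."""

import numpy as np
import pytest
from scipy import stats

from heteromf.bifurcation import find_equilibrium
from heteromf.heterogeneity import DistributionSpec, HeterogeneitySpec
from heteromf.meanfield import MFI
from heteromf.params import nondimensionalize, rheobase
from heteromf.rates import (DensityEstimate, InvertibilityError, RangeError,
                            RateMap, histogram_density, invert_rate_density,
                            ks_distance, multiparam_rate_interpolation,
                            predict_rate_density, recover_individual_params,
                            smoothed_fI, steady_conditional_rate_map)


NORMAL_I = DistributionSpec("normal", mu=4500.0, sigma=1000.0)


@pytest.fixture(scope="module")
def p200(p_table=None):
    from heteromf.params import DimensionalParams
    return DimensionalParams(I_app=4500.0, g_syn=200.0)


@pytest.fixture(scope="module")
def imap(p200):
    het = HeterogeneitySpec({"I_app": NORMAL_I})
    return steady_conditional_rate_map(het, p200, M=200)


class TestRateMap:
    def test_homogeneous_map_is_mean_field_rate(self, p200):
        """Zero heterogeneity: every node carries the homogeneous
        steady-state rate."""
        het = HeterogeneitySpec(
            {"I_app": DistributionSpec("normal", mu=4500.0, sigma=1e-7)})
        rmap = steady_conditional_rate_map(het, p200, M=7)
        q = nondimensionalize(p200)
        system = MFI(q)
        R_star = system.mean_rate(find_equilibrium(system).state)
        assert np.allclose(rmap.rate * p200.time_unit, R_star, rtol=1e-6)

    def test_two_modes_agree_at_self_consistent_sbar(self, p200, imap):
        """Pinning s_bar at the converged mean rate reproduces the
        dynamical fixed point node by node."""
        het = HeterogeneitySpec({"I_app": NORMAL_I})
        q = nondimensionalize(p200)
        R_bar = np.nan
        # the dynamic map's mean rate (dimensionless)
        from heteromf.heterogeneity import make_beta_grid
        grid = make_beta_grid(het, p200, 200, mode="deterministic")
        from heteromf.meanfield import MFIII
        from heteromf.rates import _mfiii_steady_state
        system = MFIII(q, grid)
        R_bar = system.mean_rate(_mfiii_steady_state(system))
        fixed = steady_conditional_rate_map(het, p200, M=200,
                                            mode="from-fixed-sbar",
                                            R_bar=R_bar)
        assert np.allclose(fixed.rate, imap.rate, atol=1e-6)

    def test_map_increasing_in_current(self, imap):
        firing = imap.rate > 0
        assert np.all(np.diff(imap.rate[firing]) > 0)

    def test_oscillatory_regime_rejected(self):
        from heteromf.params import DimensionalParams
        from heteromf.rates import NotTonicError
        p = DimensionalParams(I_app=3500.0, g_syn=200.0)   # bursting
        het = HeterogeneitySpec(
            {"I_app": DistributionSpec("normal", mu=3500.0, sigma=100.0)})
        with pytest.raises(NotTonicError):
            steady_conditional_rate_map(het, p, M=40)


class TestPredictDensity:
    def test_linear_map_change_of_variables(self):
        """g(beta) = c beta maps rho_beta to rho_beta(r/c)/c."""
        c = 0.25
        beta = np.linspace(1.0, 9.0, 400)
        rmap = RateMap("I_app", beta, c * beta, s_bar=0.0)
        spec = DistributionSpec("normal", mu=5.0, sigma=0.8)
        dens = predict_rate_density(rmap, spec)
        expected = stats.norm.pdf(dens.grid / c, 5.0, 0.8) / c
        assert np.allclose(dens.density, expected, atol=1e-4)

    def test_density_normalized_nonnegative(self, imap):
        dens = predict_rate_density(imap, NORMAL_I)
        assert np.all(dens.density >= 0)
        assert np.trapezoid(dens.density, dens.grid) == pytest.approx(
            1.0, abs=1e-3)
        assert dens.grid.min() >= 0.0

    def test_non_monotone_map_rejected(self):
        beta = np.linspace(0, 1, 50)
        rmap = RateMap("I_app", beta, np.sin(6 * beta) + 2.0, s_bar=0.0)
        with pytest.raises(InvertibilityError):
            predict_rate_density(rmap, DistributionSpec("normal", mu=0.5,
                                                        sigma=0.2))


class TestSmoothedFI:
    def test_zero_spread_reduces_to_single_neuron_curve(self, q_table):
        from heteromf.core import firing_rate_izh
        spec = DistributionSpec("normal", mu=0.0, sigma=0.0)
        I = np.linspace(0.0, 0.5, 40)
        got = smoothed_fI(spec, I, q_table)
        want = firing_rate_izh(0.0, 0.0, I, q_table.with_(g=0.0))
        assert np.allclose(got, want, atol=1e-12)

    def test_spread_smooths_firing_onset(self, q_table):
        """With distributed currents the population rate is strictly
        positive below the rheobase."""
        I_rh = rheobase(q_table)
        spec = DistributionSpec("normal", mu=0.0, sigma=0.03)
        assert smoothed_fI(spec, I_rh - 0.01, q_table) > 0.0

    def test_quadrature_against_trapezoid(self, q_table):
        from heteromf.core import firing_rate_izh
        spec = DistributionSpec("normal", mu=0.0, sigma=0.02)
        for I_syn in (0.05, 0.1, 0.3):
            x = np.linspace(-6 * 0.02, 6 * 0.02, 400001)
            ref = np.trapezoid(
                firing_rate_izh(0.0, 0.0, x + I_syn, q_table.with_(g=0.0))
                * stats.norm.pdf(x, 0.0, 0.02), x)
            assert smoothed_fI(spec, I_syn, q_table) == pytest.approx(
                ref, abs=1e-8)


class TestInversion:
    def test_round_trip_recovers_normal_parameters(self, p200, imap):
        """invert(predict(rho_beta)) returns mu within 2% and sigma
        within 10%."""
        dens_R = predict_rate_density(imap, NORMAL_I)
        rec = invert_rate_density(dens_R, "I_app", p200)
        mu = rec.mean
        sig = np.sqrt(np.trapezoid((rec.grid - mu) ** 2 * rec.density,
                                   rec.grid))
        assert mu == pytest.approx(4500.0, rel=0.02)
        assert sig == pytest.approx(1000.0, rel=0.10)

    def test_narrow_input_concentrates_at_truth(self, p200):
        het = HeterogeneitySpec(
            {"I_app": DistributionSpec("normal", mu=4500.0, sigma=20.0)})
        rmap = steady_conditional_rate_map(het, p200, M=60)
        dens_R = predict_rate_density(rmap, het.specs["I_app"])
        rec = invert_rate_density(dens_R, "I_app", p200)
        assert rec.mean == pytest.approx(4500.0, rel=0.01)
        spread = np.sqrt(np.trapezoid((rec.grid - rec.mean) ** 2
                                      * rec.density, rec.grid))
        assert spread < 100.0

    def test_recover_exact_on_map_generated_rates(self, imap, rng):
        firing = imap.rate > 0
        sub = RateMap(imap.param, imap.beta[firing], imap.rate[firing],
                      imap.s_bar)
        g = sub.forward()
        beta_true = rng.uniform(sub.beta[0] + 50, sub.beta[-1] - 50, 200)
        beta_hat = recover_individual_params(g(beta_true), sub)
        assert np.max(np.abs(beta_hat - beta_true) / beta_true) < 1e-4

    def test_recovery_degrades_gracefully_under_rate_noise(self, imap, rng):
        firing = imap.rate > 0
        sub = RateMap(imap.param, imap.beta[firing], imap.rate[firing],
                      imap.s_bar)
        g = sub.forward()
        beta_true = rng.uniform(3000.0, 6000.0, 300)
        noisy = g(beta_true) * (1.0 + 0.01 * rng.standard_normal(300))
        beta_hat = recover_individual_params(noisy, sub)
        err = np.abs(beta_hat - beta_true) / beta_true
        assert err.mean() < 0.05

    def test_out_of_range_rates(self, imap):
        firing = imap.rate > 0
        sub = RateMap(imap.param, imap.beta[firing], imap.rate[firing],
                      imap.s_bar)
        big = np.array([sub.rate.max() * 2.0])
        with pytest.raises(RangeError):
            recover_individual_params(big, sub, clamp=False)
        with pytest.warns(UserWarning, match="clamping"):
            out = recover_individual_params(big, sub)
        assert out[0] == pytest.approx(sub.beta[-1])


class TestDensityUtilities:
    def test_histogram_density_normalized(self, rng):
        d = histogram_density(rng.normal(3.0, 1.0, 4000))
        assert np.trapezoid(d.density, d.grid) == pytest.approx(1.0, abs=1e-3)

    def test_ks_distance_of_matching_sample_is_small(self, rng):
        x = np.linspace(-5, 5, 2001)
        dens = DensityEstimate(grid=x, density=stats.norm.pdf(x))
        sample = rng.standard_normal(4000)
        assert ks_distance(dens, sample) < 0.03

    def test_mode_count(self):
        x = np.linspace(-8, 8, 1001)
        uni = DensityEstimate(grid=x, density=stats.norm.pdf(x))
        bi = DensityEstimate(grid=x, density=stats.norm.pdf(x, -3)
                             + stats.norm.pdf(x, 3))
        assert uni.mode_count() == 1
        assert bi.mode_count() == 2


class TestMultiParam:
    def test_degenerate_single_parameter_consistent_with_map(self, p200):
        """Monte Carlo multi-parameter sampling with one parameter agrees
        with the conditional rate map at the sampled points."""
        het = HeterogeneitySpec({"I_app": NORMAL_I})
        mp = multiparam_rate_interpolation(het, p200, M=150, seed=2)
        rmap = steady_conditional_rate_map(het, p200, M=300)
        firing = rmap.rate > 0
        sub = RateMap("I_app", rmap.beta[firing], rmap.rate[firing],
                      rmap.s_bar)
        g = sub.forward()
        inside = (mp.samples["I_app"] > sub.beta[0]) & \
                 (mp.samples["I_app"] < sub.beta[-1]) & (mp.rates > 0)
        pred = g(mp.samples["I_app"][inside])
        assert np.allclose(pred, mp.rates[inside], rtol=0.02)

    def test_interpolation_matches_direct_rate_at_held_out_points(self, p200):
        het = HeterogeneitySpec({
            "I_app": DistributionSpec("normal", mu=5500.0, sigma=400.0),
            "g_syn": DistributionSpec("normal", mu=200.0, sigma=30.0)})
        mp = multiparam_rate_interpolation(het, p200, M=400, seed=6)
        mp2 = multiparam_rate_interpolation(het, p200, M=60, seed=7)
        pred = mp.predict(mp2.samples)
        rel = np.abs(pred - mp2.rates) / mp2.rates
        assert np.median(rel) < 0.01
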