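"""Long-timescale reversible-mutation Wright-Fisher model."""

import math

import numpy as np
import pytest
from scipy import integrate

from basecomp.containers import SpectrumSet
from basecomp.popgen import MutationScheme, equilibrium_gc
from basecomp.zc import (
    FrequencyGrid,
    ZcParams,
    fit_zc,
    stationary_sample_probs,
    transient_sample_probs,
    zc_loglik,
    zc_model_tests,
    zc_param_count,
)


def multinomial_spectrum(p: ZcParams, n: int, sites: int, seed: int) -> SpectrumSet:
    """Model-drawn dataset (exact sampling distribution, no forward sim)."""
    rng = np.random.default_rng(seed)
    probs = transient_sample_probs(p, n, FrequencyGrid(100))
    hist = rng.multinomial(sites, probs).astype(float)
    return SpectrumSet(n=n, ws=hist[1:n], sw=np.zeros(n - 1),
                       neu=np.zeros(n - 1), fixed_w=hist[0], fixed_s=hist[n])


class TestStationary:
    def test_neutral_symmetric(self):
        p = ZcParams(gamma=0.0, theta=0.05, kappa=1.0)
        probs = stationary_sample_probs(p, 12)
        assert np.allclose(probs, probs[::-1], atol=1e-12)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_beta_integral_oracle(self):
        """gamma=0 reduces Wright's density to a Beta; direct quadrature of
        the binomial mixture is the oracle."""
        p = ZcParams(gamma=0.0, theta=0.01, kappa=1.0)
        probs = stationary_sample_probs(p, 2)
        a, b = 0.01, 0.01
        oracle = []
        for i in range(3):
            val, _ = integrate.quad(
                lambda x: math.comb(2, i) * x**(i + a - 1)
                * (1 - x)**(2 - i + b - 1), 0, 1)
            oracle.append(val)
        oracle = np.array(oracle) / sum(oracle)
        assert np.abs(probs - oracle).max() < 1e-8

    def test_selected_quadrature_oracle(self):
        p = ZcParams(gamma=1.5, theta=0.05, kappa=2.0)
        n = 6
        probs = stationary_sample_probs(p, n)
        a, b = p.theta, p.kappa * p.theta
        oracle = []
        for i in range(n + 1):
            val, _ = integrate.quad(
                lambda x: math.comb(n, i) * np.exp(p.gamma * x)
                * x**(i + a - 1) * (1 - x)**(n - i + b - 1), 0, 1)
            oracle.append(val)
        oracle = np.array(oracle) / sum(oracle)
        assert np.abs(probs - oracle).max() < 1e-8

    def test_low_theta_boundary_odds(self):
        """As theta -> 0 the fixed-class odds approach e^gamma / kappa, the
        Li-Bulmer equilibrium odds of GC vs AT."""
        target = math.exp(1.0) / 2.0
        errs = []
        for theta in (1e-2, 1e-3, 1e-4):
            p = ZcParams(gamma=1.0, theta=theta, kappa=2.0)
            probs = stationary_sample_probs(p, 10)
            errs.append(abs(probs[10] / probs[0] - target))
        assert errs[-1] < 5e-3 * target
        assert errs[0] > errs[-1]  # converging in the limit

    def test_cross_module_equilibrium_gc(self):
        gamma, kappa = 1.3, 2.5
        q = equilibrium_gc(MutationScheme(u=kappa, v=1.0), gamma)
        p = ZcParams(gamma=gamma, theta=1e-4, kappa=kappa)
        probs = stationary_sample_probs(p, 20)
        q_fix = probs[20] / (probs[0] + probs[20])
        assert q_fix == pytest.approx(q, abs=2e-3)


class TestTransient:
    def test_probabilities_normalized_everywhere(self):
        grid = FrequencyGrid(60)
        for gamma, tau, g in [(0.0, 0.3, 1.0), (2.0, 1.5, 3.0),
                              (-1.0, 0.05, 0.5)]:
            p = ZcParams(gamma=gamma, theta=0.02, kappa=2.0, g=g, tau=tau)
            probs = transient_sample_probs(p, 15, grid)
            assert probs.min() >= 0.0
            assert probs.sum() == pytest.approx(1.0, abs=1e-10)

    def test_tau_zero_equals_ancestral_stationary(self):
        p = ZcParams(gamma=1.0, theta=0.02, kappa=2.0, g=2.0, tau=0.0)
        out = transient_sample_probs(p, 20, FrequencyGrid(100))
        ref = stationary_sample_probs(p, 20, epoch="ancestral")
        assert np.abs(out - ref).max() < 1e-8

    def test_large_tau_reaches_current_stationary(self):
        p = ZcParams(gamma=1.0, theta=0.02, kappa=2.0, g=2.0, tau=12.0)
        out = transient_sample_probs(p, 20, FrequencyGrid(100))
        ref = stationary_sample_probs(p, 20, epoch="current")
        assert np.abs(out - ref).max() < 1e-6

    def test_forward_simulation_oracle_single_point(self):
        from basecomp.simulate import simulate_wf_sites
        p = ZcParams(gamma=1.0, theta=0.02, kappa=2.0, g=2.0, tau=0.5)
        spec, _ = simulate_wf_sites(p, sites=30_000, n=20, seed=9, N0=100)
        emp = spec.s_allele_counts()
        emp /= emp.sum()
        pred = transient_sample_probs(p, 20, FrequencyGrid(100))
        tv = 0.5 * np.abs(emp - pred).sum()
        assert tv < 0.02  # MC noise at 30k sites plus O(1/N) rescaling error

    def test_grid_refinement_stability(self):
        """Sampling distributions (hence likelihoods and estimates) are
        stable once the grid is at least ~200."""
        p = ZcParams(gamma=1.0, theta=0.02, kappa=2.0, g=2.0, tau=0.5)
        a = transient_sample_probs(p, 20, FrequencyGrid(200))
        b = transient_sample_probs(p, 20, FrequencyGrid(300))
        assert np.abs(a - b).max() < 1e-3


class TestLoglik:
    def test_degenerate_all_fixed_w_is_finite(self):
        n = 10
        spec = SpectrumSet(n=n, ws=np.zeros(n - 1), sw=np.zeros(n - 1),
                           neu=np.zeros(n - 1), fixed_w=1000.0)
        p = ZcParams(gamma=0.5, theta=0.01, kappa=2.0)
        ll = zc_loglik(p, spec, FrequencyGrid(50))
        assert np.isfinite(ll)

    def test_multinomial_identity_under_count_scaling(self):
        p = ZcParams(gamma=0.5, theta=0.02, kappa=1.5)
        spec = multinomial_spectrum(p, 12, 10_000, seed=3)
        double = SpectrumSet(n=12, ws=2 * spec.ws, sw=2 * spec.sw,
                             neu=2 * spec.neu, fixed_w=2 * spec.fixed_w,
                             fixed_s=2 * spec.fixed_s)
        grid = FrequencyGrid(60)
        assert zc_loglik(p, double, grid) == pytest.approx(
            2.0 * zc_loglik(p, spec, grid), rel=1e-12)

    def test_truth_nearly_maximizes_on_large_model_draw(self):
        p = ZcParams(gamma=1.0, theta=0.02, kappa=2.0)
        spec = multinomial_spectrum(p, 20, 500_000, seed=4)
        grid = FrequencyGrid(100)
        ll_true = zc_loglik(p, spec, grid)
        worse = ZcParams(gamma=0.0, theta=0.02, kappa=2.0)
        assert ll_true > zc_loglik(worse, spec, grid)


class TestFitting:
    def test_param_counts(self):
        assert zc_param_count("ZC1") == 5
        assert zc_param_count("ZC0") == 4
        assert zc_param_count("ZC1c") == 3
        assert zc_param_count("ZC0c") == 2

    def test_recovery_on_model_drawn_data(self):
        p = ZcParams(gamma=1.0, theta=0.02, kappa=2.0)
        spec = multinomial_spectrum(p, 20, 300_000, seed=6)
        fit = fit_zc(spec, "ZC1", restarts=2, seed=0, grid=FrequencyGrid(60))
        assert 0.8 <= fit.params["gamma"] <= 1.2
        assert 1.6 <= fit.params["kappa"] <= 2.4

    def test_zc1_nests_zc0(self):
        p = ZcParams(gamma=0.5, theta=0.02, kappa=2.0)
        spec = multinomial_spectrum(p, 15, 50_000, seed=8)
        grid = FrequencyGrid(60)
        f1 = fit_zc(spec, "ZC1", restarts=2, seed=0, grid=grid)
        f0 = fit_zc(spec, "ZC0", restarts=2, seed=0, grid=grid)
        assert f1.loglik >= f0.loglik - 1e-6
        tests = zc_model_tests({"ZC1": f1, "ZC0": f0})
        assert tests["ZC1 vs ZC0"]["df"] == 1

    def test_expansion_detected(self):
        """Data simulated with a recent 5x expansion (ancestral size g=5
        relative to... g>1 means a larger past population, i.e. a
        contraction; expansion is g<1) rejects the constant-size model."""
        p = ZcParams(gamma=1.0, theta=0.02, kappa=2.0, g=5.0, tau=0.2)
        spec = multinomial_spectrum(p, 20, 200_000, seed=10)
        grid = FrequencyGrid(60)
        f1 = fit_zc(spec, "ZC1", restarts=3, seed=0, grid=grid)
        f1c = fit_zc(spec, "ZC1c", restarts=3, seed=0, grid=grid)
        tests = zc_model_tests({"ZC1": f1, "ZC1c": f1c})
        assert tests["ZC1 vs ZC1c"]["df"] == 2
        assert tests["ZC1 vs ZC1c"]["p"] < 1e-4

    def test_mismatched_data_raises(self):
        p = ZcParams(gamma=0.5, theta=0.02, kappa=2.0)
        s1 = multinomial_spectrum(p, 12, 10_000, seed=1)
        s2 = multinomial_spectrum(p, 12, 20_000, seed=2)
        grid = FrequencyGrid(50)
        f1 = fit_zc(s1, "ZC1", restarts=1, seed=0, grid=grid)
        f0 = fit_zc(s2, "ZC0", restarts=1, seed=0, grid=grid)
        with pytest.raises(ValueError, match="identical data"):
            zc_model_tests({"ZC1": f1, "ZC0": f0})
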