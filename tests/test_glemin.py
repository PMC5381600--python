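"""Short-timescale (polarized-SFS Poisson field) selection model."""

import math

import numpy as np
import pytest
from scipy import integrate

from basecomp.containers import SpectrumSet
from basecomp.glemin import (
    GleminParams,
    estimate_kappa_glemin,
    expected_sfs_glemin,
    fit_glemin,
    glemin_loglik,
    glemin_model_selection,
    glemin_param_count,
    sfs_integral,
)
from basecomp.simulate import simulate_prf_spectra


def quad_oracle(gamma, n):
    """Adaptive-quadrature evaluation of the binomial-weighted frequency
    integral, independent of the closed form used by the implementation."""
    out = []
    for i in range(1, n):
        def f(x):
            H = (1 - np.exp(-gamma * (1 - x))) / ((1 - np.exp(-gamma))
                                                  * x * (1 - x))
            return math.comb(n, i) * x**i * (1 - x)**(n - i) * H
        val, _ = integrate.quad(f, 0.0, 1.0)
        out.append(val)
    return np.array(out)


class TestExpectedSfs:
    def test_neutral_closed_form(self):
        n = 12
        p = GleminParams(gamma=0.0, theta_ws=3.0, theta_sw=5.0, theta_neu=7.0,
                         r=np.ones(n - 2))
        means = expected_sfs_glemin(p)
        i = np.arange(1, n)
        assert np.allclose(means["WS"], 3.0 / i)
        assert np.allclose(means["SW"], 5.0 / i)
        assert np.allclose(means["neu"], 7.0 / i)

    @pytest.mark.parametrize("gamma", [2.0, -3.0, 0.5])
    def test_quadrature_oracle(self, gamma):
        n = 10
        assert np.abs(sfs_integral(gamma, n) - quad_oracle(gamma, n)).max() < 1e-8

    def test_continuous_through_zero(self):
        n = 15
        lo = sfs_integral(-1e-7, n)
        mid = sfs_integral(0.0, n)
        hi = sfs_integral(1e-7, n)
        assert np.abs(lo - mid).max() < 1e-6
        assert np.abs(hi - mid).max() < 1e-6

    def test_full_mixing_symmetry(self):
        n = 11
        p = GleminParams(gamma=1.5, theta_ws=2.0, theta_sw=3.0, theta_neu=1.0,
                         r=np.ones(n - 2), e_sel=0.5, e_neu=0.1, variant="M1*")
        means = expected_sfs_glemin(p)
        assert np.allclose(means["WS"], means["SW"][::-1])

    def test_distortion_factors_scale_classes(self):
        n = 8
        r = np.linspace(1.5, 0.5, n - 2)
        p = GleminParams(gamma=0.0, theta_ws=1.0, theta_sw=1.0, theta_neu=1.0,
                         r=r)
        means = expected_sfs_glemin(p)
        i = np.arange(1, n)
        assert np.allclose(means["neu"], np.concatenate([[1.0], r]) / i)

    def test_mean_daf_increases_with_gamma(self):
        n = 20
        i = np.arange(1, n)
        prev = -np.inf
        for gamma in np.linspace(0.0, 6.0, 13):
            xi = sfs_integral(gamma, n)
            daf = float(np.sum(i / n * xi) / xi.sum())
            assert daf > prev
            prev = daf


class TestLoglik:
    def _spec(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        return SpectrumSet(n=n, ws=rng.poisson(50, n - 1).astype(float),
                           sw=rng.poisson(80, n - 1).astype(float),
                           neu=rng.poisson(60, n - 1).astype(float))

    def test_score_zero_at_fitted_theta(self):
        """With data equal to the neutral expectation, the profile theta
        maximizes the Poisson likelihood exactly at the generating value."""
        n = 10
        theta = 40.0
        xi = theta / np.arange(1, n)
        spec = SpectrumSet(n=n, ws=xi, sw=xi, neu=xi)
        fit = fit_glemin(spec, "M0", seed=0)
        for key in ("theta_ws", "theta_sw", "theta_neu"):
            assert fit.params[key] == pytest.approx(theta, rel=1e-6)
        assert np.allclose(fit.params["r"], 1.0, atol=1e-6)

    def test_poisson_scaling_identity(self):
        spec = self._spec()
        n = spec.n
        p1 = GleminParams(gamma=1.0, theta_ws=30.0, theta_sw=40.0,
                          theta_neu=50.0, r=np.ones(n - 2))
        p2 = GleminParams(gamma=1.0, theta_ws=60.0, theta_sw=80.0,
                          theta_neu=100.0, r=np.ones(n - 2))
        double = SpectrumSet(n=n, ws=2 * spec.ws, sw=2 * spec.sw,
                             neu=2 * spec.neu)
        ll1 = glemin_loglik(p1, spec)
        ll2 = glemin_loglik(p2, double)
        total = spec.total_segregating()
        assert ll2 == pytest.approx(2 * ll1 + 2 * math.log(2) * total, rel=1e-12)

    def test_empty_spectra_contribute_only_means(self):
        n = 8
        empty = SpectrumSet(n=n, ws=np.zeros(n - 1), sw=np.zeros(n - 1),
                            neu=np.zeros(n - 1))
        p = GleminParams(gamma=0.0, theta_ws=2.0, theta_sw=2.0, theta_neu=2.0,
                         r=np.ones(n - 2))
        means = expected_sfs_glemin(p)
        expected = -sum(m.sum() for m in means.values())
        assert glemin_loglik(p, empty) == pytest.approx(expected)


class TestFitting:
    def test_parameter_counts(self):
        assert glemin_param_count("M1*", 21) == 25
        assert glemin_param_count("M1*", 17) == 21
        assert glemin_param_count("M0", 21) == 22
        assert glemin_param_count("M1", 21) == 23
        assert glemin_param_count("M0*", 21) == 24

    def test_gamma_recovery_single_seed(self):
        n = 20
        p = GleminParams(gamma=2.0, theta_ws=3000.0, theta_sw=5000.0,
                         theta_neu=4000.0, r=np.ones(n - 2))
        spec, _ = simulate_prf_spectra(p, seed=11)
        fit = fit_glemin(spec, "M1", seed=0)
        assert 1.6 <= fit.params["gamma"] <= 2.4

    def test_kappa_recovery(self):
        """theta ratios normalized by ancestral site totals recover the
        mutational bias: kappa=2 planted with Q=1/3 (twice as many W sites)."""
        n = 20
        LW, LS = 200_000.0, 100_000.0
        theta_site = 0.02
        p = GleminParams(gamma=0.0, theta_ws=theta_site * LW,
                         theta_sw=2 * theta_site * LS,
                         theta_neu=1000.0, r=np.ones(n - 2))
        spec, _ = simulate_prf_spectra(p, seed=5)
        fit = fit_glemin(spec, "M0", seed=0)
        kappa = estimate_kappa_glemin(fit, LW=LW, LS=LS)
        assert kappa == pytest.approx(2.0, rel=0.1)

    def test_kappa_trivial_identities(self):
        from basecomp.containers import ModelFit
        fit = ModelFit(model="M0", params={"theta_ws": 1.0, "theta_sw": 2.0},
                       loglik=0.0, n_params=1)
        assert estimate_kappa_glemin(fit, LW=10, LS=10) == pytest.approx(2.0)
        fit.params["theta_sw"] = 1.0
        assert estimate_kappa_glemin(fit, LW=10, LS=10) == pytest.approx(1.0)

    def test_starred_fit_recovers_polarization_error(self):
        n = 16
        p = GleminParams(gamma=1.5, theta_ws=4000.0, theta_sw=6000.0,
                         theta_neu=5000.0, r=np.ones(n - 2),
                         e_sel=0.15, e_neu=0.1, variant="M1*")
        spec, _ = simulate_prf_spectra(p, seed=2)
        fit = fit_glemin(spec, "M1*", restarts=2, seed=0)
        assert fit.params["e_sel"] == pytest.approx(0.15, abs=0.05)
        assert fit.params["gamma"] == pytest.approx(1.5, abs=0.5)

    def test_nested_lrt_nonnegative_and_aic_identity(self):
        n = 12
        p = GleminParams(gamma=0.0, theta_ws=500.0, theta_sw=600.0,
                         theta_neu=700.0, r=np.ones(n - 2))
        spec, _ = simulate_prf_spectra(p, seed=9)
        f0 = fit_glemin(spec, "M0", seed=0)
        f1 = fit_glemin(spec, "M1", seed=0)
        sel = glemin_model_selection({"M0": f0, "M1": f1})
        assert sel["lrt"]["M1 vs M0"]["chi2"] >= 0.0
        assert f1.aic - f0.aic == pytest.approx(
            2.0 - 2.0 * (f1.loglik - f0.loglik))

    def test_requires_two_nonempty_categories(self):
        n = 6
        spec = SpectrumSet(n=n, ws=np.ones(n - 1), sw=np.zeros(n - 1),
                           neu=np.zeros(n - 1))
        with pytest.raises(ValueError, match="two categories"):
            fit_glemin(spec, "M1")
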