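"""Ancestral reconstruction: pruning likelihoods, posteriors, parsimony."""

import itertools

import numpy as np
import pytest
from scipy import stats

from basecomp.ancestry import (
    BRANCHES,
    N_PARAMS_NH,
    N_PARAMS_STATIONARY,
    StationaryGtrModel,
    TripletPatternCounts,
    ancestral_posteriors,
    fit_nh_gtr,
    fit_stationary_gtr,
    lrt_nonstationarity,
    nh_model_from_fit,
    parsimony_ancestor,
    transition_probs,
)
from basecomp.containers import ModelFit
from basecomp.simulate import make_nonstationary_model, simulate_triplet_alignment
from basecomp.substitution import count_substitutions_patterns

from conftest import random_nh_model


def brute_force_pattern_probs(model):
    """Enumerate (root, ms) ancestral states explicitly — the oracle the
    einsum-based pruning computation must match."""
    P = {b: transition_probs(model.exch[b], model.freqs[b], model.lengths[b])
         for b in BRANCHES}
    probs = np.zeros((4, 4, 4))
    for m, s, y in itertools.product(range(4), repeat=3):
        total = 0.0
        for r in range(4):
            for a in range(4):
                total += (model.root_freqs[r] * P["root_ms"][r, a]
                          * P["ms_mel"][a, m] * P["ms_sim"][a, s]
                          * P["root_yak"][r, y])
        probs[m, s, y] = total
    return probs


class TestLikelihoodOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_pruning_equals_enumeration(self, seed):
        from basecomp.ancestry import _pattern_probs_nh
        model = random_nh_model(seed)
        fast = _pattern_probs_nh(model)
        slow = brute_force_pattern_probs(model)
        assert np.abs(fast - slow).max() < 1e-10
        assert fast.sum() == pytest.approx(1.0, abs=1e-10)

    def test_stationary_probs_sum_to_one(self):
        from basecomp.ancestry import _pattern_probs_stationary
        model = StationaryGtrModel(
            exch=np.array([1.0, 2.0, 1.0, 1.0, 2.0, 1.0]),
            freqs=np.array([0.3, 0.2, 0.2, 0.3]),
            lengths=np.array([0.1, 0.12, 0.3]))
        probs = _pattern_probs_stationary(model)
        assert probs.sum() == pytest.approx(1.0, abs=1e-10)


class TestPosteriors:
    def test_posterior_matches_enumeration(self):
        model = random_nh_model(7)
        post = ancestral_posteriors(model, "AWP")
        P = {b: transition_probs(model.exch[b], model.freqs[b],
                                 model.lengths[b]) for b in BRANCHES}
        for m, s, y in itertools.product(range(4), repeat=3):
            brute = np.zeros(4)
            for a in range(4):
                for r in range(4):
                    brute[a] += (model.root_freqs[r] * P["root_ms"][r, a]
                                 * P["ms_mel"][a, m] * P["ms_sim"][a, s]
                                 * P["root_yak"][r, y])
            brute /= brute.sum()
            assert np.abs(post.probs[m, s, y] - brute).max() < 1e-12

    def test_posterior_vectors_sum_to_one(self):
        post = ancestral_posteriors(random_nh_model(3), "AWP")
        assert np.allclose(post.probs.sum(axis=-1), 1.0)

    def test_monomorphic_pattern_mode_at_shared_base(self):
        post = ancestral_posteriors(random_nh_model(11), "AWP")
        for b in range(4):
            assert post.probs[b, b, b].argmax() == b

    def test_short_branches_give_degenerate_posterior(self):
        model = make_nonstationary_model("stationary")
        for br in BRANCHES:
            model.lengths[br] = 1e-6
        post = ancestral_posteriors(model, "AWP")
        for b in range(4):
            assert post.probs[b, b, b, b] > 0.999

    def test_sbr_is_argmax_of_awp(self):
        model = random_nh_model(5)
        awp = ancestral_posteriors(model, "AWP")
        sbr = ancestral_posteriors(model, "SBR")
        assert np.all(sbr.probs.argmax(-1) == awp.probs.argmax(-1))
        assert np.allclose(sbr.probs.sum(-1), 1.0)


class TestParsimony:
    def test_majority_base(self):
        post = parsimony_ancestor()
        # (A, A, C) -> A
        assert post.probs[0, 0, 1].argmax() == 0
        assert post.probs[0, 0, 1].sum() == 1.0
        # (A, C, A) and (C, A, A) -> A
        assert post.probs[0, 1, 0].argmax() == 0
        assert post.probs[1, 0, 0].argmax() == 0

    def test_three_distinct_bases_flagged_ambiguous(self):
        post = parsimony_ancestor()
        assert post.ambiguous[0, 1, 2]
        assert post.probs[0, 1, 2].sum() == 0.0
        assert post.ambiguous.sum() == 24  # 4*3*2 fully distinct patterns

    def test_unanimous_pattern(self):
        post = parsimony_ancestor()
        for b in range(4):
            assert post.probs[b, b, b, b] == 1.0


class TestFitting:
    def test_stationary_recovers_symmetric_truth(self):
        model = make_nonstationary_model("stationary", root_gc=0.5, seed=1)
        sim = simulate_triplet_alignment(model, 100_000, seed=2)
        fit = fit_stationary_gtr(sim["pattern_counts"], restarts=2, seed=0)
        assert fit.n_params == N_PARAMS_STATIONARY
        assert np.abs(fit.params["freqs"] - 0.25).max() < 0.02

    def test_minimum_site_count_enforced(self):
        tiny = TripletPatternCounts(np.ones((4, 4, 4)))
        with pytest.raises(ValueError, match="at least"):
            fit_stationary_gtr(tiny)

    def test_degenerate_single_pattern_does_not_crash(self):
        counts = np.zeros((4, 4, 4))
        counts[0, 0, 0] = 5000
        fit = fit_stationary_gtr(TripletPatternCounts(counts), restarts=1,
                                 seed=0)
        assert np.isfinite(fit.loglik)

    def test_nh_fit_dominates_stationary(self):
        model = make_nonstationary_model("gc-shift", seed=4)
        sim = simulate_triplet_alignment(model, 50_000, seed=4)
        st = fit_stationary_gtr(sim["pattern_counts"], restarts=1, seed=0)
        nh = fit_nh_gtr(sim["pattern_counts"], restarts=1, seed=0,
                        stationary_fit=st)
        assert nh.n_params == N_PARAMS_NH
        assert nh.loglik >= st.loglik - 1e-6

    def test_nonstationarity_detected_under_gc_shift(self):
        model = make_nonstationary_model("gc-shift", seed=4)
        sim = simulate_triplet_alignment(model, 100_000, seed=5)
        st = fit_stationary_gtr(sim["pattern_counts"], restarts=1, seed=0)
        nh = fit_nh_gtr(sim["pattern_counts"], restarts=1, seed=0,
                        stationary_fit=st)
        chi2, df, p = lrt_nonstationarity(nh, st)
        assert df == 28
        assert p < 1e-6

    def test_lrt_null_calibration(self):
        """Under stationary truth the 28-df LRT rarely rejects (10
        replicates; <=3 rejections is far outside Bin(10, .05) only if the
        test were badly anticonservative)."""
        rejections = 0
        for rep in range(10):
            model = make_nonstationary_model("stationary", seed=0)
            sim = simulate_triplet_alignment(model, 30_000, seed=100 + rep)
            st = fit_stationary_gtr(sim["pattern_counts"], restarts=1, seed=rep)
            nh = fit_nh_gtr(sim["pattern_counts"], restarts=1, seed=rep,
                            stationary_fit=st)
            _, _, p = lrt_nonstationarity(nh, st)
            rejections += p < 0.05
        assert rejections <= 3


class TestLrtBookkeeping:
    def test_identical_fits(self):
        f = ModelFit(model="GTR-NHb", params={}, loglik=-100.0, n_params=39,
                     meta={"total_sites": 1.0})
        g = ModelFit(model="GTR-stationary", params={}, loglik=-100.0,
                     n_params=11, meta={"total_sites": 1.0})
        chi2, df, p = lrt_nonstationarity(f, g)
        assert chi2 == 0.0 and df == 28 and p == pytest.approx(1.0)

    def test_printed_pvalue(self):
        assert stats.chi2.sf(166.86, 28) == pytest.approx(1.05e-21, rel=5e-3)


class TestReconstructionBias:
    def test_awp_count_error_below_parsimony(self):
        """With a planted ancestor under nonstationary evolution, expected
        AWP substitution counts track the truth while parsimony is heavily
        biased toward common->rare calls."""
        model = make_nonstationary_model("gc-shift", seed=0,
                                         branch_length=0.25, root_gc=0.7,
                                         shifted_gc=0.3)
        sim = simulate_triplet_alignment(model, 200_000, seed=7)
        joint = sim["joint"]
        true_nws = sum(joint[a, m].sum() for a in (0, 3) for m in (1, 2))
        true_nsw = sum(joint[a, m].sum() for a in (1, 2) for m in (0, 3))
        awp = ancestral_posteriors(model, "AWP")
        pars = parsimony_ancestor()
        err = {}
        for name, post in (("AWP", awp), ("parsimony", pars)):
            sc = count_substitutions_patterns(post, sim["pattern_counts"],
                                              "mel", round_totals=False)
            err[name] = abs(sc.nws - true_nws) + abs(sc.nsw - true_nsw)
        assert err["AWP"] < err["parsimony"]
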