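"""EM mixture model: E/M steps, model fitting, state assignment, post-processing."""

import numpy as np
import pytest
from scipy import optimize, stats
from scipy.special import logsumexp

from cellcna.cnacall import (ZERO_STATE_MEAN, MixtureParams, assign_states,
                             call_cell, consensus_breakpoints, default_o_grid,
                             e_step, fit_cell, m_step, merge_equal_cn,
                             postprocess_amplified, segment_loglik, state_mean)
from cellcna.segment import BreakpointSet, segmentation_from_breakpoints


def _mus(states, o):
    """Oracle state means: log2(0.5 c) + o, with state 0 pinned at the floor."""
    return np.array([state_mean(c, o) for c in states])


def _params(o=0.0, sigma=0.2, pi=None, max_cn=4):
    states = np.arange(max_cn + 1)
    if pi is None:
        pi = np.full(len(states), 1.0 / len(states))
    return MixtureParams(o, sigma, np.asarray(pi, float), states, 0.0)


def _random_instance(rng, K=3, max_cn=3):
    x = [rng.normal(rng.choice([-1, 0, 0.58]), 0.2, size=rng.integers(2, 9))
         for _ in range(K)]
    gamma = rng.dirichlet(np.ones(max_cn + 1), size=K)
    return x, gamma, np.arange(max_cn + 1)


class TestStateMean:
    @pytest.mark.parametrize("c,o,expected", [
        (2, 0.0, 0.0), (4, 0.0, 1.0), (1, 0.0, -1.0), (2, 0.3, 0.3),
    ])
    def test_known_values(self, c, o, expected):
        assert state_mean(c, o) == pytest.approx(expected)

    def test_zero_state_is_pinned_at_the_lrc_floor(self):
        assert state_mean(0, 0.0) == pytest.approx(ZERO_STATE_MEAN)
        assert state_mean(0, -0.7) == pytest.approx(ZERO_STATE_MEAN)


class TestSegmentLoglik:
    def test_density_at_the_mean(self):
        sigma = 0.37
        assert segment_loglik(np.array([1.2]), 1.2, sigma) == pytest.approx(
            np.log(1.0 / (np.sqrt(2 * np.pi) * sigma)))

    def test_doubling_identical_bins_doubles_loglik(self):
        x = np.array([0.5, 0.5])
        single = segment_loglik(x[:1], 0.2, 0.3)
        assert segment_loglik(x, 0.2, 0.3) == pytest.approx(2 * single)

    def test_matches_scipy_normal_density(self, rng):
        x = rng.normal(size=5)
        expected = stats.norm.logpdf(x, loc=0.3, scale=0.25).sum()
        assert segment_loglik(x, 0.3, 0.25) == pytest.approx(expected,
                                                             abs=1e-10)


class TestEStep:
    def test_symmetric_segment_splits_evenly(self):
        # segment exactly between the means of states 1 and 2 (at o=0:
        # -1 and 0), with equal weights on those two states only
        params = _params(pi=[0, 0.5, 0.5, 0, 0])
        gamma = e_step([np.array([-0.5])], params)
        assert gamma[0, 1] == pytest.approx(0.5)
        assert gamma[0, 2] == pytest.approx(0.5)

    def test_degenerate_prior_forces_its_state(self, rng):
        params = _params(pi=[0, 1.0, 0, 0, 0])
        gamma = e_step([rng.normal(size=4) for _ in range(3)], params)
        assert np.allclose(gamma[:, 1], 1.0)

    def test_matches_brute_force_posterior(self, rng):
        """Direct normalized-product evaluation of the posterior."""
        x, _, states = _random_instance(rng, K=3, max_cn=3)
        params = _params(o=0.1, sigma=0.3, pi=[0.1, 0.2, 0.4, 0.3], max_cn=3)
        gamma = e_step(x, params)
        mus = _mus(states, params.o)
        for k, xk in enumerate(x):
            dens = np.array([params.pi[s] * np.prod(
                stats.norm.pdf(xk, mus[s], params.sigma))
                for s in range(len(states))])
            assert np.allclose(gamma[k], dens / dens.sum(), atol=1e-10)

    def test_rows_always_normalize(self, rng):
        x, _, _ = _random_instance(rng)
        gamma = e_step(x, _params(sigma=0.05, max_cn=3))
        assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-8)
        assert np.all(np.isfinite(gamma))


class TestMStep:
    def test_hard_assignment_recovers_baseline_shift(self):
        # every bin in the copy-2 state with mean LRC 0.3 -> o = 0.3
        x = [np.array([0.25, 0.35]), np.array([0.3, 0.3, 0.3])]
        gamma = np.zeros((2, 5))
        gamma[:, 2] = 1.0
        params = m_step(x, gamma, np.arange(5))
        assert params.o == pytest.approx(0.3)

    def test_uniform_gamma_gives_uniform_weights(self, rng):
        x, _, states = _random_instance(rng, K=4, max_cn=3)
        gamma = np.full((4, 4), 0.25)
        params = m_step(x, gamma, states)
        assert np.allclose(params.pi, 0.25)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_numeric_maximization(self, trial):
        """(o, sigma) updates maximize the EM objective at fixed gamma."""
        rng = np.random.default_rng(100 + trial)
        x, gamma, states = _random_instance(rng, K=4, max_cn=3)
        params = m_step(x, gamma, states)

        def negobj(theta):
            o, log_sigma = theta
            sigma = np.exp(log_sigma)
            mus = _mus(states, o)
            total = 0.0
            for k, xk in enumerate(x):
                for s in range(len(states)):
                    total += gamma[k, s] * stats.norm.logpdf(
                        xk, mus[s], sigma).sum()
            return -total

        opt = optimize.minimize(negobj, [0.0, np.log(0.3)], method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-12})
        assert params.o == pytest.approx(opt.x[0], abs=1e-4)
        assert params.sigma == pytest.approx(np.exp(opt.x[1]), abs=1e-4)


class TestEMFit:
    def _simulate_cell(self, rng, ploidy, sigma=0.1, K=20, min_len=20):
        """LRC drawn from the model at a known baseline shift."""
        o_true = -np.log2(0.5 * ploidy)
        cns = np.full(K, ploidy)
        # odd/even mix so the profile is not a rescaled flat genome
        cns[: K // 3] = ploidy + 1
        cns[K // 3: K // 2] = max(ploidy - 1, 1)
        x = [rng.normal(np.log2(0.5 * c) + o_true, sigma,
                        size=rng.integers(min_len, 2 * min_len))
             for c in cns]
        return x, o_true, cns

    @pytest.mark.parametrize("ploidy", [2, 3, 4])
    def test_baseline_shift_recovery(self, ploidy):
        rng = np.random.default_rng(50 + ploidy)
        x, o_true, _ = self._simulate_cell(rng, ploidy)
        params, _ = fit_cell(x)
        assert params.o == pytest.approx(o_true, abs=0.05)

    def test_states_recovered_alongside_o(self):
        rng = np.random.default_rng(77)
        x, o_true, cns = self._simulate_cell(rng, 2)
        params, gamma = fit_cell(x)
        called = params.states[assign_states(gamma)]
        assert np.mean(called == cns) >= 0.99

    def test_em_iterations_never_decrease_loglik(self, rng):
        """EM monotonicity on random instances, checked step by step."""
        for trial in range(20):
            x, gamma0, states = _random_instance(rng, K=5, max_cn=3)
            params = m_step(x, gamma0, states)
            prev = _observed_loglik(x, params)
            for _ in range(15):
                gamma = e_step(x, params)
                params = m_step(x, gamma, states)
                cur = _observed_loglik(x, params)
                assert cur >= prev - 1e-8
                prev = cur

    def test_single_dominant_state_collapses_cleanly(self):
        x = [np.full(30, 0.0)]
        params, gamma = fit_cell(x, max_cn=4)
        s = assign_states(gamma)[0]
        assert params.states[s] == 2  # LRC 0 at o=0 is copy 2; tie prefers 2
        assert gamma[0, s] == pytest.approx(1.0, abs=1e-6)


def _observed_loglik(x, params):
    mus = _mus(params.states, params.o)
    total = 0.0
    for xk in x:
        comps = [np.log(max(params.pi[s], 1e-300))
                 + stats.norm.logpdf(xk, mus[s], params.sigma).sum()
                 for s in range(len(params.states))]
        total += logsumexp(comps)
    return total


class TestAssignAndPostprocess:
    def test_argmax_and_tie_rule(self):
        gamma = np.array([[0.9, 0.1], [0.5, 0.5], [0.2, 0.8]])
        assert assign_states(gamma).tolist() == [0, 0, 1]

    def test_matches_brute_force_argmax(self, rng):
        gamma = rng.dirichlet(np.ones(6), size=10)
        assert np.array_equal(assign_states(gamma), gamma.argmax(axis=1))

    def test_amplified_segment_is_recomputed(self):
        params = _params(o=0.1, max_cn=10 // 2)
        x = [np.full(8, np.log2(0.5 * 16) + params.o)]
        out = postprocess_amplified(np.array([5]), x, params, max_cn=5)
        assert out[0] == 16

    def test_exact_max_state_is_a_fixed_point(self):
        params = _params(o=0.0, max_cn=4)
        x = [np.full(8, np.log2(0.5 * 4))]
        out = postprocess_amplified(np.array([4]), x, params, max_cn=4)
        assert out[0] == 4

    def test_below_max_state_untouched(self):
        params = _params(o=0.0, max_cn=4)
        x = [np.full(8, 5.0)]  # extreme data, but state below max
        out = postprocess_amplified(np.array([3]), x, params, max_cn=4)
        assert out[0] == 3


class TestMergeAndConsensus:
    def _profile(self, seg_cn, seg):
        cn = np.repeat(seg_cn, seg.lengths)
        return type("P", (), {"seg_cn": np.asarray(seg_cn), "bin_cn": cn})()

    def test_equal_neighbors_merge(self):
        seg = segmentation_from_breakpoints(BreakpointSet((4, 8), 12), 12)
        merged = merge_equal_cn(self._profile([2, 2, 3], seg), seg)
        assert merged == [(0, 8, 2), (8, 12, 3)]

    def test_all_equal_collapses_per_chromosome(self):
        seg = segmentation_from_breakpoints(BreakpointSet((6,), 12), 12, (6,))
        chrom = np.array([0, 1])
        merged = merge_equal_cn(self._profile([2, 2], seg), seg, chrom)
        assert merged == [(0, 6, 2), (6, 12, 2)]

    def test_alternating_stays(self):
        seg = segmentation_from_breakpoints(BreakpointSet((4, 8), 12), 12)
        merged = merge_equal_cn(self._profile([2, 3, 2], seg), seg)
        assert len(merged) == 3

    def test_consensus_union_semantics(self):
        seg = segmentation_from_breakpoints(BreakpointSet((5,), 20), 20)
        flat = self._profile([2, 2], seg)
        one = self._profile([2, 3], seg)
        assert consensus_breakpoints([flat, flat]).tolist() == []
        assert consensus_breakpoints([flat, one]).tolist() == [5]
        seg2 = segmentation_from_breakpoints(BreakpointSet((5, 11), 20), 20)
        other = self._profile([2, 2, 4], seg2)
        assert consensus_breakpoints([one, other]).tolist() == [5, 11]


def test_ploidy_acn_identity():
    """When the baseline state dominates, ACN ~ 2^(1-o)."""
    rng = np.random.default_rng(4)
    ploidy = 4
    o_true = -np.log2(0.5 * ploidy)
    cns = np.r_[np.full(18, ploidy), [5, 3]]
    x = [rng.normal(np.log2(0.5 * c) + o_true, 0.1, size=30) for c in cns]
    seg = segmentation_from_breakpoints(
        BreakpointSet(tuple(np.cumsum([30] * 19)), 600), 600)
    lrc_row = np.concatenate(x)
    profile = call_cell("cell", lrc_row, seg)
    assert profile.params.ploidy == pytest.approx(2 ** (1 - profile.params.o))
    assert profile.acn == pytest.approx(cns.mean(), abs=0.1)
    assert np.allclose(profile.gamma.sum(axis=1), 1.0, atol=1e-8)
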