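"""Bipartite projection null models against independent oracles."""

import itertools

import numpy as np
import pytest
import scipy.optimize
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from netbackbone import (
    GraphValidationError,
    auto_trials,
    bicm_fit,
    curveball_sample,
    fdsm,
    fixedcol,
    fixedfill,
    fixedrow,
    poisson_binomial_tail,
    project,
    sdsm,
    synth,
)

from conftest import bip, enumerate_margin_class


def brute_force_pb_pmf(probs):
    pmf = np.zeros(len(probs) + 1)
    for bits in itertools.product((0, 1), repeat=len(probs)):
        pr = 1.0
        for p, b in zip(probs, bits):
            pr *= p if b else 1.0 - p
        pmf[sum(bits)] += pr
    return pmf


class TestPoissonBinomial:
    def test_point_mass_at_zero(self):
        assert poisson_binomial_tail([0.0, 0.0, 0.0], 0) == (1.0, 1.0)

    def test_two_coins(self):
        pu, pl = poisson_binomial_tail([0.5, 0.5], 1)
        assert pu == pytest.approx(0.75)
        assert pl == pytest.approx(0.75)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=15, deadline=None)
    def test_dp_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        probs = rng.random(10)
        pmf = brute_force_pb_pmf(probs)
        for w in range(11):
            pu, pl = poisson_binomial_tail(probs, w)
            assert pu == pytest.approx(pmf[w:].sum(), abs=1e-12)
            assert pl == pytest.approx(pmf[: w + 1].sum(), abs=1e-12)

    def test_tails_overlap_by_point_mass(self):
        rng = np.random.default_rng(7)
        probs = rng.random(20)
        pmf = brute_force_pb_pmf(probs[:10])
        for w in range(5):
            pu, pl = poisson_binomial_tail(probs[:10], w)
            assert pu + pl == pytest.approx(1.0 + pmf[w], abs=1e-10)

    def test_refined_normal_close_to_exact_at_crossover(self):
        rng = np.random.default_rng(5)
        probs = rng.random(400) * 0.3
        for w in (100, 120, 140):
            exact = poisson_binomial_tail(probs, w)
            approx = poisson_binomial_tail(probs, w, exact_limit=100)
            assert exact[0] == pytest.approx(approx[0], abs=5e-3)

    def test_out_of_range_weight_rejected(self):
        with pytest.raises(GraphValidationError):
            poisson_binomial_tail([0.5, 0.5], 3)


class TestBicm:
    def test_all_ones_gives_saturated_probabilities(self):
        B = bip(np.ones((3, 4), dtype=int))
        assert np.allclose(bicm_fit(B).Q, 1.0)

    def test_margins_reproduced_on_4x4(self):
        B = bip([[1, 1, 1, 0], [1, 1, 0, 0], [1, 0, 1, 0], [0, 0, 0, 1]])
        Q = bicm_fit(B, tol=1e-10).Q
        assert np.abs(Q.sum(axis=1) - B.agent_degrees()).max() < 1e-8
        assert np.abs(Q.sum(axis=0) - B.artifact_degrees()).max() < 1e-8

    def test_total_probability_mass_matches_fill(self, block_bipartite):
        Q = bicm_fit(block_bipartite).Q
        assert Q.sum() == pytest.approx(block_bipartite.incidence.sum(), abs=1e-6)

    def test_random_20x30_margin_residuals(self):
        rng = np.random.default_rng(42)
        B = bip((rng.random((20, 30)) < 0.35).astype(int))
        pm = bicm_fit(B)
        assert np.abs(pm.Q.sum(axis=1) - B.agent_degrees()).max() < 1e-6
        assert np.abs(pm.Q.sum(axis=0) - B.artifact_degrees()).max() < 1e-6

    def test_agrees_with_independent_root_solver(self):
        # independent oracle: solve the margin equations with a
        # general-purpose nonlinear root finder and compare Q cellwise
        B = bip([[1, 1, 0, 0, 1], [1, 0, 1, 0, 0], [0, 1, 1, 1, 0], [1, 0, 0, 0, 0]])
        d = B.agent_degrees().astype(float)
        f = B.artifact_degrees().astype(float)
        r, c = B.incidence.shape

        def residual(logz):
            x, y = np.exp(logz[:r]), np.exp(logz[r:])
            Q = np.outer(x, y) / (1 + np.outer(x, y))
            return np.concatenate([Q.sum(axis=1) - d, Q.sum(axis=0) - f])

        sol = scipy.optimize.root(residual, np.zeros(r + c), method="lm", tol=1e-14)
        x, y = np.exp(sol.x[:r]), np.exp(sol.x[r:])
        Q_oracle = np.outer(x, y) / (1 + np.outer(x, y))
        assert np.allclose(bicm_fit(B, tol=1e-12).Q, Q_oracle, atol=1e-6)


class TestDeterministicModels:
    def test_sdsm_degenerate_all_ones(self):
        R = sdsm(bip(np.ones((4, 5), dtype=int)))
        assert np.all(R.p_upper[R.tested] == 1.0)
        assert R.extract(0.05).n_edges == 0

    def test_sdsm_zero_weight_pair_has_unit_upper_tail(self):
        R = sdsm(bip([[1, 0, 0], [0, 1, 0], [0, 0, 1]]))
        assert np.all(R.p_upper[R.tested] == 1.0)

    def test_sdsm_is_deterministic(self, block_bipartite):
        R1, R2 = sdsm(block_bipartite), sdsm(block_bipartite)
        assert np.array_equal(R1.p_upper, R2.p_upper, equal_nan=True)

    def test_sdsm_matches_bernoulli_monte_carlo(self):
        # sampling oracle: draw Bernoulli(Q) incidence matrices and
        # compare empirical upper tails on a small planted fixture
        B = synth.bipartite_blocks(groups=2, agents_per=3, artifacts_per=4, seed=3)
        R = sdsm(B)
        Q = bicm_fit(B).Q
        rng = np.random.default_rng(1)
        n_draws = 50_000
        draws = (rng.random((n_draws, *Q.shape)) < Q).astype(np.int32)
        P_star = np.einsum("tik,tjk->tij", draws, draws)
        P_obs = project(B).matrix
        r = B.n_agents
        for i in range(r):
            for j in range(i + 1, r):
                emp = (P_star[:, i, j] >= P_obs[i, j]).mean()
                se = max(np.sqrt(emp * (1 - emp) / n_draws), 1e-4)
                assert abs(R.p_upper[i, j] - emp) <= 3 * se

    def test_fixedrow_matches_column_subset_enumeration(self):
        B = bip([[1, 1, 0, 0], [1, 1, 0, 0]])
        R = fixedrow(B)
        # j's 2 artifacts drawn among C(4,2)=6 subsets; only one overlaps twice
        assert R.p_upper[0, 1] == pytest.approx(1 / 6)

    def test_fixedrow_forced_overlap(self):
        B = bip([[1, 1, 0], [1, 1, 1]])  # d_j = c
        R = fixedrow(B)
        assert R.p_upper[0, 1] == pytest.approx(1.0)  # W = d_i surely
        assert R.p_lower[0, 1] == pytest.approx(1.0)

    def test_fixedrow_zero_observed(self):
        B = bip([[1, 0, 0, 0], [0, 0, 0, 0]])
        assert fixedrow(B).p_upper[0, 1] == 1.0

    def test_fixedcol_matches_placement_enumeration(self):
        # r = 3 agents, two artifacts with f = 2: each lands on a given
        # pair with prob (2/3)(1/2) = 1/3; P(W >= 2) = 1/9
        B = bip([[1, 1], [1, 1], [0, 0]])
        assert fixedcol(B).p_upper[0, 1] == pytest.approx(1 / 9)

    def test_fixedcol_single_artifact_cannot_cooccur(self):
        B = bip([[1], [0], [0]])
        R = fixedcol(B)
        assert R.p_upper[0, 1] == 1.0  # observed 0, P(W >= 0) = 1
        assert R.p_lower[0, 1] == pytest.approx(1.0)  # W identically 0

    def test_fixedfill_binomial_closed_form(self):
        B = bip([[1, 0], [1, 0]])  # q = 0.5, W ~ Binom(2, 0.25)
        assert fixedfill(B).p_upper[0, 1] == pytest.approx(1 - 0.75**2)

    def test_fixedfill_degenerate_fills(self):
        empty = fixedfill(bip(np.zeros((2, 3), dtype=int)))
        assert np.all(empty.p_upper[empty.tested] == 1.0)
        full = fixedfill(bip(np.ones((2, 3), dtype=int)))
        assert np.all(full.p_upper[full.tested] == 1.0)

    @pytest.mark.parametrize("model", [sdsm, fixedrow, fixedcol, fixedfill])
    def test_tail_sum_identity(self, model, block_bipartite):
        R = model(block_bipartite)
        s = R.p_upper[R.tested] + R.p_lower[R.tested]
        assert np.all(s >= 1.0 - 1e-10)
        assert np.all(s <= 2.0 + 1e-10)


class TestCurveball:
    def test_margins_invariant_over_many_trades(self, block_bipartite):
        S = curveball_sample(block_bipartite, steps=10_000, seed=9)
        assert np.array_equal(S.agent_degrees(), block_bipartite.agent_degrees())
        assert np.array_equal(S.artifact_degrees(), block_bipartite.artifact_degrees())

    def test_deterministic_given_seed(self, block_bipartite):
        S1 = curveball_sample(block_bipartite, steps=500, seed=4)
        S2 = curveball_sample(block_bipartite, steps=500, seed=4)
        assert np.array_equal(S1.incidence, S2.incidence)

    def test_uniform_over_permutation_class(self):
        # margins (1,1,1)/(1,1,1): the class is the 6 permutation
        # matrices; chain samples should be uniform over them
        B = bip(np.eye(3, dtype=int))
        counts = {}
        rng_seed = 12
        state = B
        n_samples = 10_000
        rng = np.random.default_rng(rng_seed)
        for _ in range(n_samples):
            state = curveball_sample(state, steps=10, seed=rng)
            key = tuple(state.incidence.argmax(axis=1))
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 6
        chi2, p = stats.chisquare(list(counts.values()))
        assert p > 1e-4


class TestFdsm:
    def test_reproducible_given_seed(self):
        B = synth.bipartite_blocks(groups=2, agents_per=3, artifacts_per=4, seed=5)
        R1 = fdsm(B, trials=300, seed=8)
        R2 = fdsm(B, trials=300, seed=8)
        assert np.array_equal(R1.p_upper, R2.p_upper, equal_nan=True)

    def test_zero_observed_weight_has_unit_upper_tail(self):
        R = fdsm(bip(np.eye(3, dtype=int)), trials=200, seed=3)
        assert np.all(R.p_upper[R.tested] == 1.0)

    def test_matches_exhaustive_margin_class_on_4x4(self):
        B = bip([[1, 1, 0, 0], [1, 0, 1, 0], [0, 1, 1, 1], [1, 0, 0, 0]])
        mats = enumerate_margin_class(B.agent_degrees(), B.artifact_degrees())
        P_obs = project(B).matrix.astype(int)
        trials = 20_000
        R = fdsm(B, trials=trials, seed=13)
        for i in range(4):
            for j in range(i + 1, 4):
                exact = np.mean([(m @ m.T)[i, j] >= P_obs[i, j] for m in mats])
                se = max(np.sqrt(exact * (1 - exact) / trials), 1e-4)
                assert abs(R.p_upper[i, j] - exact) <= 3 * se + 2 / trials

    def test_auto_trials_requires_alpha(self):
        with pytest.raises(GraphValidationError):
            fdsm(bip(np.eye(3, dtype=int)), trials=None, alpha=None)

    def test_auto_trials_rule(self):
        # smallest n with 1.96*sqrt(a(1-a)/n) <= a/10
        a = 0.05
        n = auto_trials(a)
        assert 1.96 * np.sqrt(a * (1 - a) / n) <= a / 10
        assert 1.96 * np.sqrt(a * (1 - a) / (n - 1)) > a / 10


class TestStochasticDominance:
    def test_larger_observed_weight_never_raises_p_upper(self):
        rng = np.random.default_rng(2)
        probs = rng.random(30)
        tails = [poisson_binomial_tail(probs, w)[0] for w in range(31)]
        assert all(a >= b for a, b in zip(tails, tails[1:]))
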