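import collections

import numpy as np
import pytest
from scipy import integrate, stats

from ebcobart.data import Dataset, RunConfig, preset_prior
from ebcobart.sampler import (candidate_cuts, convergence_rhat, draw_sigma2,
                              draw_terminal_values, integrated_leaf_loglik,
                              leaf_posterior_moments, probit_augment, rhat,
                              run_chains)
from ebcobart.trees import Tree, sample_tree_structure
from conftest import leaf, split


class TestIntegratedLeafLoglik:
    def test_empty_leaf_is_log_one(self):
        assert integrated_leaf_loglik(np.array([]), 1.0, 0.5) == 0.0

    def test_point_mass_prior_limit(self):
        r = np.array([0.3, -0.2, 0.9])
        tiny = integrated_leaf_loglik(r, 1.3, 1e-9)
        expected = stats.norm.logpdf(r, 0.0, np.sqrt(1.3)).sum()
        assert tiny == pytest.approx(expected, abs=1e-6)

    def test_matches_numerical_quadrature(self):
        rng = np.random.default_rng(0)
        r = rng.standard_normal(3)
        sigma2, sigma_mu = 0.7, 0.4

        def integrand(mu):
            return (np.prod(stats.norm.pdf(r, mu, np.sqrt(sigma2)))
                    * stats.norm.pdf(mu, 0.0, sigma_mu))

        val, _ = integrate.quad(integrand, -10, 10, epsabs=1e-14)
        assert integrated_leaf_loglik(r, sigma2, sigma_mu) == \
            pytest.approx(np.log(val), abs=1e-8)


class TestConjugateDraws:
    def test_leaf_posterior_hand_case(self):
        mean, var = leaf_posterior_moments(4, 2.0, 1.0, 1.0)
        assert (mean, var) == (pytest.approx(0.4), pytest.approx(0.2))

    def test_no_data_leaf_draws_from_prior(self):
        mean, var = leaf_posterior_moments(0, 0.0, 2.0, 0.7)
        assert mean == 0.0 and var == pytest.approx(0.49)

    def test_likelihood_dominates_as_sigma2_vanishes(self):
        mean, _ = leaf_posterior_moments(5, 10.0, 1e-12, 1.0)
        assert mean == pytest.approx(2.0, rel=1e-6)

    def test_draw_terminal_values_moments(self):
        tree = Tree(root=split(0, 0, 0.5, leaf(1), leaf(1)))
        rng = np.random.default_rng(1)
        X = np.array([[0.2], [0.3], [0.7], [0.9]])
        resid = np.array([1.0, 1.0, -1.0, -1.0])
        draws = []
        for _ in range(4000):
            draw_terminal_values(tree, X, resid, 1.0, 1.0, rng)
            draws.append((tree.root.left.mu, tree.root.right.mu))
        draws = np.array(draws)
        m, v = leaf_posterior_moments(2, 2.0, 1.0, 1.0)
        se = np.sqrt(v / 4000)
        assert draws[:, 0].mean() == pytest.approx(m, abs=4 * se)
        assert draws[:, 1].mean() == pytest.approx(-m, abs=4 * se)
        assert draws[:, 0].var(ddof=1) == pytest.approx(v, rel=0.15)

    def test_sigma2_posterior_moment_matches_analytic(self):
        rng = np.random.default_rng(2)
        resid = rng.standard_normal(40)
        nu, lam = 10.0, 1.0
        draws = np.array([draw_sigma2(resid, nu, lam, rng)
                          for _ in range(20000)])
        shape = (nu + 40) / 2
        rate = (nu * lam + np.sum(resid ** 2)) / 2
        analytic_mean = rate / (shape - 1)
        analytic_sd = analytic_mean / np.sqrt(shape - 2)
        assert draws.mean() == pytest.approx(
            analytic_mean, abs=3 * analytic_sd / np.sqrt(20000))

    def test_sigma2_prior_mean_with_no_data(self):
        rng = np.random.default_rng(3)
        draws = np.array([draw_sigma2(np.array([]), 10.0, 1.0, rng)
                          for _ in range(20000)])
        # IG(5, 5): mean 5/4
        assert draws.mean() == pytest.approx(1.25, rel=0.03)

    def test_sigma2_concentrates_at_truth(self):
        rng = np.random.default_rng(4)
        resid = 2.0 * rng.standard_normal(10_000)
        val = np.mean([draw_sigma2(resid, 10.0, 1.0, rng) for _ in range(50)])
        assert val == pytest.approx(4.0, rel=0.05)


class TestProbitAugment:
    def test_truncation_supports(self):
        rng = np.random.default_rng(5)
        y = np.array([1.0, 0.0] * 50)
        f = rng.standard_normal(100)
        z = probit_augment(y, f, rng)
        assert np.all(z[y == 1] > 0) and np.all(z[y == 0] <= 0)

    def test_half_normal_mean_at_zero(self):
        rng = np.random.default_rng(6)
        n = 100_000
        z = probit_augment(np.ones(n), np.zeros(n), rng)
        se = np.sqrt((1 - 2 / np.pi) / n)
        assert z.mean() == pytest.approx(np.sqrt(2 / np.pi), abs=3 * se)

    def test_far_from_boundary_is_plain_normal(self):
        rng = np.random.default_rng(7)
        z = probit_augment(np.ones(5000), np.full(5000, 10.0), rng)
        assert z.mean() == pytest.approx(10.0, abs=0.05)


class TestCandidateCuts:
    def test_midpoints_of_distinct_values(self):
        X = np.array([[1.0], [3.0], [2.0], [3.0]])
        flat, off = candidate_cuts(X)
        np.testing.assert_allclose(flat, [1.5, 2.5])
        assert list(off) == [0, 2]

    def test_constant_covariate_has_no_cuts(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        _, off = candidate_cuts(X)
        assert off[1] - off[0] == 0 and off[2] - off[1] == 4


class TestRunChains:
    def test_identical_seeds_identical_draws(self, small_continuous_dataset):
        ds = small_continuous_dataset
        prior = preset_prior("flexible", "continuous", ds.y, ds.p, K=10)
        run = RunConfig(n_iter=200, burn_in=100, n_chains=2, seed=123)
        a = run_chains(ds, prior, run)
        b = run_chains(ds, prior, run)
        np.testing.assert_array_equal(a.fits, b.fits)
        np.testing.assert_array_equal(a.sigma2, b.sigma2)
        np.testing.assert_array_equal(a.mus, b.mus)

    def test_snapshots_reproduce_in_sample_fits(self, small_continuous_dataset):
        # forest snapshots + mu0 must reproduce the cached in-sample fit:
        # a joint check of residual bookkeeping and serialization
        ds = small_continuous_dataset
        prior = preset_prior("flexible", "continuous", ds.y, ds.p, K=10)
        run = RunConfig(n_iter=150, burn_in=100, seed=5)
        d = run_chains(ds, prior, run)
        np.testing.assert_allclose(d.predict_draws(ds.X), d.fits, atol=1e-8)

    def test_step_function_is_learned(self, small_continuous_dataset):
        ds = small_continuous_dataset
        prior = preset_prior("flexible", "continuous", ds.y, ds.p)
        run = RunConfig(n_iter=1500, burn_in=750, seed=9)
        d = run_chains(ds, prior, run)
        mse = np.mean((ds.y - d.fits.mean(axis=0)) ** 2)
        assert mse < np.var(ds.y) / 4

    def test_binary_chain_separates_classes(self, small_binary_dataset):
        ds = small_binary_dataset
        prior = preset_prior("flexible", "binary", ds.y, ds.p)
        run = RunConfig(n_iter=1500, burn_in=750, seed=11)
        d = run_chains(ds, prior, run)
        assert d.sigma2 is None
        prob = d.predict_mean(ds.X)
        hi = prob[ds.X[:, 0] > 0.5].mean()
        lo = prob[ds.X[:, 0] <= 0.5].mean()
        assert hi - lo > 0.3

    def test_prior_recovery_with_likelihood_off(self):
        # with sigma^2 pinned huge the chain must sample the tree-structure
        # prior restricted to data-supported trees; compare the leaf-count
        # distribution against generative prior sampling (chi-squared)
        rng = np.random.default_rng(1)
        N, p, K = 500, 3, 5
        X = rng.random((N, p))
        y = rng.standard_normal(N)
        ds = Dataset(X, y, "continuous", [f"x{j}" for j in range(p)])
        prior = preset_prior("flexible", "continuous", y, p, K=K)
        run = RunConfig(n_iter=11000, burn_in=1000, seed=3)
        d = run_chains(ds, prior, run, fixed_sigma2=1e10)
        lc = d.leaf_counts().reshape(-1, K)[::10].ravel()  # thin the chain
        g = np.random.default_rng(7)
        gen = np.array([sample_tree_structure(0.95, 2.0, np.ones(p) / p,
                                              g).n_terminal
                        for _ in range(20000)])
        bins = [1, 2, 3, 4, 5]
        obs = np.array([(lc == b).sum() for b in bins] + [(lc > 5).sum()])
        ref = np.array([(gen == b).sum() for b in bins] + [(gen > 5).sum()])
        table = np.vstack([obs, ref])
        pval = stats.chi2_contingency(table).pvalue
        assert pval > 0.01


class TestRhat:
    def test_constant_chains_return_one(self):
        assert rhat(np.ones((3, 10))) == 1.0

    def test_same_distribution_near_one(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((4, 10_000))
        assert rhat(x) < 1.01

    def test_separated_chains_exceed_threshold(self):
        rng = np.random.default_rng(1)
        x = np.vstack([rng.standard_normal((1, 2000)),
                       rng.standard_normal((1, 2000)) + 5.0])
        assert rhat(x) > 1.5

    def test_agrees_with_reference_implementation(self):
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(2)
        x = rng.standard_normal((4, 500)) + rng.random((4, 1))
        ours = rhat(x)
        ref = float(np.asarray(
            arviz.rhat(arviz.convert_to_dataset(x)).to_array()).ravel()[0])
        assert ours == pytest.approx(ref, abs=0.02)

    def test_convergence_scalar_continuous(self, small_continuous_dataset):
        ds = small_continuous_dataset
        prior = preset_prior("flexible", "continuous", ds.y, ds.p, K=10)
        run = RunConfig(n_iter=400, burn_in=200, n_chains=2, seed=21)
        d = run_chains(ds, prior, run)
        assert convergence_rhat(d) < 1.2


class TestProposalContracts:
    def test_degenerate_S_uses_only_that_covariate(self):
        # all prior mass on covariate 2: every sampled split must use it
        rng = np.random.default_rng(8)
        N, p = 40, 4
        X = rng.random((N, p))
        y = np.where(X[:, 2] > 0.5, 1.0, -1.0) + 0.1 * rng.standard_normal(N)
        ds = Dataset(X, y, "continuous", [f"x{j}" for j in range(p)])
        prior = preset_prior("flexible", "continuous", y, p, K=10)
        S = np.zeros(p)
        S[2] = 1.0
        prior = prior.with_updates(S=S)
        d = run_chains(ds, prior, RunConfig(n_iter=400, burn_in=200, seed=13))
        sv = d.split_var_indices()
        assert sv.size > 0 and np.all(sv == 2)
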