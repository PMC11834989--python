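import numpy as np
import pytest
from scipy import optimize, stats

from conftest import draws_from_forests, leaf, split
from ebcobart.eb import (DegenerateForestError, SplitCounts, count_splits,
                         eb_update_S_raw, eb_update_alpha, eb_update_k,
                         eb_update_nu_lambda)
from ebcobart.trees import Forest, Tree


def _forest_of(trees):
    return Forest(trees=trees, mu0=0.0)


class TestCountSplits:
    def test_terminal_root_forests_count_nothing(self):
        forests = [_forest_of([Tree(root=leaf(0)) for _ in range(3)])
                   for _ in range(2)]
        draws = draws_from_forests(forests, p=4)
        counts = count_splits(draws)
        assert counts.B == 0
        with pytest.raises(DegenerateForestError):
            eb_update_S_raw(counts)

    def test_single_stump(self):
        forests = [_forest_of([Tree(root=split(0, 3, 0.5, leaf(1), leaf(1))),
                               Tree(root=leaf(0))])]
        counts = count_splits(draws_from_forests(forests, p=5))
        assert counts.B == 1 and counts.b[3] == 1

    def test_manual_tally_two_draws(self):
        t_deep = Tree(root=split(0, 0, 0.5,
                                 split(1, 2, 0.3, leaf(2), leaf(2)),
                                 leaf(1)))
        forests = [
            _forest_of([t_deep, Tree(root=split(0, 2, 0.7, leaf(1), leaf(1)))]),
            _forest_of([Tree(root=leaf(0)), t_deep]),
        ]
        counts = count_splits(draws_from_forests(forests, p=4))
        assert list(counts.b) == [2, 0, 3, 0]
        assert counts.B == 5


class TestUpdateSRaw:
    def test_closed_form(self):
        assert list(eb_update_S_raw(SplitCounts(b=[3, 1, 0]))) == [0.75, 0.25, 0.0]

    def test_uniform_counts_give_uniform_S(self):
        S = eb_update_S_raw(SplitCounts(b=[7, 7, 7, 7]))
        np.testing.assert_allclose(S, 0.25)

    def test_sum_exactly_one_on_integer_counts(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            b = rng.integers(0, 50, size=6)
            if b.sum() == 0:
                continue
            from fractions import Fraction
            S = eb_update_S_raw(SplitCounts(b=b))
            exact = sum(Fraction(int(x), int(b.sum())) for x in b)
            assert exact == 1
            assert S.sum() == pytest.approx(1.0, abs=1e-15)

    def test_maximizes_categorical_objective(self):
        # independent simplex maximization of sum_j b_j log s_j via an
        # unconstrained softmax parameterization
        b = np.array([5.0, 2.0, 1.0, 1.0])

        def neg(theta):
            z = np.concatenate([[0.0], theta])
            logs = z - np.log(np.sum(np.exp(z)))
            return -np.sum(b * logs)

        res = optimize.minimize(neg, x0=np.zeros(3), method="BFGS")
        z = np.concatenate([[0.0], res.x])
        s_oracle = np.exp(z) / np.sum(np.exp(z))
        np.testing.assert_allclose(s_oracle, b / b.sum(), atol=1e-6)


class TestUpdateK:
    def test_constant_magnitude_sample(self):
        k = eb_update_k(np.full(100, 0.1), K=50, response_kind="continuous")
        assert k == pytest.approx(0.5 / (0.1 * np.sqrt(50)), rel=1e-10)

    def test_inverts_sigma_mu_closed_form(self):
        sig = 0.5 / (2 * np.sqrt(50))
        k = eb_update_k(np.array([sig, -sig]), K=50,
                        response_kind="continuous")
        assert k == pytest.approx(2.0, rel=1e-10)

    def test_matches_grid_search_of_prior_objective(self):
        rng = np.random.default_rng(1)
        mus = 0.05 * rng.standard_normal(5000)
        K = 50
        grid = np.linspace(0.1, 10.0, 20001)
        sds = 0.5 / (grid * np.sqrt(K))
        obj = np.array([np.sum(stats.norm.logpdf(mus, 0, s)) for s in sds])
        k_grid = grid[np.argmax(obj)]
        k_hat = eb_update_k(mus, K=K, response_kind="continuous")
        assert k_hat == pytest.approx(k_grid, abs=1e-3)

    def test_parameter_recovery_from_prior_draws(self):
        rng = np.random.default_rng(2)
        K, k_true = 50, 2.0
        sd = 0.5 / (k_true * np.sqrt(K))
        mus = sd * rng.standard_normal(10_000)
        k_hat = eb_update_k(mus, K=K, response_kind="continuous")
        assert k_hat == pytest.approx(k_true, rel=0.05)

    def test_binary_scale_factor(self):
        sig = 3.0 / (1.5 * np.sqrt(50))
        k = eb_update_k(np.array([sig]), K=50, response_kind="binary")
        assert k == pytest.approx(1.5, rel=1e-10)


class TestUpdateAlpha:
    def test_all_terminal_roots_hits_lower_clip(self):
        alpha = eb_update_alpha((np.array([], dtype=int), np.zeros(100, int)),
                                beta=2.0)
        assert alpha == pytest.approx(0.01, abs=1e-4)

    def test_stump_fixture_matches_grid_oracle(self):
        d_int = np.zeros(200, dtype=int)
        d_term = np.ones(400, dtype=int)
        grid = np.linspace(0.01, 0.99, 98001)
        obj = (200 * np.log(grid) + 400 * np.log1p(-grid / 4.0))
        oracle = grid[np.argmax(obj)]
        alpha = eb_update_alpha((d_int, d_term), beta=2.0)
        assert alpha == pytest.approx(oracle, abs=1e-4)

    def test_mixture_lies_between_pure_fixtures(self):
        stump = (np.zeros(100, int), np.ones(200, int))
        roots = (np.array([], dtype=int), np.zeros(100, int))
        mix = (stump[0], np.concatenate([stump[1], roots[1]]))
        a_stump = eb_update_alpha(stump, beta=2.0)
        a_roots = eb_update_alpha(roots, beta=2.0)
        a_mix = eb_update_alpha(mix, beta=2.0)
        assert a_roots < a_mix < a_stump

    def test_parameter_recovery_from_prior_sampled_trees(self):
        from ebcobart.trees import sample_tree_structure
        rng = np.random.default_rng(3)
        alpha_true, beta = 0.6, 2.0
        d_int, d_term = [], []
        for _ in range(4000):
            t = sample_tree_structure(alpha_true, beta, np.ones(3) / 3, rng)
            internal, terminal = t.nodes()
            d_int.extend(n.depth for n in internal)
            d_term.extend(n.depth for n in terminal)
        a_hat = eb_update_alpha((np.array(d_int), np.array(d_term)), beta=beta)
        assert a_hat == pytest.approx(alpha_true, abs=0.05)


class TestUpdateNuLambda:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(4)
        nu, lam = 10.0, 1.0
        draws = stats.invgamma.rvs(nu / 2, scale=nu * lam / 2, size=100_000,
                                   random_state=rng)
        nu_hat, lam_hat = eb_update_nu_lambda(draws)
        assert nu_hat == pytest.approx(nu, rel=0.05)
        assert lam_hat == pytest.approx(lam, rel=0.05)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(5)
        draws = stats.invgamma.rvs(5, scale=5, size=5000, random_state=rng)
        nu1, lam1 = eb_update_nu_lambda(draws)
        nu2, lam2 = eb_update_nu_lambda(3.0 * draws)
        assert nu2 == pytest.approx(nu1, rel=1e-3)
        assert lam2 == pytest.approx(3.0 * lam1, rel=1e-10)

    def test_degenerate_draws_raise(self):
        with pytest.raises(ValueError, match="degenerate"):
            eb_update_nu_lambda(np.full(100, 2.5))

    def test_matches_reference_mle(self):
        # scipy's generic inverse-gamma ML fit as the independent oracle
        rng = np.random.default_rng(6)
        draws = stats.invgamma.rvs(4.0, scale=6.0, size=20_000,
                                   random_state=rng)
        nu_hat, lam_hat = eb_update_nu_lambda(draws)
        a_ref, _, scale_ref = stats.invgamma.fit(draws, floc=0)
        assert nu_hat == pytest.approx(2 * a_ref, rel=0.01)
        assert lam_hat == pytest.approx(scale_ref / a_ref, rel=0.01)
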