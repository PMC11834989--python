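import json

import numpy as np
import pytest

from conftest import leaf, split
from ebcobart.trees import (Forest, Tree, forest_from_json, forest_to_json,
                            log_terminal_node_prior, log_tree_structure_prior,
                            predict_forest, predict_tree,
                            sample_tree_structure, split_prob)


class TestSplitProb:
    @pytest.mark.parametrize("d,alpha,beta,expected", [
        (0, 0.95, 2.0, 0.95),
        (1, 0.95, 2.0, 0.2375),
        (3, 0.1, 4.0, 0.000390625),
    ])
    def test_closed_form(self, d, alpha, beta, expected):
        assert split_prob(d, alpha, beta) == pytest.approx(expected, rel=1e-12)


def _recursive_prior_oracle(node, alpha, beta, S):
    """Independent node-by-node recursion over the tree."""
    if node.is_terminal:
        return np.log1p(-split_prob(node.depth, alpha, beta))
    return (np.log(split_prob(node.depth, alpha, beta))
            + np.log(S[node.split_var])
            + _recursive_prior_oracle(node.left, alpha, beta, S)
            + _recursive_prior_oracle(node.right, alpha, beta, S))


class TestStructurePrior:
    def test_terminal_root(self):
        t = Tree(root=leaf(0))
        assert log_tree_structure_prior(t, 0.95, 2, np.ones(3) / 3) == \
            pytest.approx(np.log(0.05))

    def test_stump_expansion(self):
        S = np.array([0.2, 0.8])
        t = Tree(root=split(0, 1, 0.5, leaf(1), leaf(1)))
        expected = (np.log(0.95) + np.log(0.8)
                    + 2 * np.log(1 - 0.95 * 2 ** -2.0))
        assert log_tree_structure_prior(t, 0.95, 2, S) == pytest.approx(expected)

    def test_matches_recursive_oracle_on_random_trees(self):
        rng = np.random.default_rng(0)
        S = rng.dirichlet(np.ones(6))
        for _ in range(20):
            t = sample_tree_structure(0.95, 2.0, S, rng, sigma_mu=1.0)
            assert log_tree_structure_prior(t, 0.95, 2.0, S) == \
                pytest.approx(_recursive_prior_oracle(t.root, 0.95, 2.0, S))

    def test_zero_weight_used_variable_gives_neg_inf(self):
        t = Tree(root=split(0, 0, 0.5, leaf(1), leaf(1)))
        S = np.array([0.0, 1.0])
        assert log_tree_structure_prior(t, 0.95, 2, S) == -np.inf

    def test_leaf_count_invariant(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            t = sample_tree_structure(0.95, 2.0, np.ones(4) / 4, rng)
            assert t.n_terminal == t.n_internal + 1


class TestTerminalPrior:
    def test_all_zero_mus_density_at_mode(self):
        t = Tree(root=split(0, 0, 0.5, leaf(1, 0.0), leaf(1, 0.0)))
        sd = 0.5 / (2 * np.sqrt(50))
        expected = 2 * (-0.5 * np.log(2 * np.pi * sd ** 2))
        assert log_terminal_node_prior(t, k=2, K=50) == pytest.approx(expected)

    def test_forest_prior_additivity(self):
        # joint prior of an i.i.d. forest = sum of per-tree structure and
        # terminal-value priors (the product form, tree by tree)
        rng = np.random.default_rng(9)
        S = np.ones(5) / 5
        trees = [sample_tree_structure(0.5, 1.5, S, rng, sigma_mu=0.3)
                 for _ in range(4)]
        total = sum(log_tree_structure_prior(t, 0.5, 1.5, S)
                    + log_terminal_node_prior(t, 2, 50) for t in trees)
        parts = [log_tree_structure_prior(t, 0.5, 1.5, S) for t in trees] + \
                [log_terminal_node_prior(t, 2, 50) for t in trees]
        assert total == pytest.approx(sum(parts))


class TestPrediction:
    def test_terminal_root_constant(self):
        t = Tree(root=leaf(0, mu=3.5))
        for x in np.random.default_rng(0).random((5, 2)):
            assert predict_tree(t, x) == 3.5

    def test_boundary_goes_left(self):
        t = Tree(root=split(0, 0, 0.4, leaf(1, -1.0), leaf(1, 1.0)))
        assert predict_tree(t, np.array([0.4])) == -1.0
        assert predict_tree(t, np.array([0.400001])) == 1.0

    def test_depth_two_manual_routing(self):
        t = Tree(root=split(0, 0, 0.5,
                            split(1, 1, 0.3, leaf(2, 1.0), leaf(2, 2.0)),
                            leaf(1, 3.0)))
        assert predict_tree(t, np.array([0.2, 0.1])) == 1.0
        assert predict_tree(t, np.array([0.2, 0.9])) == 2.0
        assert predict_tree(t, np.array([0.9, 0.1])) == 3.0

    def test_forest_sums_trees_plus_offset(self):
        rng = np.random.default_rng(1)
        trees = [sample_tree_structure(0.9, 1.0, np.ones(3) / 3, rng,
                                       sigma_mu=0.5) for _ in range(5)]
        forest = Forest(trees=trees, mu0=1.25)
        X = rng.random((10, 3))
        expected = 1.25 + sum(
            np.array([predict_tree(t, x) for x in X]) for t in trees)
        np.testing.assert_allclose(predict_forest(forest, X), expected)

    def test_every_point_lands_in_exactly_one_leaf(self):
        rng = np.random.default_rng(2)
        t = sample_tree_structure(0.95, 1.0, np.ones(3) / 3, rng, sigma_mu=1.0)
        X = rng.random((200, 3))
        for x in X:
            predict_tree(t, x)  # routing is total: no exception, one leaf


class TestGenerativePriorFrequencies:
    def test_structure_frequencies_match_split_prob(self):
        # empirical depth-0 split frequency and leaf-count distribution
        # against the closed forms implied by alpha(1+d)^-beta
        rng = np.random.default_rng(11)
        alpha, beta = 0.95, 2.0
        n = 10_000
        trees = [sample_tree_structure(alpha, beta, np.ones(2) / 2, rng)
                 for _ in range(n)]
        leaves = np.array([t.n_terminal for t in trees])
        p1 = 1 - alpha
        pd1 = split_prob(1, alpha, beta)
        p2 = alpha * (1 - pd1) ** 2
        from scipy.stats import chisquare
        obs = np.array([(leaves == 1).sum(), (leaves == 2).sum(),
                        (leaves > 2).sum()])
        exp = n * np.array([p1, p2, 1 - p1 - p2])
        assert chisquare(obs, exp).pvalue > 0.01


class TestSerialization:
    def test_json_round_trip_bit_exact(self):
        rng = np.random.default_rng(5)
        trees = [sample_tree_structure(0.9, 1.5, np.ones(4) / 4, rng,
                                       sigma_mu=0.7) for _ in range(3)]
        forest = Forest(trees=trees, mu0=0.3, sigma2=1.7)
        names = ["a", "b", "c", "d"]
        payload = json.loads(json.dumps(forest_to_json(forest, names)))
        back = forest_from_json(payload, names)
        X = rng.random((20, 4))
        np.testing.assert_array_equal(predict_forest(back, X),
                                      predict_forest(forest, X))
        assert back.sigma2 == forest.sigma2
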