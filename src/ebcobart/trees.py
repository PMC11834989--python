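"""Explicit tree/forest structures, their priors, and deterministic prediction.

A regression tree is a set of internal nodes carrying splitting rules
``x_j <= a`` (ties go left) and terminal nodes carrying response values
``mu``.  The structure prior makes a node at depth ``d`` internal with
probability ``alpha * (1+d)^-beta`` and draws split variables from the
categorical prior ``S``; terminal values are i.i.d. centred normal with sd
``sigma_mu``.  These objects are the readable reference representation —
the sampler itself runs on flat arrays (:mod:`ebcobart._kernel`) and its
snapshots can be converted back with :func:`forest_from_snapshot`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import CONTINUOUS, sigma_mu_for

__all__ = [
    "Node", "Tree", "Forest", "split_prob",
    "log_tree_structure_prior", "log_terminal_node_prior",
    "predict_tree", "predict_forest", "sample_tree_structure",
    "tree_to_dict", "tree_from_dict", "forest_to_json", "forest_from_json",
]


@dataclass
class Node:
    depth: int
    split_var: int | None = None
    split_value: float | None = None
    mu: float | None = None
    left: "Node | None" = None
    right: "Node | None" = None

    @property
    def is_terminal(self) -> bool:
        return self.split_var is None

    def validate(self):
        if self.is_terminal:
            if self.left is not None or self.right is not None:
                raise ValueError("terminal node must not have children")
        else:
            if self.left is None or self.right is None:
                raise ValueError("internal node needs two children")
            if self.left.depth != self.depth + 1 or self.right.depth != self.depth + 1:
                raise ValueError("children must sit at depth d+1")
            self.left.validate()
            self.right.validate()


@dataclass
class Tree:
    root: Node

    def __post_init__(self):
        self.root.validate()

    def nodes(self):
        """(internal nodes, terminal nodes), each in depth-first order."""
        internal, terminal = [], []
        stack = [self.root]
        while stack:
            nd = stack.pop()
            if nd.is_terminal:
                terminal.append(nd)
            else:
                internal.append(nd)
                stack.append(nd.right)
                stack.append(nd.left)
        return internal, terminal

    @property
    def n_internal(self) -> int:
        return len(self.nodes()[0])

    @property
    def n_terminal(self) -> int:
        return len(self.nodes()[1])


@dataclass
class Forest:
    trees: list[Tree]
    mu0: float
    sigma2: float | None = None


def split_prob(d: int, alpha: float, beta: float) -> float:
    """Prior probability alpha*(1+d)^-beta that a depth-d node is internal."""
    return alpha * (1.0 + d) ** (-beta)


def log_tree_structure_prior(tree: Tree, alpha: float, beta: float,
                             S: np.ndarray) -> float:
    """Log prior of a tree structure: depth terms plus categorical-S terms.

    Splitting values are excluded (uniform over their candidate set).  A used
    split variable with s_j = 0 yields -inf rather than an exception.
    """
    S = np.asarray(S, dtype=np.float64)
    internal, terminal = tree.nodes()
    total = 0.0
    for nd in internal:
        sj = S[nd.split_var]
        if sj <= 0.0:
            return -np.inf
        total += np.log(sj) + np.log(split_prob(nd.depth, alpha, beta))
    for nd in terminal:
        total += np.log1p(-split_prob(nd.depth, alpha, beta))
    return total


def log_terminal_node_prior(tree: Tree, k: float, K: int,
                            response_kind: str = CONTINUOUS) -> float:
    """Sum of centred-normal log densities of the terminal values."""
    sd = sigma_mu_for(k, K, response_kind)
    total = 0.0
    for nd in tree.nodes()[1]:
        total += -0.5 * np.log(2.0 * np.pi * sd * sd) - nd.mu ** 2 / (2.0 * sd * sd)
    return total


def predict_tree(tree: Tree, x: np.ndarray) -> float:
    nd = tree.root
    while not nd.is_terminal:
        nd = nd.left if x[nd.split_var] <= nd.split_value else nd.right
    return nd.mu


def predict_forest(forest: Forest, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    out = np.full(X.shape[0], forest.mu0)
    for tree in forest.trees:
        for i in range(X.shape[0]):
            out[i] += predict_tree(tree, X[i])
    return out


def sample_tree_structure(alpha: float, beta: float, S: np.ndarray,
                          rng: np.random.Generator, sigma_mu: float = 0.0,
                          max_depth: int = 12) -> Tree:
    """Generative draw from the structure prior (used for property checks)."""
    S = np.asarray(S, dtype=np.float64)
    p = S.shape[0]

    def build(depth):
        if depth < max_depth and rng.random() < split_prob(depth, alpha, beta):
            j = int(rng.choice(p, p=S))
            return Node(depth=depth, split_var=j, split_value=float(rng.random()),
                        left=build(depth + 1), right=build(depth + 1))
        mu = float(rng.normal(0.0, sigma_mu)) if sigma_mu > 0 else 0.0
        return Node(depth=depth, mu=mu)

    return Tree(root=build(0))


# --- serialization ---------------------------------------------------------

def tree_to_dict(tree: Tree, covariate_names=None) -> dict:
    def rec(nd: Node) -> dict:
        if nd.is_terminal:
            return {"kind": "terminal", "depth": nd.depth, "mu": nd.mu}
        name = (covariate_names[nd.split_var] if covariate_names is not None
                else nd.split_var)
        return {"kind": "internal", "depth": nd.depth, "split_var": name,
                "split_value": nd.split_value,
                "left": rec(nd.left), "right": rec(nd.right)}

    return rec(tree.root)


def tree_from_dict(d: dict, covariate_names=None) -> Tree:
    def rec(rd: dict, depth: int) -> Node:
        if rd["kind"] == "terminal":
            return Node(depth=depth, mu=rd["mu"])
        sv = rd["split_var"]
        if covariate_names is not None and not isinstance(sv, int):
            sv = covariate_names.index(sv)
        return Node(depth=depth, split_var=int(sv),
                    split_value=rd["split_value"],
                    left=rec(rd["left"], depth + 1),
                    right=rec(rd["right"], depth + 1))

    return Tree(root=rec(d, 0))


def forest_to_json(forest: Forest, covariate_names=None) -> dict:
    return {"mu0": forest.mu0, "sigma2": forest.sigma2,
            "trees": [tree_to_dict(t, covariate_names) for t in forest.trees]}


def forest_from_json(d: dict, covariate_names=None) -> Forest:
    return Forest(trees=[tree_from_dict(t, covariate_names) for t in d["trees"]],
                  mu0=d["mu0"], sigma2=d.get("sigma2"))


def forest_from_snapshot(slots, vars_, splits, mus, offsets, tree_lo, tree_hi,
                         mu0, sigma2=None) -> Forest:
    """Rebuild Forest objects from one draw's slice of kernel snapshots."""
    trees = []
    for t in range(tree_lo, tree_hi):
        lo, hi = offsets[t], offsets[t + 1]
        rec = {int(slots[k]): k for k in range(lo, hi)}

        def build(slot, depth):
            k = rec[slot]
            if vars_[k] < 0:
                return Node(depth=depth, mu=float(mus[k]))
            return Node(depth=depth, split_var=int(vars_[k]),
                        split_value=float(splits[k]),
                        left=build(2 * slot + 1, depth + 1),
                        right=build(2 * slot + 2, depth + 1))

        trees.append(Tree(root=build(0, 0)))
    return Forest(trees=trees, mu0=mu0, sigma2=sigma2)
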