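import numpy as np
import pytest

from ebcobart.data import Dataset
from ebcobart.sampler import PosteriorDraws
from ebcobart.trees import Forest, Node, Tree


def tree_slots(tree: Tree):
    """(slot, var, split, mu) records for a Tree laid out on the heap."""
    rec = []

    def walk(node: Node, slot: int):
        if node.is_terminal:
            rec.append((slot, -1, 0.0, float(node.mu)))
        else:
            rec.append((slot, int(node.split_var), float(node.split_value), 0.0))
            walk(node.left, 2 * slot + 1)
            walk(node.right, 2 * slot + 2)

    walk(tree.root, 0)
    return rec


def draws_from_forests(forests, p, mu0=0.0, fits=None, sigma2=None,
                       response_kind="continuous", chain=None):
    """Package explicit per-draw forests as PosteriorDraws for the EB and
    WAIC machinery (test fixture helper)."""
    K = len(forests[0].trees)
    slots, vars_, splits, mus = [], [], [], []
    offsets = [0]
    for forest in forests:
        assert len(forest.trees) == K
        for tree in forest.trees:
            for s, v, a, m in tree_slots(tree):
                slots.append(s)
                vars_.append(v)
                splits.append(a)
                mus.append(m)
            offsets.append(len(slots))
    n_mc = len(forests)
    if fits is None:
        fits = np.zeros((n_mc, 1))
    if sigma2 is None and response_kind == "continuous":
        sigma2 = np.ones(n_mc)
    return PosteriorDraws(
        fits=np.asarray(fits, dtype=np.float64),
        sigma2=None if response_kind == "binary" else np.asarray(sigma2),
        chain=np.zeros(n_mc, dtype=np.int32) if chain is None else chain,
        offsets=np.asarray(offsets, dtype=np.int64),
        slots=np.asarray(slots, dtype=np.int32),
        vars_=np.asarray(vars_, dtype=np.int32),
        splits=np.asarray(splits, dtype=np.float64),
        mus=np.asarray(mus, dtype=np.float64),
        K=K, p=p, mu0=mu0, response_kind=response_kind, accept_rate=0.0)


def leaf(depth, mu=0.0):
    return Node(depth=depth, mu=mu)


def split(depth, j, a, left, right):
    return Node(depth=depth, split_var=j, split_value=a, left=left, right=right)


@pytest.fixture(scope="session")
def small_continuous_dataset():
    rng = np.random.default_rng(42)
    N, p = 50, 4
    X = rng.random((N, p))
    y = np.where(X[:, 1] > 0.5, 2.0, -2.0) + 0.3 * rng.standard_normal(N)
    return Dataset(X, y, "continuous", [f"x{j}" for j in range(p)])


@pytest.fixture(scope="session")
def small_binary_dataset():
    rng = np.random.default_rng(7)
    N, p = 60, 3
    X = rng.random((N, p))
    prob = np.where(X[:, 0] > 0.5, 0.85, 0.2)
    y = (rng.random(N) < prob).astype(float)
    return Dataset(X, y, "binary", [f"x{j}" for j in range(p)])
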