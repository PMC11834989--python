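"""Synthetic-data generators for the simulation designs and a lymphoma-like
binary fixture.

The main design is sparse and non-linear: p=500 Unif(0,1) covariates of
which five — {1, 2, 3, 101, 102} (1-based) — drive the response through the
five-dimensional Friedman test function, with unit Gaussian noise.  Grouping
co-data with G equal-sized blocks of consecutive covariates then places
{1,2,3} in the first group and {101,102} together in another, so informative
co-data amounts to knowing which two groups carry signal.  A dense linear
design with noisy effect-size co-data, a permuted (uninformative) grouping,
and a small binary-response fixture emulating a DLBCL prognosis cohort
(four covariate types with one dominant clinical covariate) complete the
set.  All generators are pure functions of (scenario, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import stats

from .data import Dataset

__all__ = [
    "SimScenario", "FriedmanSim", "friedman_f0", "simulate_friedman",
    "make_group_codata", "make_uninformative_codata",
    "simulate_dense_linear", "simulate_binary_fixture",
    "FRIEDMAN_PREDICTIVE",
]

# 0-based indices of the predictive covariates {1, 2, 3, 101, 102}
FRIEDMAN_PREDICTIVE = (0, 1, 2, 100, 101)


@dataclass
class SimScenario:
    design: str = "friedman"
    N: int = 100
    p: int = 500
    G: int = 20
    Ntest: int = 500
    seed: int = 0
    knobs: dict = field(default_factory=dict)

    def __post_init__(self):
        if min(self.N, self.p, self.Ntest) < 1:
            raise ValueError("N, p, Ntest must be positive")


class FriedmanSim(NamedTuple):
    train: Dataset
    test: Dataset
    f0_train: np.ndarray
    f0_test: np.ndarray


def friedman_f0(x: np.ndarray) -> np.ndarray:
    """The sparse five-dimensional test function on [0,1]^p, p >= 102:

        f0(x) = 10 sin(pi x1 x2) + 10 x3 + 20 (x101 - 0.5)^2 + 10 x102

    (1-based covariate indexing).  All other coordinates are inert.
    """
    X = np.atleast_2d(np.asarray(x, dtype=np.float64))
    if X.shape[1] < 102:
        raise ValueError("need at least 102 covariates")
    out = (10.0 * np.sin(np.pi * X[:, 0] * X[:, 1])
           + 10.0 * X[:, 2]
           + 20.0 * (X[:, 100] - 0.5) ** 2
           + 10.0 * X[:, 101])
    return out[0] if np.asarray(x).ndim == 1 else out


def _names(p):
    return [f"x{j + 1}" for j in range(p)]


def simulate_friedman(scenario: SimScenario) -> FriedmanSim:
    """Unif(0,1) covariates, y = f0(x) + N(0,1) noise, plus a shared test set."""
    rng = np.random.default_rng(scenario.seed)
    p = scenario.p
    noise_sd = float(scenario.knobs.get("noise_sd", 1.0))
    X = rng.random((scenario.N, p))
    f0_tr = friedman_f0(X)
    y = f0_tr + noise_sd * rng.standard_normal(scenario.N)
    Xt = rng.random((scenario.Ntest, p))
    f0_te = friedman_f0(Xt)
    yt = f0_te + noise_sd * rng.standard_normal(scenario.Ntest)
    names = _names(p)
    return FriedmanSim(
        train=Dataset(X, y, "continuous", names),
        test=Dataset(Xt, yt, "continuous", names),
        f0_train=f0_tr, f0_test=f0_te)


def make_group_codata(p: int, G: int) -> np.ndarray:
    """Equal-sized consecutive groups: covariates 1..p/G -> group 1, etc."""
    if p % G != 0:
        raise ValueError(f"G={G} does not divide p={p}")
    return np.repeat(np.arange(1, G + 1), p // G)


def make_uninformative_codata(p: int, G: int, seed: int) -> np.ndarray:
    """The equal-sized grouping with membership randomly permuted, severing
    any link between groups and predictive covariates."""
    rng = np.random.default_rng(seed)
    return rng.permutation(make_group_codata(p, G))


class DenseLinearSim(NamedTuple):
    train: Dataset
    test: Dataset
    beta: np.ndarray
    codata: np.ndarray


def simulate_dense_linear(scenario: SimScenario) -> DenseLinearSim:
    """Dense linear response with noisy effect sizes as continuous co-data.

    y = X beta + eps with beta_j ~ N(0, beta_sd^2) (every covariate carries
    some signal), standard-normal covariates, and co-data beta + noise.
    Defaults: beta_sd=0.5, noise_sd=1, codata_noise_sd=0.1 — all exposed
    through scenario.knobs.
    """
    rng = np.random.default_rng(scenario.seed)
    p = scenario.p
    beta_sd = float(scenario.knobs.get("beta_sd", 0.5))
    noise_sd = float(scenario.knobs.get("noise_sd", 1.0))
    co_sd = float(scenario.knobs.get("codata_noise_sd", 0.1))
    beta = beta_sd * rng.standard_normal(p)
    X = rng.standard_normal((scenario.N, p))
    y = X @ beta + noise_sd * rng.standard_normal(scenario.N)
    Xt = rng.standard_normal((scenario.Ntest, p))
    yt = Xt @ beta + noise_sd * rng.standard_normal(scenario.Ntest)
    codata = beta + co_sd * rng.standard_normal(p)
    names = _names(p)
    return DenseLinearSim(train=Dataset(X, y, "continuous", names),
                          test=Dataset(Xt, yt, "continuous", names),
                          beta=beta, codata=codata)


class BinaryFixture(NamedTuple):
    train: Dataset
    grouping: np.ndarray            # covariate-type labels
    assoc_scores: np.ndarray        # -logit BH-adjusted p-values (aux cohort)
    dominant_index: int


def simulate_binary_fixture(N: int = 101, p: int = 140, seed: int = 0,
                            event_rate: float = 0.82,
                            dominant_effect: float = 1.2,
                            n_aux: int = 430) -> BinaryFixture:
    """A synthetic stand-in for a lymphoma prognosis cohort.

    Four covariate blocks — 67 copy-number-like continuous scores, 69 binary
    mutation indicators, 3 rare binary translocations, and 1 ordinal
    clinical index (the dominant predictor, in its own co-data group) — with
    a probit response whose positive rate defaults to 82% ("yes").
    Continuous co-data are per-covariate association scores (-logit of
    BH-adjusted p-values) estimated from an auxiliary simulated cohort, so
    the dominant covariate's marginal association is strongest by
    construction.  Synthetic data only: it emulates the structure of the
    real application, not its measurements.
    """
    if p != 67 + 69 + 3 + 1:
        raise ValueError("the fixture uses the 67/69/3/1 block structure")
    rng = np.random.default_rng(seed)

    def draw_block(n):
        cnv = rng.standard_normal((n, 67))
        mut = (rng.random((n, 69)) < 0.25).astype(float)
        trans = (rng.random((n, 3)) < 0.08).astype(float)
        ipi = rng.integers(0, 5, size=(n, 1)).astype(float)
        return np.hstack([cnv, mut, trans, ipi])

    # latent probit score: dominant clinical effect plus weak omics signal
    weak = np.zeros(p)
    weak_idx = rng.choice(139, size=8, replace=False)
    weak[weak_idx] = 0.25 * rng.standard_normal(8)

    def latent(X):
        ipi_std = (X[:, -1] - 2.0) / 1.5
        return dominant_effect * ipi_std + X[:, :-1] @ weak[:-1]

    intercept = float(stats.norm.ppf(event_rate))

    def draw_y(X):
        z = intercept + latent(X) / np.sqrt(1.0 + np.var(latent(X)))
        return (rng.standard_normal(X.shape[0]) < z).astype(float)

    X = draw_block(N)
    y = draw_y(X)
    # guard against an all-one/all-zero draw at tiny N
    if y.min() == y.max():
        y[rng.integers(0, N)] = 1.0 - y[0]

    # auxiliary cohort for the continuous co-data
    Xa = draw_block(n_aux)
    ya = draw_y(Xa)
    pvals = np.empty(p)
    for j in range(p):
        col = Xa[:, j]
        if np.ptp(col) == 0:
            pvals[j] = 1.0
            continue
        pvals[j] = stats.pearsonr(col, ya).pvalue
    from statsmodels.stats.multitest import multipletests
    p_adj = np.clip(multipletests(pvals, method="fdr_bh")[1], 1e-12, 1 - 1e-12)
    scores = -np.log(p_adj / (1.0 - p_adj))  # -logit scale

    grouping = np.array(["cnv"] * 67 + ["mutation"] * 69
                        + ["translocation"] * 3 + ["clinical"])
    names = ([f"cnv{j+1}" for j in range(67)]
             + [f"mut{j+1}" for j in range(69)]
             + [f"tl{j+1}" for j in range(3)] + ["ipi"])
    return BinaryFixture(train=Dataset(X, y, "binary", names),
                         grouping=grouping, assoc_scores=scores,
                         dominant_index=p - 1)
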