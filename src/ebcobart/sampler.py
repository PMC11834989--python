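"""Posterior sampling for BART: backfitting MCMC, probit augmentation, R-hat.

The heavy lifting happens in the compiled kernel; this module prepares the
frozen split-candidate sets, derives per-chain sub-seeds, runs the chains and
packages the kept draws (in-sample fits, sigma^2, and compact per-draw tree
snapshots sufficient to evaluate the tree priors and to predict on new data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import _kernel
from .data import BINARY, CONTINUOUS, Dataset, PriorConfig, RunConfig, child_seed

__all__ = [
    "PosteriorDraws", "run_chains", "candidate_cuts",
    "integrated_leaf_loglik", "leaf_posterior_moments", "draw_terminal_values",
    "draw_sigma2", "probit_augment", "rhat", "convergence_rhat",
]


def candidate_cuts(X: np.ndarray):
    """Frozen split-value sets: midpoints of consecutive distinct values.

    Returns (flat values, offsets) with the cuts of covariate j in
    ``flat[offsets[j]:offsets[j+1]]``.  A constant covariate gets an empty
    set and can never be split on.
    """
    N, p = X.shape
    pieces = []
    offsets = np.zeros(p + 1, dtype=np.int64)
    for j in range(p):
        u = np.unique(X[:, j])
        mids = 0.5 * (u[:-1] + u[1:])
        pieces.append(mids)
        offsets[j + 1] = offsets[j] + mids.size
    flat = np.concatenate(pieces) if pieces else np.empty(0)
    return np.ascontiguousarray(flat, dtype=np.float64), offsets


@dataclass
class PosteriorDraws:
    """Kept MCMC draws pooled over chains.

    ``fits`` holds the in-sample latent fit f(x_i) (including mu0) per draw;
    the snapshot arrays encode every tree of every draw as (heap slot, split
    var, split value, terminal mu) records indexed by ``offsets[draw*K + t]``.
    """

    fits: np.ndarray                 # (n_mc, N)
    sigma2: np.ndarray | None        # (n_mc,) continuous only
    chain: np.ndarray                # (n_mc,) chain index per draw
    offsets: np.ndarray
    slots: np.ndarray
    vars_: np.ndarray
    splits: np.ndarray
    mus: np.ndarray
    K: int
    p: int
    mu0: float
    response_kind: str
    accept_rate: float

    @property
    def n_mc(self) -> int:
        return self.fits.shape[0]

    # --- node summaries (enough to evaluate the tree priors) --------------
    def split_var_indices(self) -> np.ndarray:
        return self.vars_[self.vars_ >= 0]

    def _depths(self, mask) -> np.ndarray:
        return np.floor(np.log2(self.slots[mask] + 1) + 1e-12).astype(np.int64)

    def internal_depths(self) -> np.ndarray:
        return self._depths(self.vars_ >= 0)

    def terminal_depths(self) -> np.ndarray:
        return self._depths(self.vars_ < 0)

    def terminal_mus(self) -> np.ndarray:
        return self.mus[self.vars_ < 0]

    def leaf_counts(self) -> np.ndarray:
        """Number of terminal nodes per (draw, tree)."""
        term = (self.vars_ < 0).astype(np.int64)
        csum = np.concatenate([[0], np.cumsum(term)])
        return csum[self.offsets[1:]] - csum[self.offsets[:-1]]

    # --- prediction -------------------------------------------------------
    def predict_draws(self, X: np.ndarray) -> np.ndarray:
        """Per-draw sum-of-trees predictions on new rows -> (n_mc, M)."""
        X = np.ascontiguousarray(np.atleast_2d(X), dtype=np.float64)
        if X.shape[1] != self.p:
            raise ValueError(f"expected {self.p} columns, got {X.shape[1]}")
        return _kernel.predict_snapshots(
            self.offsets, self.slots, self.vars_, self.splits, self.mus,
            self.K, self.mu0, X)

    def predict_mean(self, X: np.ndarray) -> np.ndarray:
        """Posterior-mean prediction: latent-scale mean (continuous) or
        mean event probability Phi(f) (binary)."""
        f = self.predict_draws(X)
        if self.response_kind == BINARY:
            return stats.norm.cdf(f).mean(axis=0)
        return f.mean(axis=0)


def run_chains(dataset: Dataset, prior: PriorConfig, run: RunConfig,
               seed: int | None = None,
               fixed_sigma2: float | None = None) -> PosteriorDraws:
    """Run ``run.n_chains`` independent backfitting chains and pool the draws.

    Each chain initializes all K trees as terminal roots with mu=0 and
    sigma^2 = Var(y), applies one MH move + conjugate leaf redraw per tree
    per sweep, then refreshes sigma^2 (continuous) or the truncated-normal
    latents (binary).  ``fixed_sigma2`` pins the error variance, which turns
    the chain into a prior sampler as sigma^2 -> inf (used by tests).
    """
    if seed is None:
        seed = run.seed
    X = dataset.X
    binary = dataset.response_kind == BINARY
    cuts_flat, cuts_off = candidate_cuts(X)
    cumS = np.cumsum(prior.S)
    cumS[-1] = 1.0
    ybin = dataset.y.astype(np.int8) if binary else np.zeros(0, dtype=np.int8)
    nu = float(prior.nu) if prior.nu is not None else 0.0
    lam = float(prior.lambda_) if prior.lambda_ is not None else 0.0
    # The 0.5/(k sqrt(K)) terminal-node prior presumes the response mapped to
    # [-0.5, 0.5]; sample on that internal scale and transform the draws back.
    if binary:
        y_s, mid, rng_y = dataset.y, 0.0, 1.0
        mu0_s = float(prior.mu0)
    else:
        ymin, ymax = float(dataset.y.min()), float(dataset.y.max())
        mid, rng_y = 0.5 * (ymin + ymax), ymax - ymin
        if rng_y <= 0:
            raise ValueError("constant continuous response")
        y_s = (dataset.y - mid) / rng_y
        mu0_s = (float(prior.mu0) - mid) / rng_y
        lam = lam / rng_y ** 2
        if fixed_sigma2 is not None:
            fixed_sigma2 = fixed_sigma2 / rng_y ** 2
    move_probs = np.asarray(run.move_probs, dtype=np.float64)
    n_kept = run.n_iter - run.burn_in
    snap_cap0 = max(1024, n_kept * prior.K * 8)

    all_fits, all_sig, all_chain = [], [], []
    all_off, all_slot, all_var, all_split, all_mu = [], [], [], [], []
    node_base = 0
    total_accept = 0
    for c in range(run.n_chains):
        sub = child_seed(seed, c)
        (fits, sig, off, slot, var, split, mu, n_acc) = _kernel.run_chain(
            X, y_s, binary, ybin, cuts_flat, cuts_off, cumS,
            float(prior.alpha), float(prior.beta), float(prior.sigma_mu),
            nu, lam, mu0_s, int(prior.K),
            int(run.n_iter), int(run.burn_in), sub, int(run.max_depth),
            move_probs, int(run.min_node),
            -1.0 if fixed_sigma2 is None else float(fixed_sigma2),
            snap_cap0)
        if not np.all(np.isfinite(fits)):
            raise FloatingPointError("non-finite fit detected in chain "
                                     f"{c}; state dumped with the draws")
        all_fits.append(mid + rng_y * fits if not binary else fits)
        all_sig.append(sig * rng_y ** 2 if not binary else sig)
        all_chain.append(np.full(n_kept, c, dtype=np.int32))
        all_off.append(off[1:] + node_base if c else off)
        node_base += slot.size
        all_slot.append(slot)
        all_var.append(var)
        all_split.append(split)
        all_mu.append(mu * rng_y if not binary else mu)
        total_accept += n_acc
    offsets = np.concatenate(all_off)
    draws = PosteriorDraws(
        fits=np.concatenate(all_fits),
        sigma2=None if binary else np.concatenate(all_sig),
        chain=np.concatenate(all_chain),
        offsets=offsets,
        slots=np.concatenate(all_slot),
        vars_=np.concatenate(all_var),
        splits=np.concatenate(all_split),
        mus=np.concatenate(all_mu),
        K=prior.K, p=dataset.p,
        mu0=float(prior.mu0) if binary else mid + rng_y * mu0_s,
        response_kind=dataset.response_kind,
        accept_rate=total_accept / (run.n_chains * run.n_iter * prior.K),
    )
    return draws


# --- conjugate/primitive operations (single source also used by tests) -----

def integrated_leaf_loglik(resid, sigma2: float, sigma_mu: float) -> float:
    """log integral of prod_i N(r_i; mu, sigma2) * N(mu; 0, sigma_mu^2) dmu."""
    r = np.asarray(resid, dtype=np.float64)
    n = r.size
    if n == 0:
        return 0.0
    s = r.sum()
    sig2mu = sigma_mu * sigma_mu
    denom = sigma2 + n * sig2mu
    return (-0.5 * n * np.log(2.0 * np.pi * sigma2)
            + 0.5 * np.log(sigma2 / denom)
            - np.dot(r, r) / (2.0 * sigma2)
            + sig2mu * s * s / (2.0 * sigma2 * denom))


def leaf_posterior_moments(n: int, resid_sum: float, sigma2: float,
                           sigma_mu: float):
    """Normal-normal posterior (mean, var) for a leaf value."""
    sig2mu = sigma_mu * sigma_mu
    denom = sigma2 + n * sig2mu
    return sig2mu * resid_sum / denom, sigma2 * sig2mu / denom


def draw_terminal_values(tree, X, partial_resid, sigma2: float,
                         sigma_mu: float, rng: np.random.Generator):
    """Refresh a Tree's terminal mus from their conjugate posteriors."""
    from .trees import predict_tree  # noqa: F401  (structure walk below)
    X = np.atleast_2d(X)
    leaves = {}
    for i in range(X.shape[0]):
        nd = tree.root
        while not nd.is_terminal:
            nd = nd.left if X[i, nd.split_var] <= nd.split_value else nd.right
        leaves.setdefault(id(nd), [nd, 0, 0.0])
        rec = leaves[id(nd)]
        rec[1] += 1
        rec[2] += partial_resid[i]
    for nd in tree.nodes()[1]:
        rec = leaves.get(id(nd), [nd, 0, 0.0])
        mean, var = leaf_posterior_moments(rec[1], rec[2], sigma2, sigma_mu)
        nd.mu = float(mean + np.sqrt(var) * rng.standard_normal())
    return tree


def draw_sigma2(resid, nu: float, lambda_: float,
                rng: np.random.Generator) -> float:
    """sigma^2 ~ InvGamma((nu+N)/2, (nu*lambda + sum r^2)/2)."""
    r = np.asarray(resid, dtype=np.float64)
    shape = 0.5 * (nu + r.size)
    rate = 0.5 * (nu * lambda_ + np.dot(r, r))
    return rate / rng.gamma(shape)


def probit_augment(y, f, rng: np.random.Generator) -> np.ndarray:
    """Albert-Chib latents: z_i ~ N(f_i, 1) truncated by the sign rule of y_i."""
    y = np.asarray(y)
    f = np.asarray(f, dtype=np.float64)
    u = rng.uniform(size=f.shape)
    lo = stats.norm.cdf(-f)          # P(z <= 0 | f)
    z = np.empty_like(f)
    pos = y == 1
    # inverse-cdf on the truncated region; clip guards the extreme tails
    z[pos] = f[pos] + stats.norm.ppf(
        np.clip(lo[pos] + u[pos] * (1.0 - lo[pos]), 1e-16, 1 - 1e-16))
    z[~pos] = f[~pos] + stats.norm.ppf(
        np.clip(u[~pos] * lo[~pos], 1e-16, 1 - 1e-16))
    return z


# --- convergence diagnostics ----------------------------------------------

def _classic_rhat(x: np.ndarray) -> float:
    """Classic potential scale reduction on an (m, n) array of chains."""
    m, n = x.shape
    cm = x.mean(axis=1)
    W = x.var(axis=1, ddof=1).mean()
    B = n * cm.var(ddof=1)
    if W <= 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def _rank_normalize(x: np.ndarray) -> np.ndarray:
    flat = x.reshape(-1)
    ranks = stats.rankdata(flat, method="average")
    z = stats.norm.ppf((ranks - 3.0 / 8.0) / (flat.size + 0.25))
    return z.reshape(x.shape)


def rhat(chain_draws) -> float:
    """Rank-normalized split R-hat (max of bulk and folded variants).

    ``chain_draws`` is an (n_chains, n_draws) array; chains are split in
    half, the pooled draws rank-normalized, and the classic R-hat taken on
    the transformed halves.  Constant draws return 1 by convention.
    """
    x = np.asarray(chain_draws, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 4:
        raise ValueError("need >= 2 chains with >= 4 draws each")
    if np.ptp(x) == 0:
        return 1.0
    n = x.shape[1] // 2
    halves = np.concatenate([x[:, :n], x[:, n:2 * n]], axis=0)
    bulk = _classic_rhat(_rank_normalize(halves))
    folded = _classic_rhat(_rank_normalize(np.abs(halves - np.median(halves))))
    return max(bulk, folded)


def convergence_rhat(draws: PosteriorDraws) -> float:
    """The convergence scalar used for reporting: R-hat of sigma^2
    (continuous) or the max over observations of the fit R-hat (binary)."""
    chains = np.unique(draws.chain)
    if chains.size < 2:
        raise ValueError("R-hat needs at least two chains")
    if draws.response_kind == CONTINUOUS:
        per = np.stack([draws.sigma2[draws.chain == c] for c in chains])
        return rhat(per)
    worst = 1.0
    for i in range(draws.fits.shape[1]):
        per = np.stack([draws.fits[draws.chain == c, i] for c in chains])
        worst = max(worst, rhat(per))
    return worst
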