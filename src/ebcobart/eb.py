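"""Monte-Carlo-EM empirical-Bayes estimators for the BART prior parameters.

Each EB update maximizes the Monte-Carlo approximation of the expected
complete-data log prior — the sum, over posterior draws, of the log prior
density of the sampled tree structures, terminal values and error variance —
with respect to one prior parameter at a time.  The covariate-weight update
has the closed form b_j/B (split-rule relative frequencies); k and alpha
invert/maximize the terminal-node and depth prior terms; (nu, lambda) is an
inverse-gamma maximum-likelihood fit to the sigma^2 draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .data import BINARY, CONTINUOUS
from .sampler import PosteriorDraws

__all__ = [
    "SplitCounts", "EBUpdate", "DegenerateForestError",
    "count_splits", "eb_update_S_raw", "eb_update_k", "eb_update_alpha",
    "eb_update_nu_lambda",
]


class DegenerateForestError(RuntimeError):
    """All sampled forests are terminal roots: no splitting rules to count."""


@dataclass
class SplitCounts:
    """Split-rule counts per covariate, pooled over draws, chains and trees."""

    b: np.ndarray          # (p,) int64
    q: int = 0

    def __post_init__(self):
        self.b = np.asarray(self.b, dtype=np.int64)
        if np.any(self.b < 0):
            raise ValueError("split counts must be non-negative")

    @property
    def B(self) -> int:
        return int(self.b.sum())


@dataclass
class EBUpdate:
    S1: np.ndarray | None
    k_hat: float | None = None
    alpha_hat: float | None = None
    nu_hat: float | None = None
    lambda_hat: float | None = None
    q: int = 0


def count_splits(draws: PosteriorDraws, p: int | None = None) -> SplitCounts:
    """b_j = number of splitting rules using covariate j over all kept draws."""
    if p is None:
        p = draws.p
    sv = draws.split_var_indices()
    return SplitCounts(b=np.bincount(sv, minlength=p))


def eb_update_S_raw(counts: SplitCounts) -> np.ndarray:
    """The raw EB covariate-weight estimate (b_1/B, ..., b_p/B)."""
    B = counts.B
    if B == 0:
        raise DegenerateForestError(
            "no splitting rules in the posterior sample; keep the previous S")
    return counts.b / B


def eb_update_k(draws: PosteriorDraws, K: int | None = None,
                response_kind: str | None = None,
                clip: tuple = (0.1, 10.0)) -> float:
    """Invert the terminal-node prior sd from the sampled leaf values.

    The maximizer of sum_m log N(mu; 0, sigma_mu(k)^2) sets sigma_mu^2 to the
    plain second moment of the sampled terminal values, then k follows from
    sigma_mu = 0.5/(k sqrt(K)) (continuous) or 3/(k sqrt(K)) (binary).
    """
    if K is None:
        K = draws.K
    if response_kind is None:
        response_kind = draws.response_kind
    mus = draws.terminal_mus() if isinstance(draws, PosteriorDraws) else np.asarray(draws)
    if mus.size == 0:
        raise ValueError("no terminal values recorded")
    sig_hat = float(np.sqrt(np.mean(mus ** 2)))
    num = 0.5 if response_kind == CONTINUOUS else 3.0
    if sig_hat == 0.0:
        import warnings
        warnings.warn("all terminal values are zero; clipping k at the upper bound")
        return clip[1]
    return float(np.clip(num / (sig_hat * np.sqrt(K)), clip[0], clip[1]))


def eb_update_alpha(draws, beta: float,
                    bounds: tuple = (0.01, 0.99), tol: float = 1e-5) -> float:
    """Maximize the depth terms of the tree-structure prior over alpha.

    Accepts PosteriorDraws or a pair (internal_depths, terminal_depths).
    beta is held fixed; the 1-D maximization uses bounded golden-section.
    """
    if isinstance(draws, PosteriorDraws):
        d_int = draws.internal_depths()
        d_term = draws.terminal_depths()
    else:
        d_int, d_term = (np.asarray(d) for d in draws)
    if d_int.size + d_term.size == 0:
        raise ValueError("no node depths recorded")
    # depth histograms make the objective O(max_depth) per evaluation
    ci = np.bincount(d_int) if d_int.size else np.zeros(1, dtype=np.int64)
    ct = np.bincount(d_term)
    di = np.arange(ci.size)
    dt = np.arange(ct.size)

    def neg_obj(alpha):
        pi_ = alpha * (1.0 + di) ** (-beta)
        pt = alpha * (1.0 + dt) ** (-beta)
        return -(np.sum(ci * np.log(pi_)) + np.sum(ct * np.log1p(-pt)))

    res = optimize.minimize_scalar(neg_obj, bounds=bounds, method="bounded",
                                   options={"xatol": tol})
    return float(res.x)


def eb_update_nu_lambda(sigma2_draws, nu_bounds: tuple = (2.1, 200.0)):
    """Inverse-gamma ML fit to sigma^2 draws in the (nu, lambda) form.

    The sigma^2 prior is IG(nu/2, nu*lambda/2).  At fixed nu the stationarity
    condition in lambda gives the harmonic mean of the draws (independent of
    nu); nu is then profiled by a bounded 1-D search.
    """
    x = np.asarray(sigma2_draws, dtype=np.float64)
    if x.size < 10:
        raise ValueError("need at least 10 sigma^2 draws")
    if np.any(x <= 0) or float(np.var(x)) == 0.0:
        raise ValueError("degenerate sigma^2 draws")
    n = x.size
    mean_log = float(np.mean(np.log(x)))
    mean_inv = float(np.mean(1.0 / x))
    lam_hat = 1.0 / mean_inv  # harmonic mean

    def neg_profile(nu):
        a = 0.5 * nu
        b = 0.5 * nu * lam_hat  # nu*lambda/2 with the profiled lambda
        ll = (a * np.log(b) - special.gammaln(a)
              - (a + 1.0) * mean_log - b * mean_inv)
        return -n * ll

    res = optimize.minimize_scalar(neg_profile, bounds=nu_bounds,
                                   method="bounded", options={"xatol": 1e-6})
    return float(res.x), float(lam_hat)
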