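"""WAIC for Gaussian and probit BART posteriors and the min-WAIC stopping rule.

WAIC = -2 * lppd + 2 * p_waic, with lppd the summed log pointwise predictive
density (log of the posterior-mean density per observation) and p_waic the
summed posterior variance of the pointwise log densities.  The empirical-
Bayes loop tracks WAIC across iterations and returns the fit at the global
minimum; the criterion is asymptotically equivalent to leave-one-out
cross-validation, which is what makes it a cheap surrogate for tracking the
marginal likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .data import BINARY, Dataset
from .sampler import PosteriorDraws

__all__ = ["WAICEntry", "WAICTrace", "pointwise_loglik", "waic",
           "select_min_waic"]


@dataclass
class WAICEntry:
    q: int
    waic: float
    lppd: float
    penalty: float


@dataclass
class WAICTrace:
    entries: list = field(default_factory=list)

    def append(self, q: int, waic_v: float, lppd: float, penalty: float):
        self.entries.append(WAICEntry(q=q, waic=waic_v, lppd=lppd,
                                      penalty=penalty))

    def values(self) -> np.ndarray:
        return np.array([e.waic for e in self.entries])


def pointwise_loglik(draws: PosteriorDraws, dataset: Dataset) -> np.ndarray:
    """(n_mc, N) matrix of per-draw, per-observation log predictive densities."""
    f = draws.fits
    y = dataset.y
    if f.shape[1] != y.size:
        raise ValueError("draws and dataset are not aligned")
    if dataset.response_kind == BINARY:
        logp1 = stats.norm.logcdf(f)
        logp0 = stats.norm.logcdf(-f)
        return np.where(y[None, :] == 1.0, logp1, logp0)
    s2 = draws.sigma2[:, None]
    return -0.5 * (np.log(2.0 * np.pi * s2) + (y[None, :] - f) ** 2 / s2)


def waic(loglik: np.ndarray):
    """(WAIC, lppd, penalty) from an (n_mc, N) pointwise log-likelihood matrix.

    lppd uses log-sum-exp over draws; the penalty is the sample variance
    (divisor n_mc - 1) of the log densities, summed over observations.
    """
    ll = np.asarray(loglik, dtype=np.float64)
    n_mc = ll.shape[0]
    if n_mc < 2:
        raise ValueError("need at least 2 draws for the WAIC variance term")
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(n_mc)))
    penalty = float(np.sum(np.var(ll, axis=0, ddof=1)))
    return -2.0 * lppd + 2.0 * penalty, lppd, penalty


def select_min_waic(trace: WAICTrace) -> int:
    """Iteration index of the global WAIC minimum; ties go to the smaller q
    (less prior adaptation)."""
    if not trace.entries:
        raise ValueError("empty WAIC trace")
    vals = trace.values()
    best = int(np.argmin(vals))  # argmin returns the first (smallest q) tie
    return trace.entries[best].q
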