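"""Performance metrics, replicated BART-vs-EB-coBART experiments, partial
dependence and learning curves."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .codata import build_codata_matrix
from .data import BINARY, Dataset, RunConfig, child_seed, preset_prior
from .ebco import EBcoResult, fit_bart, predict, run_ebcobart
from .simulate import (SimScenario, make_group_codata,
                       make_uninformative_codata, simulate_friedman)

__all__ = ["pmse", "brier", "auc", "ReplicateResult",
           "pmse_ratio_experiment", "partial_dependence", "learning_curve"]


def pmse(y_test, y_hat) -> float:
    """Prediction mean squared error with divisor Ntest."""
    y_test = np.asarray(y_test, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y_test.shape != y_hat.shape:
        raise ValueError("length mismatch")
    return float(np.mean((y_test - y_hat) ** 2))


def brier(y_binary, p_hat) -> float:
    """Mean squared distance between event probabilities and outcomes."""
    y = np.asarray(y_binary, dtype=np.float64)
    p = np.asarray(p_hat, dtype=np.float64)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean((p - y) ** 2))


def auc(y_binary, score) -> float:
    """Area under the ROC curve (Mann-Whitney form, ties counted 1/2)."""
    y = np.asarray(y_binary)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(y, np.asarray(score, dtype=np.float64)))


@dataclass
class ReplicateResult:
    """Per-replicate PMSEs of both arms on the shared test set."""

    pmse_bart: np.ndarray
    pmse_ebco: np.ndarray
    weights: list                   # q_star weight vectors per replicate
    q_stars: np.ndarray
    seeds: np.ndarray

    @property
    def ratio(self) -> np.ndarray:
        return self.pmse_ebco / self.pmse_bart

    def summary(self) -> dict:
        r = self.ratio
        return {
            "mean_pmse_bart": float(self.pmse_bart.mean()),
            "mean_pmse_ebco": float(self.pmse_ebco.mean()),
            "mean_ratio": float(r.mean()),
            "frac_ratio_gt_1": float(np.mean(r > 1.0)),
            "n_reps": int(r.size),
        }


def pmse_ratio_experiment(n_reps: int, N: int = 100, p: int = 500,
                          G: int = 20, preset: str = "flexible",
                          bart_run: RunConfig | None = None,
                          eb_run: RunConfig | None = None,
                          uninformative: bool = False,
                          seed: int = 0, Ntest: int = 500,
                          mode: str = "ebco1") -> ReplicateResult:
    """Fit BART and EB-coBART on identical replicated Friedman data sets and
    evaluate both on the shared test set.

    ``bart_run``/``eb_run`` carry the chain settings for the two arms; the
    BART arm equals the first EB iteration, so forcing ``max_eb_iter=1``
    with identical settings gives ratio 1 on every replicate.
    """
    if n_reps < 1:
        raise ValueError("need at least one replicate")
    if bart_run is None:
        bart_run = RunConfig(preset=preset)
    if eb_run is None:
        eb_run = bart_run
    pm_b = np.empty(n_reps)
    pm_e = np.empty(n_reps)
    q_stars = np.empty(n_reps, dtype=np.int64)
    weights = []
    seeds = np.empty(n_reps, dtype=np.int64)
    for r in range(n_reps):
        rep_seed = child_seed(seed, 100 + r)
        seeds[r] = rep_seed
        sim = simulate_friedman(SimScenario(N=N, p=p, G=G, Ntest=Ntest,
                                            seed=rep_seed))
        if uninformative:
            groups = make_uninformative_codata(p, G, child_seed(rep_seed, 7))
        else:
            groups = make_group_codata(p, G)
        cmat = build_codata_matrix({"group": ("grouping", groups)}, p)
        prior = preset_prior(preset, "continuous", sim.train.y, p)
        b_run = bart_run.__class__(**{**bart_run.__dict__, "seed": rep_seed,
                                      "preset": preset, "max_eb_iter": 1})
        e_run = eb_run.__class__(**{**eb_run.__dict__, "seed": rep_seed,
                                    "preset": preset})
        draws_b = fit_bart(sim.train, prior, b_run)
        pm_b[r] = pmse(sim.test.y, draws_b.predict_mean(sim.test.X))
        res = run_ebcobart(sim.train, cmat, e_run, mode=mode, prior=prior)
        pm_e[r] = pmse(sim.test.y, predict(res, sim.test.X))
        q_stars[r] = res.q_star
        weights.append(res.weights_star)
    return ReplicateResult(pmse_bart=pm_b, pmse_ebco=pm_e, weights=weights,
                           q_stars=q_stars, seeds=seeds)


def partial_dependence(result, X, j: int, grid) -> tuple:
    """Marginal effect of covariate j on the latent prediction.

    For each grid value g, covariate j of every training row is forced to g
    and the per-draw mean prediction recorded; returns (mean, sd) across
    posterior draws — the latent (probit) scale for binary responses.
    """
    draws = result.draws if isinstance(result, EBcoResult) else result
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    grid = np.asarray(grid, dtype=np.float64)
    means = np.empty(grid.size)
    sds = np.empty(grid.size)
    for g_idx, g in enumerate(grid):
        Xg = X.copy()
        Xg[:, j] = g
        per_draw = draws.predict_draws(Xg).mean(axis=1)
        means[g_idx] = per_draw.mean()
        sds[g_idx] = per_draw.std(ddof=1)
    return means, sds


def learning_curve(dataset: Dataset, codata, run: RunConfig,
                   subsample_sizes, reps_per_size: int = 3,
                   mode: str = "ebco2", metric: str = "auc",
                   seed: int = 0) -> dict:
    """Average out-of-sample performance as a function of training size.

    For each size n, training sets are drawn without replacement and the
    model evaluated on the left-out complement; degenerate test sets (fewer
    than 2 samples, or single-class for the AUC) skip the replicate with a
    warning.
    """
    import warnings
    rng = np.random.default_rng(seed)
    out = {}
    for n in subsample_sizes:
        if n >= dataset.n:
            raise ValueError("subsample size must be below N")
        vals = []
        for r in range(reps_per_size):
            idx = rng.permutation(dataset.n)
            tr, te = idx[:n], idx[n:]
            if te.size < 2 or (dataset.response_kind == BINARY
                               and np.unique(dataset.y[te]).size < 2):
                warnings.warn(f"size {n}, rep {r}: degenerate test set; skipped")
                continue
            sub = Dataset(dataset.X[tr], dataset.y[tr], dataset.response_kind,
                          dataset.covariate_names)
            if dataset.response_kind == BINARY and np.unique(sub.y).size < 2:
                warnings.warn(f"size {n}, rep {r}: single-class training; skipped")
                continue
            run_r = run.__class__(**{**run.__dict__,
                                     "seed": child_seed(seed, n, r)})
            res = run_ebcobart(sub, codata, run_r, mode=mode)
            yhat = predict(res, dataset.X[te])
            if metric == "auc":
                vals.append(auc(dataset.y[te], yhat))
            elif metric == "pmse":
                vals.append(pmse(dataset.y[te], yhat))
            elif metric == "brier":
                vals.append(brier(dataset.y[te], yhat))
            else:
                raise ValueError(f"unknown metric {metric!r}")
        out[int(n)] = float(np.mean(vals)) if vals else np.nan
    return out
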