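"""The co-data model: smoothing raw split proportions into prior weights.

Co-data are external variables on the *covariates* (not the samples): a
grouping (dummy-coded, with missingness as its own group) and/or continuous
scores such as -logit-scale adjusted p-values from a related study.  The
split-rule count of covariate j is treated as binomial, b_j ~ Bin(w_j, B),
and w_j = expit(c_j' eta) is fit by grouped-binomial maximum likelihood with
the p covariates acting as samples (their dependencies deliberately
ignored).  Because the model carries an intercept, the fitted weights sum to
one and need no renormalization; they are the co-data-guided covariate
weights handed to the next BART fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .eb import SplitCounts

__all__ = ["CoDataMatrix", "CoDataFit", "CoDataError",
           "build_codata_matrix", "fit_codata_model", "codata_weights"]


class CoDataError(ValueError):
    pass


@dataclass
class CoDataMatrix:
    """p x (kappa+1) model matrix; first column is the intercept."""

    C: np.ndarray
    column_names: list[str]
    source_tags: list[str]          # intercept | grouping:<level> | continuous

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=np.float64)
        if self.C.ndim != 2:
            raise ValueError("C must be a matrix")
        if not np.all(np.isfinite(self.C)):
            raise ValueError("co-data matrix must be complete")
        if not np.all(self.C[:, 0] == 1.0):
            raise ValueError("first column must be the intercept")
        if len(self.column_names) != self.C.shape[1]:
            raise ValueError("column_names length mismatch")

    @property
    def p(self) -> int:
        return self.C.shape[0]


@dataclass
class CoDataFit:
    eta: np.ndarray
    w: np.ndarray
    n_iter: int
    converged: bool
    deviance: float
    column_names: list[str]


def build_codata_matrix(sources, p: int,
                        missing_policy: str = "own_group") -> CoDataMatrix:
    """Assemble the co-data model matrix from raw per-covariate sources.

    ``sources`` maps a source name to ``("grouping", labels)`` or
    ``("continuous", values)``, each of length p.  Groupings are reference-
    coded (first sorted level dropped against the intercept); missing labels
    become their own ``missing`` level under the default policy.  Continuous
    sources are passed through unchanged — any transform (e.g. -logit of
    BH-adjusted p-values) belongs to the caller.
    """
    cols = [np.ones(p)]
    names = ["intercept"]
    tags = ["intercept"]
    for name, (kind, values) in sources.items():
        if len(values) != p:
            raise CoDataError(f"co-data source {name!r} has {len(values)} "
                              f"entries, expected {p}")
        if kind == "grouping":
            lab = pd.Series(values, dtype=object)
            if missing_policy == "own_group":
                lab = lab.where(~lab.isna(), "missing")
            elif lab.isna().any():
                raise CoDataError(f"missing labels in grouping {name!r}")
            levels = sorted(map(str, lab.unique()))
            lab = lab.astype(str)
            counts = lab.value_counts()
            for lv in levels[1:]:
                if counts.get(lv, 0) == 0:
                    warnings.warn(f"level {lv!r} of {name!r} has no members; dropped")
                    continue
                cols.append((lab == lv).to_numpy(dtype=np.float64))
                names.append(f"{name}:{lv}")
                tags.append(f"grouping:{lv}")
        elif kind == "continuous":
            v = np.asarray(values, dtype=np.float64)
            if not np.all(np.isfinite(v)):
                raise CoDataError(f"missing values in continuous source {name!r}")
            if np.ptp(v) == 0:
                warnings.warn(f"continuous co-data source {name!r} is constant")
            cols.append(v)
            names.append(name)
            tags.append("continuous")
        else:
            raise CoDataError(f"unknown co-data kind {kind!r}")
    return CoDataMatrix(C=np.column_stack(cols), column_names=names,
                        source_tags=tags)


def _binom_negll(eta, C, b, B):
    lin = C @ eta
    # log Bin(b; expit(lin), B) up to the constant binomial coefficient
    return -(np.sum(b * lin) - B * np.sum(np.logaddexp(0.0, lin)))


def fit_codata_model(counts: SplitCounts, C: CoDataMatrix,
                     tol: float = 1e-8, max_iter: int = 100,
                     ridge_fallback: float = 1e-6) -> CoDataFit:
    """Grouped-binomial logistic fit of the split counts on the co-data.

    Newton-Raphson with step-halving on the log likelihood; a rank-deficient
    model matrix raises, naming the dependent columns; (quasi-)separation
    triggers a tiny-ridge refit with a warning.
    """
    Cm = C.C
    p, ncol = Cm.shape
    b = counts.b.astype(np.float64)
    B = float(counts.B)
    if B <= 0:
        raise CoDataError("no splitting rules: B must be positive")
    rank = np.linalg.matrix_rank(Cm)
    if rank < ncol:
        # name columns involved in the dependency via QR pivoting
        _, R = np.linalg.qr(Cm)
        bad = [C.column_names[j] for j in range(ncol)
               if abs(R[min(j, R.shape[0] - 1), j]) < 1e-10]
        raise CoDataError(f"co-data matrix is rank deficient; dependent "
                          f"columns: {bad}")

    def newton(penalty):
        eta = np.zeros(ncol)
        eta[0] = float(np.log(1.0 / (p - 1.0)))  # logit(1/p): uniform start
        ll = -_binom_negll(eta, Cm, b, B) - 0.5 * penalty * eta @ eta
        for it in range(1, max_iter + 1):
            w = expit(Cm @ eta)
            grad = Cm.T @ (b - B * w) - penalty * eta
            if np.linalg.norm(grad) < tol * max(1.0, B):
                return eta, it, True, ll
            W = B * w * (1.0 - w)
            H = Cm.T @ (Cm * W[:, None]) + penalty * np.eye(ncol)
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                return eta, it, False, ll
            t = 1.0
            for _ in range(50):
                cand = eta + t * step
                ll_new = (-_binom_negll(cand, Cm, b, B)
                          - 0.5 * penalty * cand @ cand)
                if ll_new >= ll - 1e-12:
                    eta = cand
                    ll = ll_new
                    break
                t *= 0.5
            else:
                return eta, it, False, ll
        return eta, max_iter, False, ll

    eta, n_iter, converged, _ = newton(0.0)
    if not converged or not np.all(np.isfinite(eta)) or \
            float(np.max(np.abs(eta))) > 30.0:
        warnings.warn("separation or non-convergence in the co-data model; "
                      "refitting with a tiny ridge penalty")
        eta, n_iter, converged, _ = newton(ridge_fallback)
        if not converged:
            raise CoDataError("co-data model did not converge")
    w = expit(Cm @ eta)
    # deviance against the saturated model (b_j/B), guarding empty counts
    with np.errstate(divide="ignore", invalid="ignore"):
        ws = b / B
        dev = 2.0 * np.nansum(b * (np.log(ws) - np.log(w))
                              + (B - b) * (np.log1p(-ws) - np.log1p(-w)))
    return CoDataFit(eta=eta, w=w, n_iter=n_iter, converged=converged,
                     deviance=float(dev), column_names=list(C.column_names))


def codata_weights(fit: CoDataFit, atol: float = 1e-6) -> np.ndarray:
    """The co-data-guided weights (w_1, ..., w_p).

    The intercept calibrates the fit, so the weights sum to one without
    renormalization; the identity is asserted and only repaired (with a
    warning) if violated numerically.
    """
    if not fit.converged:
        raise CoDataError("co-data fit did not converge")
    w = fit.w
    total = float(w.sum())
    if abs(total - 1.0) > atol:
        warnings.warn(f"calibration identity violated (sum w = {total:.8f}); "
                      "renormalizing")
        w = w / total
    return w
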