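"""Domain types, delimited-matrix I/O, prior presets and seed management.

The primary data are an ``N x p`` covariate matrix with a continuous or
binary response, read from delimited text with a header row; priors follow
the two standard tree-flexibility presets (*rigid* and *flexible*) with the
error-variance prior calibrated to the response scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Dataset", "PriorConfig", "RunConfig",
    "MatrixFormatError", "MatrixParseError", "CalibrationError",
    "read_labeled_matrix", "write_labeled_matrix",
    "preset_prior", "calibrate_lambda", "sigma_mu_for", "child_seed",
    "write_manifest",
]

CONTINUOUS = "continuous"
BINARY = "binary"


class MatrixFormatError(ValueError):
    """Ragged or structurally invalid delimited matrix."""


class MatrixParseError(ValueError):
    """Non-numeric cell outside the header/label positions."""


class CalibrationError(ValueError):
    """Prior calibration impossible (e.g. constant continuous response)."""


@dataclass
class Dataset:
    """Primary data: covariates ``X`` (N x p) and response ``y`` (length N)."""

    X: np.ndarray
    y: np.ndarray
    response_kind: str
    covariate_names: list[str]
    sample_ids: list[str] | None = None

    def __post_init__(self):
        self.X = np.ascontiguousarray(np.asarray(self.X, dtype=np.float64))
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValueError("X must be two-dimensional")
        n, p = self.X.shape
        if n < 2:
            raise ValueError("need at least 2 observations")
        if p < 1:
            raise ValueError("need at least 1 covariate")
        if self.y.shape != (n,):
            raise ValueError("y length must match the number of rows of X")
        if self.response_kind not in (CONTINUOUS, BINARY):
            raise ValueError(f"unknown response_kind {self.response_kind!r}")
        if not np.all(np.isfinite(self.X)) or not np.all(np.isfinite(self.y)):
            raise ValueError("missing/non-finite entries are not supported")
        if self.response_kind == BINARY and not np.all(np.isin(self.y, (0.0, 1.0))):
            raise ValueError("binary response must contain only 0/1")
        if len(self.covariate_names) != p:
            raise ValueError("covariate_names length must equal p")
        if len(set(self.covariate_names)) != p:
            raise ValueError("covariate_names must be unique")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def sigma_mu_for(k: float, K: int, response_kind: str) -> float:
    """Terminal-node prior sd: 0.5/(k sqrt(K)) continuous, 3/(k sqrt(K)) binary."""
    num = 0.5 if response_kind == CONTINUOUS else 3.0
    return num / (k * np.sqrt(K))


@dataclass
class PriorConfig:
    """All BART prior parameters: (alpha, beta, k, nu, lambda, S) plus mu0, K."""

    alpha: float
    beta: float
    k: float
    K: int
    S: np.ndarray
    mu0: float
    nu: float | None = None
    lambda_: float | None = None
    response_kind: str = CONTINUOUS

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.beta <= 0 or self.k <= 0 or self.K < 1:
            raise ValueError("beta, k must be positive and K >= 1")
        self.S = np.asarray(self.S, dtype=np.float64)
        if np.any(self.S < 0) or abs(self.S.sum() - 1.0) > 1e-6:
            raise ValueError("S must be a probability vector summing to 1")
        self.S = self.S / self.S.sum()  # exact simplex after tiny GLM slack
        if self.response_kind == CONTINUOUS:
            if self.nu is None or self.lambda_ is None:
                raise ValueError("continuous responses need (nu, lambda_)")
            if self.nu <= 0 or self.lambda_ <= 0:
                raise ValueError("nu and lambda_ must be positive")

    @property
    def sigma_mu(self) -> float:
        return sigma_mu_for(self.k, self.K, self.response_kind)

    def with_updates(self, **kw) -> "PriorConfig":
        return replace(self, **kw)


@dataclass
class RunConfig:
    """Sampler and EB-loop settings."""

    n_chains: int = 1
    n_iter: int = 2000
    burn_in: int = 1000
    max_eb_iter: int = 10
    estimate_set: frozenset = frozenset({"S"})
    preset: str = "flexible"
    seed: int = 0
    patience: int = 5
    max_depth: int = 12
    min_node: int = 1
    move_probs: tuple = (0.25, 0.25, 0.40, 0.10)

    def __post_init__(self):
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.max_eb_iter < 1:
            raise ValueError("max_eb_iter must be >= 1")
        if abs(sum(self.move_probs) - 1.0) > 1e-9 or len(self.move_probs) != 4:
            raise ValueError("move_probs must be 4 probabilities summing to 1")
        self.estimate_set = frozenset(self.estimate_set)


def _detect_delimiter(header: str) -> str:
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_labeled_matrix(path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a delimited numeric matrix with a header row and row labels.

    The first column holds row labels.  Raises :class:`MatrixFormatError`
    for ragged rows and :class:`MatrixParseError` (naming the offending
    row/column) for non-numeric cells.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() != ""]
    if not lines:
        raise MatrixFormatError(f"{path}: empty file")
    if delimiter is None:
        delimiter = _detect_delimiter(lines[0])
    header = lines[0].split(delimiter)
    body = [ln.split(delimiter) for ln in lines[1:]]
    if not body:
        raise MatrixFormatError(f"{path}: no data rows")
    ncol = len(body[0])
    for i, row in enumerate(body[1:], start=3):
        if len(row) != ncol:
            raise MatrixFormatError(f"{path}: ragged row at line {i}")
    # the header may or may not carry a leading label-column name
    if len(header) == ncol:
        col_names = header[1:]
    elif len(header) == ncol - 1:
        col_names = header
    else:
        raise MatrixFormatError(f"{path}: ragged header row")
    index = [row[0] for row in body]
    values = np.empty((len(body), len(col_names)))
    for i, row in enumerate(body):
        for j, cell in enumerate(row[1:]):
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise MatrixParseError(
                    f"{path}: non-numeric value {cell!r} at row "
                    f"{index[i]!r}, column {col_names[j]!r}") from None
    return pd.DataFrame(values, index=index, columns=col_names)


def write_labeled_matrix(df: pd.DataFrame, path, delimiter: str = ",") -> None:
    df.to_csv(path, sep=delimiter, index=True, float_format="%.17g")


def calibrate_lambda(y, nu: float, q: float = 0.75,
                     target_mult: float = 2.0 / 3.0) -> float:
    """Scale lambda so the ``q`` prior quantile of sigma^2 hits the target.

    The sigma^2 prior is InvGamma(nu/2, nu*lambda/2); its quantile is linear
    in the scale, so the calibration ``Q_q(sigma^2) = target_mult * Var(y)``
    is solved exactly by rescaling the unit-scale quantile.
    """
    y = np.asarray(y, dtype=np.float64)
    vy = float(np.var(y, ddof=1))
    if not vy > 0:
        raise CalibrationError("response variance is zero; cannot calibrate lambda")
    target = target_mult * vy
    unit_q = stats.invgamma.ppf(q, nu / 2.0, scale=1.0)
    if not np.isfinite(unit_q) or unit_q <= 0:
        raise CalibrationError(f"invalid inverse-gamma quantile for nu={nu}")
    lam = 2.0 * target / (nu * unit_q)
    realized = stats.invgamma.ppf(q, nu / 2.0, scale=nu * lam / 2.0)
    if abs(realized - target) > 1e-6 * target:
        raise CalibrationError("lambda calibration did not converge")
    return lam


_PRESETS = {"rigid": (0.1, 4.0, 1.0), "flexible": (0.95, 2.0, 2.0)}


def preset_prior(preset: str, response_kind: str, y, p: int, K: int = 50,
                 nu: float = 10.0, q: float = 0.75,
                 target_mult: float = 2.0 / 3.0) -> PriorConfig:
    """Standard prior presets: rigid (0.1, 4, k=1) or flexible (0.95, 2, k=2).

    S starts uniform; mu0 is the mean response (continuous) or its probit
    (binary); continuous responses get nu=10 with lambda from
    :func:`calibrate_lambda`.
    """
    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}")
    alpha, beta, k = _PRESETS[preset]
    y = np.asarray(y, dtype=np.float64)
    S = np.full(p, 1.0 / p)
    if response_kind == CONTINUOUS:
        mu0 = float(np.mean(y))
        lam = calibrate_lambda(y, nu, q=q, target_mult=target_mult)
        return PriorConfig(alpha=alpha, beta=beta, k=k, K=K, S=S, mu0=mu0,
                           nu=nu, lambda_=lam, response_kind=CONTINUOUS)
    ybar = float(np.mean(y))
    ybar = min(max(ybar, 1e-12), 1 - 1e-12)
    mu0 = float(stats.norm.ppf(ybar))
    return PriorConfig(alpha=alpha, beta=beta, k=k, K=K, S=S, mu0=mu0,
                       response_kind=BINARY)


def child_seed(master: int, *keys: int) -> int:
    """Deterministic sub-seed below 2^31 from a master seed and integer keys."""
    ss = np.random.SeedSequence([int(master)] + [int(k) for k in keys])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def write_manifest(path, **resolved) -> None:
    """Dump the fully resolved run configuration (JSON) next to the outputs."""

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, frozenset):
            return sorted(o)
        return str(o)

    Path(path).write_text(json.dumps(resolved, indent=2, default=_default))
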