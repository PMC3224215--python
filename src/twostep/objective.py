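"""Regularized robust regression objective and its gradient.

The model is a linear scoring function ``f(x) = w.x + b`` whose objective is

    L(w, b) = (1 - l1 - l2) / N * sum_i mu_i g(f(x_i), m_i)
              + l1 * sum_j |w_j| + l2 * sum_j w_j^2

with per-sample weights ``mu_i`` (default 1) and the *soft* loss
``g(f, m) = log(1 + (f - m)^2)``, which grows only logarithmically with the
residual and therefore damps the influence of outliers; a squared loss is
available for comparison and for the closed-form ridge oracle.  The bias
``b`` is never penalized.

The penalties default to the Lasso/ridge power forms ``sum |w_j|^p``; the
literal p-norm ``(sum |w_j|^p)^(1/p)`` is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoders import FeatureMatrix
from .errors import InputError


@dataclass
class LinearModel:
    """Hyperplane ``f(x) = w.x + b``: normal vector and bias."""

    w: np.ndarray
    b: float

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float).ravel()
        self.b = float(self.b)
        if not (np.all(np.isfinite(self.w)) and np.isfinite(self.b)):
            raise InputError("linear model has non-finite parameters")


@dataclass
class ObjectiveConfig:
    """Regularization strengths, loss choice and sample weights."""

    lambda1: float = 0.0
    lambda2: float = 0.0
    sample_weights: np.ndarray | None = None
    loss: str = "soft"
    literal_norm: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.lambda1 < 1.0 and 0.0 <= self.lambda2 < 1.0):
            raise InputError("lambda1 and lambda2 must lie in [0, 1)")
        if self.lambda1 + self.lambda2 >= 1.0:
            raise InputError("lambda1 + lambda2 must be < 1")
        if self.loss not in ("soft", "squared"):
            raise InputError(f"unknown loss {self.loss!r}")
        if self.sample_weights is not None:
            self.sample_weights = np.asarray(self.sample_weights, dtype=float)
            if np.any(self.sample_weights <= 0):
                raise InputError("sample weights must be positive")

    def weights_for(self, n: int) -> np.ndarray:
        if self.sample_weights is None:
            return np.ones(n)
        if self.sample_weights.shape != (n,):
            raise InputError(
                f"{self.sample_weights.size} sample weights for {n} samples"
            )
        return self.sample_weights


def _as_array(x: FeatureMatrix | np.ndarray) -> np.ndarray:
    if isinstance(x, FeatureMatrix):
        return x.values
    return np.asarray(x, dtype=float)


def score(model: LinearModel, x: np.ndarray) -> float | np.ndarray:
    """Evaluate ``f(x) = w.x + b`` for a single vector or a matrix of rows."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != model.w.size:
        raise InputError(
            f"feature dimension {x.shape[-1]} does not match model "
            f"dimension {model.w.size}"
        )
    return x @ model.w + model.b


def soft_loss(f, m):
    """Robust log loss ``log(1 + (f - m)^2)`` (natural logarithm)."""
    r = np.asarray(f, dtype=float) - np.asarray(m, dtype=float)
    return np.log1p(r * r)


def squared_loss(f, m):
    """Plain squared error ``(f - m)^2``."""
    r = np.asarray(f, dtype=float) - np.asarray(m, dtype=float)
    return r * r


def loss_value(f, m, loss: str = "soft"):
    return soft_loss(f, m) if loss == "soft" else squared_loss(f, m)


def loss_gradient(f, m, loss: str = "soft"):
    """d g / d f: ``2r / (1 + r^2)`` for the soft loss, ``2r`` for squared."""
    r = np.asarray(f, dtype=float) - np.asarray(m, dtype=float)
    if loss == "soft":
        return 2.0 * r / (1.0 + r * r)
    return 2.0 * r


def penalty(w: np.ndarray, p: int, literal_norm: bool = False) -> float:
    """Regularization term for the weight vector (bias excluded).

    Default is the power form ``sum |w_j|^p`` (Lasso for p=1, ridge for
    p=2); ``literal_norm=True`` gives the p-norm ``(sum |w_j|^p)^(1/p)``.
    """
    if p not in (1, 2):
        raise InputError("penalty order p must be 1 or 2")
    w = np.asarray(w, dtype=float)
    total = float(np.sum(np.abs(w) ** p))
    if literal_norm:
        return total ** (1.0 / p)
    return total


def penalty_gradient(
    w: np.ndarray, p: int, literal_norm: bool = False
) -> np.ndarray:
    """(sub)gradient of :func:`penalty`; ``sign(0) = 0`` for the L1 term."""
    w = np.asarray(w, dtype=float)
    if p == 1:
        # identical for both forms: (sum|w|)^1
        return np.sign(w)
    if literal_norm:
        nrm = float(np.sqrt(np.sum(w * w)))
        if nrm == 0.0:
            return np.zeros_like(w)
        return w / nrm
    return 2.0 * w


def objective_value(
    model: LinearModel,
    X: FeatureMatrix | np.ndarray,
    targets: np.ndarray,
    cfg: ObjectiveConfig,
) -> float:
    """Full regularized objective at (w, b)."""
    x = _as_array(X)
    m = np.asarray(targets, dtype=float)
    if x.shape[0] != m.size:
        raise InputError(f"{x.shape[0]} rows but {m.size} targets")
    mu = cfg.weights_for(m.size)
    f = score(model, x)
    data = np.sum(mu * loss_value(f, m, cfg.loss))
    pref = (1.0 - cfg.lambda1 - cfg.lambda2) / m.size
    val = pref * data
    if cfg.lambda1 > 0:
        val += cfg.lambda1 * penalty(model.w, 1, cfg.literal_norm)
    if cfg.lambda2 > 0:
        val += cfg.lambda2 * penalty(model.w, 2, cfg.literal_norm)
    return float(val)


def objective_gradient(
    model: LinearModel,
    X: FeatureMatrix | np.ndarray,
    targets: np.ndarray,
    cfg: ObjectiveConfig,
) -> tuple[np.ndarray, float]:
    """(dL/dw, dL/db); the bias receives only the data-term gradient."""
    x = _as_array(X)
    m = np.asarray(targets, dtype=float)
    if x.shape[0] != m.size:
        raise InputError(f"{x.shape[0]} rows but {m.size} targets")
    mu = cfg.weights_for(m.size)
    f = score(model, x)
    c = mu * loss_gradient(f, m, cfg.loss)
    pref = (1.0 - cfg.lambda1 - cfg.lambda2) / m.size
    gw = pref * (c @ x)
    gb = pref * float(np.sum(c))
    if cfg.lambda1 > 0:
        gw = gw + cfg.lambda1 * penalty_gradient(model.w, 1, cfg.literal_norm)
    if cfg.lambda2 > 0:
        gw = gw + cfg.lambda2 * penalty_gradient(model.w, 2, cfg.literal_norm)
    return gw, gb
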