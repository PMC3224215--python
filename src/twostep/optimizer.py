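"""Rprop minimization of the regularized objective, plus an exact ridge solver.

Rprop (resilient propagation) adapts one step size per parameter from the
*sign* of successive partial derivatives only, which makes it insensitive
to the scale of the gradient and lets it cope with the discontinuous
derivative of the L1 penalty at zero: weights that the exact Lasso solution
would set to zero oscillate around zero with ever-shrinking steps and end
up orders of magnitude below any sensible selection threshold.  The variant
implemented is iRprop- (no weight backtracking): on a sign change the step
shrinks, the parameter is left in place for one iteration and its stored
derivative is zeroed.

For the squared loss with L2 penalty the minimizer is also available in
closed form via the normal equations and a Cholesky factorization
(:func:`ridge_closed_form`); it serves as the package's primary numerical
oracle for the iterative path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.linalg import cho_factor, cho_solve

from .encoders import FeatureMatrix
from .errors import InputError, NumericalError
from .objective import LinearModel, ObjectiveConfig, _as_array


@dataclass
class RpropConfig:
    """Rprop hyperparameters.

    ``delta_min`` sits one decade below the 1e-8 feature-selection
    threshold so near-zero weights can settle safely below the cut.
    """

    eta_plus: float = 1.2
    eta_minus: float = 0.5
    delta0: float = 0.1
    delta_min: float = 1e-9
    delta_max: float = 50.0
    max_iter: int = 2000
    tol: float = 1e-10

    def __post_init__(self) -> None:
        if not (self.eta_plus > 1.0 and 0.0 < self.eta_minus < 1.0):
            raise InputError("need eta_plus > 1 and eta_minus in (0, 1)")
        if not (0 < self.delta_min < self.delta0 < self.delta_max):
            raise InputError("need delta_min < delta0 < delta_max")
        if self.max_iter < 1:
            raise InputError("max_iter must be >= 1")


@dataclass
class FitResult:
    """Outcome of an Rprop run: best-seen iterate and bookkeeping."""

    model: LinearModel
    n_iterations: int
    final_objective: float
    converged: bool


@njit(cache=True)
def _rprop_core(
    X, y, mu, lam1, lam2, loss_sq,
    eta_p, eta_m, delta0, dmin, dmax, max_iter, tol, w, b,
):  # pragma: no cover - exercised through rprop_minimize
    n, d = X.shape
    pref = (1.0 - lam1 - lam2) / n
    gw_prev = np.zeros(d)
    gb_prev = 0.0
    dw = np.full(d, delta0)
    db = delta0
    best_obj = np.inf
    w_best = w.copy()
    b_best = b
    prev_obj = np.inf
    converged = False
    bad_iter = -1
    it = 0
    small_streak = 0
    c = np.empty(n)
    for it in range(1, max_iter + 1):
        f = np.dot(X, w) + b
        obj = 0.0
        for i in range(n):
            r = f[i] - y[i]
            if loss_sq:
                obj += mu[i] * r * r
                c[i] = mu[i] * 2.0 * r
            else:
                obj += mu[i] * np.log1p(r * r)
                c[i] = mu[i] * 2.0 * r / (1.0 + r * r)
        obj *= pref
        gw = pref * np.dot(c, X)
        gb = pref * np.sum(c)
        if lam1 > 0.0:
            for j in range(d):
                obj += lam1 * abs(w[j])
                if w[j] > 0.0:
                    gw[j] += lam1
                elif w[j] < 0.0:
                    gw[j] -= lam1
        if lam2 > 0.0:
            for j in range(d):
                obj += lam2 * w[j] * w[j]
                gw[j] += 2.0 * lam2 * w[j]
        if not np.isfinite(obj):
            bad_iter = it
            break
        if obj < best_obj:
            best_obj = obj
            w_best[:] = w
            b_best = b
        # iRprop- alternates skip and move phases, so a single tiny
        # objective change is not evidence of convergence; require two in
        # a row
        if abs(obj - prev_obj) < tol:
            small_streak += 1
            if small_streak >= 2:
                converged = True
                break
        else:
            small_streak = 0
        prev_obj = obj
        # iRprop- per-parameter update
        for j in range(d):
            s = gw_prev[j] * gw[j]
            if s > 0.0:
                step = dw[j] * eta_p
                if step > dmax:
                    step = dmax
                dw[j] = step
                if gw[j] > 0.0:
                    w[j] -= step
                elif gw[j] < 0.0:
                    w[j] += step
                gw_prev[j] = gw[j]
            elif s < 0.0:
                step = dw[j] * eta_m
                if step < dmin:
                    step = dmin
                dw[j] = step
                gw_prev[j] = 0.0
            else:
                if gw[j] > 0.0:
                    w[j] -= dw[j]
                elif gw[j] < 0.0:
                    w[j] += dw[j]
                gw_prev[j] = gw[j]
        s = gb_prev * gb
        if s > 0.0:
            db = db * eta_p
            if db > dmax:
                db = dmax
            if gb > 0.0:
                b -= db
            elif gb < 0.0:
                b += db
            gb_prev = gb
        elif s < 0.0:
            db = db * eta_m
            if db < dmin:
                db = dmin
            gb_prev = 0.0
        else:
            if gb > 0.0:
                b -= db
            elif gb < 0.0:
                b += db
            gb_prev = gb
        # all step sizes at the floor: nothing can move noticeably anymore
        max_delta = db
        for j in range(d):
            if dw[j] > max_delta:
                max_delta = dw[j]
        if max_delta <= dmin:
            converged = True
            break
    return w_best, b_best, best_obj, it, converged, bad_iter


def rprop_minimize(
    X: FeatureMatrix | np.ndarray,
    targets: np.ndarray,
    cfg: ObjectiveConfig,
    opt: RpropConfig | None = None,
    init: LinearModel | None = None,
) -> FitResult:
    """Minimize the regularized objective with iRprop-.

    Deterministic: a fixed initial model and fixed data give identical
    results.  Default initialization is ``w = 0`` and ``b`` equal to the
    mean target.  The best-objective iterate encountered is returned, which
    guards against terminal oscillation.
    """
    x = np.ascontiguousarray(_as_array(X))
    y = np.asarray(targets, dtype=float)
    if x.shape[0] != y.size:
        raise InputError(f"{x.shape[0]} rows but {y.size} targets")
    if cfg.literal_norm:
        raise InputError(
            "rprop_minimize supports only the power-form penalties"
        )
    opt = opt or RpropConfig()
    n, d = x.shape
    mu = cfg.weights_for(n)
    if init is None:
        w0 = np.zeros(d)
        b0 = float(y.mean())
    else:
        if init.w.size != d:
            raise InputError(
                f"initial model has {init.w.size} weights for {d} features"
            )
        w0 = init.w.copy()
        b0 = init.b
    w_best, b_best, best_obj, n_iter, converged, bad_iter = _rprop_core(
        x, y, mu, cfg.lambda1, cfg.lambda2, cfg.loss == "squared",
        opt.eta_plus, opt.eta_minus, opt.delta0, opt.delta_min,
        opt.delta_max, opt.max_iter, opt.tol, w0, b0,
    )
    if bad_iter >= 0:
        raise NumericalError(
            f"objective became non-finite at iteration {bad_iter}"
        )
    return FitResult(
        model=LinearModel(w=w_best, b=b_best),
        n_iterations=int(n_iter),
        final_objective=float(best_obj),
        converged=bool(converged),
    )


def ridge_closed_form(
    X: FeatureMatrix | np.ndarray,
    targets: np.ndarray,
    lambda2: float,
    prefactor_convention: bool = True,
    sample_weights: np.ndarray | None = None,
) -> LinearModel:
    """Exact minimizer for squared loss + L2 penalty via Cholesky.

    Solves the normal equations of
    ``c * sum_i mu_i (w.x_i + b - m_i)^2 + lambda2 * sum_j w_j^2`` with the
    bias unpenalized, where ``c = (1 - lambda2) / N`` under the default
    prefactor convention (set ``prefactor_convention=False`` for a plain
    unscaled residual sum of squares).
    """
    x = _as_array(X)
    y = np.asarray(targets, dtype=float)
    n, d = x.shape
    if n != y.size:
        raise InputError(f"{n} rows but {y.size} targets")
    if lambda2 < 0:
        raise InputError("lambda2 must be non-negative")
    mu = (
        np.ones(n)
        if sample_weights is None
        else np.asarray(sample_weights, dtype=float)
    )
    c = (1.0 - lambda2) / n if prefactor_convention else 1.0
    a = np.hstack([x, np.ones((n, 1))])
    am = a * mu[:, None]
    gram = c * (a.T @ am)
    gram[np.arange(d), np.arange(d)] += lambda2
    rhs = c * (am.T @ y)
    singular_msg = (
        "normal equations are singular; increase lambda2 above 0 "
        "(collinear features with no ridge penalty)"
    )
    try:
        factor = cho_factor(gram)
        # tiny Cholesky pivots signal (near-)collinearity even when the
        # system happens to be consistent
        pivots = np.diag(factor[0])
        if (pivots.min() / pivots.max()) ** 2 < 1e-12:
            raise NumericalError(singular_msg)
        theta = cho_solve(factor, rhs)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(singular_msg) from exc
    if not np.all(np.isfinite(theta)):
        raise NumericalError(singular_msg)
    return LinearModel(w=theta[:d], b=float(theta[d]))
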