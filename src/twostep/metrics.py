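"""Prediction-quality measures for external test sets.

``q_squared`` is the coefficient of determination about the *measured*
mean, ``1 - RSS/TSS``; it can be arbitrarily negative when predictions are
worse than predicting the mean, which happens in particular when the
training targets are not a representative sample of the test targets (a
train/test range mismatch).  The Spearman rank correlation stays
informative in that situation because it only compares orderings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InputError


def _pair(measured, predicted) -> tuple[np.ndarray, np.ndarray]:
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.shape != p.shape or m.ndim != 1:
        raise InputError("measured and predicted must be 1-d and equal-length")
    if m.size < 2:
        raise InputError("need at least 2 values")
    return m, p


def q_squared(measured, predicted) -> float:
    """Coefficient of determination ``1 - RSS / TSS`` about the measured mean."""
    m, p = _pair(measured, predicted)
    tss = float(np.sum((m - m.mean()) ** 2))
    if tss == 0.0:
        raise InputError("all measured values identical: q^2 undefined")
    rss = float(np.sum((m - p) ** 2))
    return 1.0 - rss / tss


def spearman_rcc(measured, predicted) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks)."""
    m, p = _pair(measured, predicted)
    if np.unique(m).size < 2 or np.unique(p).size < 2:
        raise InputError("zero rank variance: Spearman correlation undefined")
    rho = stats.spearmanr(m, p).statistic
    if not np.isfinite(rho):
        raise InputError("Spearman correlation undefined for these inputs")
    return float(rho)


@dataclass
class EvaluationReport:
    """q^2, Spearman rank correlation and sample count for one test set."""

    q2: float
    srcc: float
    n: int


def evaluate(measured, predicted) -> EvaluationReport:
    """Compute both quality measures on one measured/predicted pair."""
    m, p = _pair(measured, predicted)
    return EvaluationReport(
        q2=q_squared(m, p), srcc=spearman_rcc(m, p), n=m.size
    )
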