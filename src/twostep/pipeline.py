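"""The two-step training procedure.

Stage 1 fits a linear model with the robust soft loss under an L1 penalty,
whose strength ``lambda1`` is chosen by k-times-repeated n-fold cross
validation; weights with ``|w| < threshold`` (default 1e-8) are then
discarded, performing embedded feature selection.  Stage 2 refits only the
surviving features under a (usually milder) L2 penalty, with ``lambda2``
chosen by the same CV scheme on the reduced matrix.  Defaults follow the
protocol the method was developed with: k = 5 repeats of 10-fold CV,
``lambda1`` candidates {0.001, 0.005, 0.01, 0.05, 0.08, 0.1, 0.2, 0.3} and
``lambda2`` candidates {0.0001, 0.001, 0.01, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6,
0.7, 0.8, 0.9, 0.93}.

Normalization is refit inside every CV fold on the fold-training portion
(no information leakage); a ``global`` mode that normalizes once on the
full training set is available for comparison.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .encoders import (
    DescriptorTable,
    FeatureMatrix,
    Normalizer,
    PeptideDataset,
    apply_normalizer,
    build_feature_matrix,
    fit_normalizer,
)
from .errors import InputError, NumericalError
from .metrics import q_squared
from .objective import LinearModel, ObjectiveConfig, loss_value, score
from .optimizer import RpropConfig, rprop_minimize

#: Default candidate grid for the stage-1 (L1) regularization strength.
DEFAULT_LAMBDA1_GRID = (0.001, 0.005, 0.01, 0.05, 0.08, 0.1, 0.2, 0.3)
#: Default candidate grid for the stage-2 (L2) regularization strength.
DEFAULT_LAMBDA2_GRID = (
    0.0001, 0.001, 0.01, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.93
)
#: Absolute-weight threshold below which a stage-1 feature is dropped.
DEFAULT_THRESHOLD = 1e-8


@dataclass
class RunConfig:
    """Everything that determines a two-step fit besides the data."""

    lambda1_grid: tuple[float, ...] = DEFAULT_LAMBDA1_GRID
    lambda2_grid: tuple[float, ...] = DEFAULT_LAMBDA2_GRID
    k_repeats: int = 5
    n_folds: int = 10
    threshold: float = DEFAULT_THRESHOLD
    seed: int = 0
    loss: str = "soft"
    normalization: str = "per-fold"
    validation_metric: str = "soft_loss"
    rprop: RpropConfig = field(default_factory=RpropConfig)

    def __post_init__(self) -> None:
        if not self.lambda1_grid or not self.lambda2_grid:
            raise InputError("lambda grids must be nonempty")
        for lam in (*self.lambda1_grid, *self.lambda2_grid):
            if not 0.0 <= lam < 1.0:
                raise InputError(f"lambda {lam} outside [0, 1)")
        if self.threshold <= 0:
            raise InputError("threshold must be positive")
        if self.normalization not in ("per-fold", "global"):
            raise InputError(f"unknown normalization {self.normalization!r}")
        if self.validation_metric not in ("soft_loss", "q2"):
            raise InputError(
                f"unknown validation metric {self.validation_metric!r}"
            )


@dataclass
class CVResult:
    """Cross-validation curve for one lambda grid."""

    candidates: list[float]
    mean_validation_error: np.ndarray
    chosen_lambda: float
    per_fold_errors: np.ndarray  # shape (k, n, len(candidates))


@dataclass
class TwoStepModel:
    """A fitted two-step predictor.

    ``selected_indices`` index the *normalized* feature space (the columns
    kept by ``normalizer``); use :attr:`selected_original_indices` or
    :attr:`selected_feature_names` for the combined-encoding space.
    """

    normalizer: Normalizer
    stage1: LinearModel
    selected_indices: np.ndarray
    stage2: LinearModel
    lambda1: float
    lambda2: float
    threshold: float
    peptide_length: int
    feature_names: list[str]
    table: DescriptorTable
    config: RunConfig
    provenance: dict = field(default_factory=dict)
    cv_stage1: CVResult | None = None
    cv_stage2: CVResult | None = None

    @property
    def selected_original_indices(self) -> np.ndarray:
        """Selected columns expressed in the combined-encoding space."""
        return self.normalizer.kept_indices[self.selected_indices]

    @property
    def selected_feature_names(self) -> list[str]:
        return [self.feature_names[i] for i in self.selected_original_indices]


def dataset_hash(dataset: PeptideDataset) -> str:
    """Stable hash of a dataset for model provenance."""
    h = hashlib.sha256()
    for pid, seq in zip(dataset.ids, dataset.sequences):
        h.update(pid.encode())
        h.update(b"\t")
        h.update(seq.encode())
        h.update(b"\n")
    if dataset.targets is not None:
        h.update(np.asarray(dataset.targets, dtype=float).tobytes())
    return h.hexdigest()[:16]


def _spawn_seed(seed: int, index: int) -> int:
    child = np.random.SeedSequence(seed).spawn(index + 1)[index]
    return int(child.generate_state(1)[0] % (2**31))


def make_folds(
    n_samples: int, n_folds: int, k_repeats: int, seed: int
) -> np.ndarray:
    """Seeded repeated fold assignments.

    Returns an integer array of shape ``(k_repeats, n_samples)`` whose
    entry ``[r, i]`` is the validation-fold label (0-based) of sample ``i``
    in repeat ``r``; fold sizes differ by at most one.
    """
    if n_folds < 2:
        raise InputError("need at least 2 folds")
    if n_folds > n_samples:
        raise InputError(
            f"cannot split {n_samples} samples into {n_folds} folds"
        )
    if k_repeats < 1:
        raise InputError("need at least 1 repeat")
    rngs = [
        np.random.default_rng(s)
        for s in np.random.SeedSequence(seed).spawn(k_repeats)
    ]
    assignment = np.empty((k_repeats, n_samples), dtype=int)
    for r, rng in enumerate(rngs):
        perm = rng.permutation(n_samples)
        labels = np.empty(n_samples, dtype=int)
        for f, part in enumerate(np.array_split(perm, n_folds)):
            labels[part] = f
        assignment[r] = labels
    return assignment


def _validation_error(
    model: LinearModel,
    z_val: np.ndarray,
    y_val: np.ndarray,
    loss: str,
    metric: str,
) -> float:
    pred = score(model, z_val)
    if metric == "q2":
        return 1.0 - q_squared(y_val, pred)
    return float(np.mean(loss_value(pred, y_val, loss)))


def cross_validate_lambda(
    X: FeatureMatrix | np.ndarray,
    targets: np.ndarray,
    candidates,
    stage: int,
    k: int = 5,
    n: int = 10,
    seed: int = 0,
    loss: str = "soft",
    rprop: RpropConfig | None = None,
    normalization: str = "per-fold",
    validation_metric: str = "soft_loss",
) -> CVResult:
    """Choose a regularization strength by k-times-repeated n-fold CV.

    ``stage=1`` interprets the candidates as L1 strengths (L2 fixed at 0),
    ``stage=2`` as L2 strengths.  Each (repeat, fold, candidate) cell fits
    a normalizer and a model on the fold-training portion and scores the
    held-out part; the candidate with the smallest average error wins, with
    ties resolved toward the larger (more conservative) lambda.
    """
    if stage not in (1, 2):
        raise InputError("stage must be 1 or 2")
    candidates = [float(c) for c in candidates]
    if not candidates:
        raise InputError("candidate list must be nonempty")
    x = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, float)
    y = np.asarray(targets, dtype=float)
    folds = make_folds(x.shape[0], n, k, seed)
    errors = np.empty((k, n, len(candidates)))
    global_norm = fit_normalizer(x) if normalization == "global" else None
    for r in range(k):
        for f in range(n):
            val_mask = folds[r] == f
            tr_mask = ~val_mask
            if tr_mask.sum() < 2:
                raise InputError(
                    "fold-training portion has fewer than 2 samples"
                )
            norm = (
                global_norm
                if global_norm is not None
                else fit_normalizer(x[tr_mask])
            )
            z_tr = apply_normalizer(norm, x[tr_mask]).values
            z_val = apply_normalizer(norm, x[val_mask]).values
            for ci, lam in enumerate(candidates):
                cfg = ObjectiveConfig(
                    lambda1=lam if stage == 1 else 0.0,
                    lambda2=lam if stage == 2 else 0.0,
                    loss=loss,
                )
                fit = rprop_minimize(z_tr, y[tr_mask], cfg, rprop)
                errors[r, f, ci] = _validation_error(
                    fit.model, z_val, y[val_mask], loss, validation_metric
                )
    means = errors.mean(axis=(0, 1))
    best = means.min()
    chosen = max(c for c, m in zip(candidates, means) if m == best)
    return CVResult(
        candidates=candidates,
        mean_validation_error=means,
        chosen_lambda=chosen,
        per_fold_errors=errors,
    )


def train_stage1(
    X: FeatureMatrix | np.ndarray,
    targets: np.ndarray,
    lambda1: float,
    rprop: RpropConfig | None = None,
    loss: str = "soft",
) -> LinearModel:
    """L1-regularized fit on a normalized matrix (feature-selection stage)."""
    cfg = ObjectiveConfig(lambda1=lambda1, lambda2=0.0, loss=loss)
    return rprop_minimize(X, targets, cfg, rprop).model


def select_features(model: LinearModel, threshold: float) -> np.ndarray:
    """Indices of weights whose magnitude reaches the selection threshold."""
    if threshold <= 0:
        raise InputError("threshold must be positive")
    return np.flatnonzero(np.abs(model.w) >= threshold)


def train_stage2(
    X: FeatureMatrix | np.ndarray,
    targets: np.ndarray,
    selected: np.ndarray,
    lambda2: float,
    rprop: RpropConfig | None = None,
    loss: str = "soft",
) -> LinearModel:
    """L2-regularized refit restricted to the selected columns."""
    selected = np.asarray(selected, dtype=int)
    if selected.size == 0:
        raise InputError(
            "no features selected; lower lambda1 or the selection threshold"
        )
    x = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, float)
    cfg = ObjectiveConfig(lambda1=0.0, lambda2=lambda2, loss=loss)
    return rprop_minimize(x[:, selected], targets, cfg, rprop).model


def fit_two_step(
    dataset: PeptideDataset,
    table: DescriptorTable,
    config: RunConfig | None = None,
) -> TwoStepModel:
    """Run the full two-step procedure on a training dataset.

    Encodes the peptides, cross-validates ``lambda1``, fits stage 1 on the
    whole training set, thresholds the weights into a feature selection,
    cross-validates ``lambda2`` on the selected sub-matrix and refits
    stage 2 on the whole training set.
    """
    if dataset.targets is None:
        raise InputError("training dataset has no targets")
    config = config or RunConfig()
    x = build_feature_matrix(dataset, table)
    y = dataset.targets
    seed_cv1 = _spawn_seed(config.seed, 0)
    seed_cv2 = _spawn_seed(config.seed, 1)
    cv1 = cross_validate_lambda(
        x.values, y, config.lambda1_grid, stage=1,
        k=config.k_repeats, n=config.n_folds, seed=seed_cv1,
        loss=config.loss, rprop=config.rprop,
        normalization=config.normalization,
        validation_metric=config.validation_metric,
    )
    norm = fit_normalizer(x)
    z = apply_normalizer(norm, x).values
    stage1 = train_stage1(z, y, cv1.chosen_lambda, config.rprop, config.loss)
    selected = select_features(stage1, config.threshold)
    if selected.size == 0:
        raise NumericalError(
            "stage 1 removed every feature; lower lambda1 or the threshold"
        )
    x_sel = x.values[:, norm.kept_indices[selected]]
    cv2 = cross_validate_lambda(
        x_sel, y, config.lambda2_grid, stage=2,
        k=config.k_repeats, n=config.n_folds, seed=seed_cv2,
        loss=config.loss, rprop=config.rprop,
        normalization=config.normalization,
        validation_metric=config.validation_metric,
    )
    stage2 = train_stage2(
        z, y, selected, cv2.chosen_lambda, config.rprop, config.loss
    )
    return TwoStepModel(
        normalizer=norm,
        stage1=stage1,
        selected_indices=selected,
        stage2=stage2,
        lambda1=cv1.chosen_lambda,
        lambda2=cv2.chosen_lambda,
        threshold=config.threshold,
        peptide_length=dataset.length,
        feature_names=x.feature_names,
        table=table,
        config=config,
        provenance={
            "dataset_hash": dataset_hash(dataset),
            "seed": config.seed,
            "n_train": dataset.n,
            "n_features_initial": x.n_features,
            "n_features_kept": norm.n_kept,
            "n_features_selected": int(selected.size),
        },
        cv_stage1=cv1,
        cv_stage2=cv2,
    )


def predict(
    model: TwoStepModel,
    dataset: PeptideDataset,
    table: DescriptorTable | None = None,
    stage: int = 2,
) -> np.ndarray:
    """Predict pIC50 values for new peptides with a fitted model.

    ``stage=1`` scores with the dense stage-1 model (useful for comparing
    the two stages); the default uses the stage-2 model on the selected
    features.
    """
    if dataset.length != model.peptide_length:
        raise InputError(
            f"peptides of length {dataset.length} but the model was trained "
            f"on length {model.peptide_length}"
        )
    x = build_feature_matrix(dataset, table or model.table)
    z = apply_normalizer(model.normalizer, x).values
    if stage == 1:
        return np.asarray(score(model.stage1, z), dtype=float)
    if stage == 2:
        return np.asarray(
            score(model.stage2, z[:, model.selected_indices]), dtype=float
        )
    raise InputError("stage must be 1 or 2")
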