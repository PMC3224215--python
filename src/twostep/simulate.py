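"""Synthetic data emulating the small-n / large-d peptide QSAR regime.

The generators produce random fixed-length peptides, random (optionally
redundant) amino-acid descriptor tables and targets driven by a planted
sparse linear signal plus Gaussian noise: on the order of a hundred
peptides of length 8-9 described by thousands of partially redundant
features, of which only a handful carry signal.  Targets are generated in
the *normalized* feature space so planted effect sizes are comparable
across encoder blocks, and are offset into a pIC50-like range.

A train/test split whose test targets are shifted by a constant reproduces
the pathological situation where the training set is not a representative
sample of the prediction set: the coefficient of determination collapses
below zero while the rank correlation stays high.

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoders import (
    STANDARD_AA,
    DescriptorTable,
    PeptideDataset,
    apply_normalizer,
    build_feature_matrix,
    fit_normalizer,
)
from .errors import InputError


@dataclass
class PlantedGroundTruth:
    """The sparse linear signal behind a synthetic regression dataset.

    ``true_weights`` lives in the combined-encoding feature space (before
    zero-variance filtering); ``informative_indices`` is its support.
    Weights apply to *standardized* feature columns.
    """

    true_weights: np.ndarray
    true_bias: float
    noise_sd: float
    informative_indices: np.ndarray

    def __post_init__(self) -> None:
        self.true_weights = np.asarray(self.true_weights, dtype=float)
        self.informative_indices = np.asarray(
            self.informative_indices, dtype=int
        )
        support = np.flatnonzero(self.true_weights)
        if not np.array_equal(np.sort(self.informative_indices), support):
            raise InputError(
                "informative_indices must be the support of true_weights"
            )


def generate_peptides(n: int, length: int, seed: int) -> PeptideDataset:
    """``n`` random peptides drawn uniformly over the 20 standard letters."""
    if n < 1 or length < 1:
        raise InputError("need n >= 1 and length >= 1")
    rng = np.random.default_rng(seed)
    letters = np.array(list(STANDARD_AA))
    seqs = ["".join(rng.choice(letters, size=length)) for _ in range(n)]
    width = max(4, len(str(n)))
    ids = [f"pep{i + 1:0{width}d}" for i in range(n)]
    return PeptideDataset(ids=ids, sequences=seqs)


def generate_descriptor_table(
    n_properties: int, seed: int, redundancy: float = 0.0
) -> DescriptorTable:
    """A random descriptor table with an optional redundant fraction.

    Property values are standard-normal per amino acid.  A fraction
    ``redundancy`` of the properties are noisy linear copies of earlier
    independent properties (pairwise correlation around 0.995), emulating
    the strong redundancy of literature-derived physico-chemical
    collections where many scales measure near-identical quantities.
    """
    if n_properties < 1:
        raise InputError("need at least one property")
    if not 0.0 <= redundancy <= 1.0:
        raise InputError("redundancy must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_red = int(round(redundancy * n_properties))
    n_base = n_properties - n_red
    if n_red > 0 and n_base == 0:
        n_base, n_red = 1, n_properties - 1
    base = rng.standard_normal((20, n_base))
    cols = [base]
    if n_red > 0:
        src = rng.integers(0, n_base, size=n_red)
        copies = base[:, src] + 0.1 * rng.standard_normal((20, n_red))
        cols.append(copies)
    mat = np.hstack(cols)
    names = [f"prop{j + 1:03d}" for j in range(n_base)] + [
        f"prop{n_base + j + 1:03d}_dup{src[j] + 1:03d}" for j in range(n_red)
    ]
    values = {aa: mat[i] for i, aa in enumerate(STANDARD_AA)}
    return DescriptorTable(property_names=names, values=values)


def _plant_targets(
    dataset: PeptideDataset,
    table: DescriptorTable,
    support_size: int,
    effect_size: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, PlantedGroundTruth]:
    x = build_feature_matrix(dataset, table)
    if support_size < 1 or support_size > x.n_features:
        raise InputError(
            f"support_size {support_size} outside [1, {x.n_features}]"
        )
    norm = fit_normalizer(x)
    z = apply_normalizer(norm, x).values
    if support_size > norm.n_kept:
        raise InputError(
            f"support_size {support_size} exceeds the {norm.n_kept} "
            "informative (non-constant) columns"
        )
    support_kept = np.sort(
        rng.choice(norm.n_kept, size=support_size, replace=False)
    )
    signs = rng.choice([-1.0, 1.0], size=support_size)
    bias = float(rng.uniform(5.0, 8.0))
    signal = z[:, support_kept] @ (signs * effect_size) + bias
    targets = signal + rng.normal(0.0, noise_sd, size=dataset.n)
    w_true = np.zeros(x.n_features)
    support_combined = norm.kept_indices[support_kept]
    w_true[support_combined] = signs * effect_size
    truth = PlantedGroundTruth(
        true_weights=w_true,
        true_bias=bias,
        noise_sd=noise_sd,
        informative_indices=support_combined,
    )
    return targets, truth


def generate_regression_dataset(
    n: int,
    length: int,
    table: DescriptorTable,
    support_size: int,
    effect_size: float,
    noise_sd: float,
    seed: int,
) -> tuple[PeptideDataset, PlantedGroundTruth]:
    """Peptides with targets from a planted sparse linear signal."""
    if noise_sd < 0:
        raise InputError("noise_sd must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    peptides = generate_peptides(n, length, seed)
    targets, truth = _plant_targets(
        peptides, table, support_size, effect_size, noise_sd, rng
    )
    return (
        PeptideDataset(
            ids=peptides.ids, sequences=peptides.sequences, targets=targets
        ),
        truth,
    )


def generate_split_regression_dataset(
    n_train: int,
    n_test: int,
    length: int,
    table: DescriptorTable,
    support_size: int,
    effect_size: float,
    noise_sd: float,
    seed: int,
    test_shift: float = 0.0,
) -> tuple[PeptideDataset, PeptideDataset, PlantedGroundTruth]:
    """A train/test pair governed by one planted signal.

    ``test_shift`` adds a constant to the *test* targets only, producing
    the range-mismatch scenario in which the training set is not a
    representative sample of the prediction set (strongly negative q^2,
    high rank correlation).
    """
    full, truth = generate_regression_dataset(
        n_train + n_test, length, table, support_size, effect_size,
        noise_sd, seed,
    )
    train = PeptideDataset(
        ids=full.ids[:n_train],
        sequences=full.sequences[:n_train],
        targets=full.targets[:n_train],
    )
    test = PeptideDataset(
        ids=full.ids[n_train:],
        sequences=full.sequences[n_train:],
        targets=full.targets[n_train:] + test_shift,
    )
    return train, test, truth


def generate_shifted_split(
    n_train: int,
    n_test: int,
    length: int,
    table: DescriptorTable,
    support_size: int,
    effect_size: float,
    noise_sd: float,
    seed: int,
    shift: float = 3.0,
) -> tuple[PeptideDataset, PeptideDataset, PlantedGroundTruth]:
    """Named fixture for the train/test target-range mismatch scenario."""
    return generate_split_regression_dataset(
        n_train, n_test, length, table, support_size, effect_size,
        noise_sd, seed, test_shift=shift,
    )
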