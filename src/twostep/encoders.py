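"""Peptide feature encoders and training-set normalization.

Fixed-length peptides are mapped to numeric feature vectors by three
encoders which are concatenated per residue position:

* *physico-chemical*: each residue contributes the ``P`` property values of
  its amino acid from a descriptor table (``P * L`` features),
* *sparse*: a 24-component one-hot sub-vector per residue over the 20
  standard amino acids plus the placeholders ``* B X Z`` (``24 * L``),
* *BLOSUM62*: the residue's row of the 24x24 NCBI BLOSUM62 matrix
  (``24 * L``).

The combined matrix therefore has ``d = (P + 48) * L`` columns; for a
nine-residue peptide and a 643-property table this is 6219, for an
eight-residue peptide 5528.  Features are standardized to zero mean / unit
standard deviation using *training-set* statistics; constant columns carry
no information and are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .blosum62 import BLOSUM62_ORDER, BLOSUM62_ROWS
from .errors import EncodingError, InputError

#: Canonical alphabetical order of the 20 standard amino acids.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Placeholder letters legal in sparse/BLOSUM encoding: gap, Asn/Asp
#: ambiguity, unknown residue, Gln/Glu ambiguity.
PLACEHOLDERS = "*BXZ"
#: Component order of the 24-long one-hot sub-vectors.
SPARSE_ORDER = STANDARD_AA + PLACEHOLDERS

_SPARSE_INDEX = {aa: i for i, aa in enumerate(SPARSE_ORDER)}

#: Columns whose training standard deviation falls below this tolerance are
#: treated as constant and removed.
ZERO_VARIANCE_TOL = 1e-12


@dataclass
class PeptideDataset:
    """A set of equal-length peptides with optional pIC50 targets.

    pIC50 is the negative decadic log of the half-maximal inhibitory
    concentration, the binding-affinity scale used for peptide/MHC
    regression.
    """

    ids: list[str]
    sequences: list[str]
    targets: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise InputError("ids and sequences differ in length")
        if len(self.sequences) == 0:
            raise InputError("empty peptide dataset")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise InputError(f"duplicate peptide ids: {dupes[:5]}")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise InputError(f"sequences have mixed lengths {sorted(lengths)}")
        alphabet = set(SPARSE_ORDER)
        for pid, seq in zip(self.ids, self.sequences):
            bad = set(seq) - alphabet
            if bad:
                raise EncodingError(
                    f"peptide {pid!r}: illegal residue(s) {sorted(bad)}"
                )
        if self.targets is not None:
            self.targets = np.asarray(self.targets, dtype=float)
            if self.targets.shape != (len(self.sequences),):
                raise InputError(
                    f"{len(self.sequences)} sequences but "
                    f"{self.targets.size} targets"
                )

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])


@dataclass
class DescriptorTable:
    """Per-amino-acid physico-chemical property values.

    One row per standard amino acid, ``P`` named properties per row — the
    shape of the literature-derived 643-property tables used for peptide
    QSAR.  Placeholder letters have no descriptor values.
    """

    property_names: list[str]
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if len(self.property_names) < 1:
            raise InputError("descriptor table needs at least one property")
        missing = [aa for aa in STANDARD_AA if aa not in self.values]
        if missing:
            raise InputError(f"descriptor table missing amino acid(s) {missing}")
        p = len(self.property_names)
        for aa in STANDARD_AA:
            vec = np.asarray(self.values[aa], dtype=float)
            if vec.shape != (p,):
                raise InputError(
                    f"descriptor row {aa!r} has {vec.size} values, expected {p}"
                )
            if not np.all(np.isfinite(vec)):
                raise InputError(f"descriptor row {aa!r} has non-finite values")
            self.values[aa] = vec

    @property
    def n_properties(self) -> int:
        return len(self.property_names)


@dataclass
class FeatureMatrix:
    """An ``n x d`` feature matrix with per-column provenance names.

    Column names record block, residue position (0-based) and component,
    e.g. ``physchem_pos3_hydropathy`` or ``blosum_pos0_R``.
    """

    values: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InputError("feature matrix must be 2-dimensional")
        if len(self.feature_names) != self.values.shape[1]:
            raise InputError(
                f"{len(self.feature_names)} feature names for "
                f"{self.values.shape[1]} columns"
            )
        if not np.all(np.isfinite(self.values)):
            raise InputError("feature matrix contains non-finite entries")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class Normalizer:
    """Training-set feature standardization parameters.

    ``kept_indices`` are the columns that survived zero-variance filtering;
    ``means``/``sds`` are their training statistics (population standard
    deviation, denominator ``n``).
    """

    kept_indices: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.kept_indices = np.asarray(self.kept_indices, dtype=int)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        k = self.kept_indices.size
        if self.means.shape != (k,) or self.sds.shape != (k,):
            raise InputError("normalizer means/sds do not match kept_indices")
        if np.any(self.sds <= 0):
            raise InputError("normalizer standard deviations must be positive")

    @property
    def n_kept(self) -> int:
        return self.kept_indices.size


def _check_sequence(sequence: str, allowed: set[str]) -> None:
    for pos, ch in enumerate(sequence):
        if ch not in allowed:
            raise EncodingError(
                f"cannot encode residue {ch!r} at position {pos}"
            )


def sparse_encode(sequence: str) -> np.ndarray:
    """One-hot encode a peptide: 24 components per residue.

    Component order is ``ACDEFGHIKLMNPQRSTVWY`` followed by ``* B X Z``.
    """
    _check_sequence(sequence, set(SPARSE_ORDER))
    out = np.zeros(24 * len(sequence))
    for j, ch in enumerate(sequence):
        out[24 * j + _SPARSE_INDEX[ch]] = 1.0
    return out


def blosum_encode(sequence: str) -> np.ndarray:
    """Encode a peptide by BLOSUM62 rows: 24 components per residue.

    Residue ``r`` at position ``j`` contributes the BLOSUM62 row of ``r``
    (NCBI column order ``ARNDCQEGHILKMFPSTWYVBZX*``) at offsets
    ``24*j .. 24*j+23``.
    """
    _check_sequence(sequence, set(SPARSE_ORDER))
    out = np.empty(24 * len(sequence))
    for j, ch in enumerate(sequence):
        out[24 * j : 24 * j + 24] = BLOSUM62_ROWS[ch]
    return out


def physchem_encode(sequence: str, table: DescriptorTable) -> np.ndarray:
    """Encode a peptide by per-residue physico-chemical properties.

    Residue at position ``j`` contributes the ``P`` table values of its
    letter at offsets ``P*j .. P*j+P-1``.  Placeholder letters have no
    descriptors and are rejected.
    """
    p = table.n_properties
    out = np.empty(p * len(sequence))
    for j, ch in enumerate(sequence):
        if ch not in table.values:
            raise EncodingError(
                f"residue {ch!r} at position {j} is not in the descriptor table"
            )
        out[p * j : p * (j + 1)] = table.values[ch]
    return out


def combined_feature_names(length: int, table: DescriptorTable) -> list[str]:
    """Column names of the combined [physchem | sparse | BLOSUM] encoding."""
    names: list[str] = []
    for j in range(length):
        for prop in table.property_names:
            names.append(f"physchem_pos{j}_{prop}")
    for j in range(length):
        for sym in SPARSE_ORDER:
            names.append(f"sparse_pos{j}_{sym}")
    for j in range(length):
        for sym in BLOSUM62_ORDER:
            names.append(f"blosum_pos{j}_{sym}")
    return names


def build_feature_matrix(
    dataset: PeptideDataset, table: DescriptorTable
) -> FeatureMatrix:
    """Combined encoding of a dataset: ``d = (P + 48) * L`` columns.

    Blocks are concatenated in the fixed order
    ``[physico-chemical | sparse | BLOSUM]``, so e.g. 9-mers with a
    643-property table give ``5787 + 216 + 216 = 6219`` features.
    """
    rows = [
        np.concatenate(
            [
                physchem_encode(seq, table),
                sparse_encode(seq),
                blosum_encode(seq),
            ]
        )
        for seq in dataset.sequences
    ]
    return FeatureMatrix(
        values=np.vstack(rows),
        feature_names=combined_feature_names(dataset.length, table),
    )


def fit_normalizer(train: FeatureMatrix | np.ndarray) -> Normalizer:
    """Learn standardization parameters from a training matrix.

    Columns with (population) standard deviation below
    :data:`ZERO_VARIANCE_TOL` are dropped; the rest record their training
    mean and standard deviation.
    """
    names: list[str] = []
    if isinstance(train, FeatureMatrix):
        names = train.feature_names
        x = train.values
    else:
        x = np.asarray(train, dtype=float)
    if x.shape[0] < 2:
        raise InputError("need at least 2 samples to fit a normalizer")
    means = x.mean(axis=0)
    sds = x.std(axis=0)  # population convention, ddof=0
    kept = np.flatnonzero(sds >= ZERO_VARIANCE_TOL)
    return Normalizer(
        kept_indices=kept,
        means=means[kept],
        sds=sds[kept],
        feature_names=[names[i] for i in kept] if names else [],
    )


def apply_normalizer(
    norm: Normalizer, data: FeatureMatrix | np.ndarray
) -> FeatureMatrix:
    """Standardize a matrix with stored training statistics.

    Keeps exactly the training-selected columns and applies
    ``(x - mean) / sd`` per column; test columns are *not* re-filtered.
    """
    if isinstance(data, FeatureMatrix):
        x = data.values
        names = data.feature_names
    else:
        x = np.asarray(data, dtype=float)
        names = [f"f{i}" for i in range(x.shape[1])]
    if norm.kept_indices.size and x.shape[1] <= norm.kept_indices.max():
        raise InputError(
            f"matrix has {x.shape[1]} columns but normalizer expects at "
            f"least {norm.kept_indices.max() + 1}"
        )
    z = (x[:, norm.kept_indices] - norm.means) / norm.sds
    return FeatureMatrix(
        values=z, feature_names=[names[i] for i in norm.kept_indices]
    )
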