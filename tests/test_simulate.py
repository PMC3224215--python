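"""Synthetic-data generators: determinism, shapes, planted signal."""

import numpy as np
import pytest

from twostep import (
    InputError,
    apply_normalizer,
    build_feature_matrix,
    fit_normalizer,
    generate_descriptor_table,
    generate_peptides,
    generate_regression_dataset,
    generate_shifted_split,
    q_squared,
    spearman_rcc,
)
from twostep.encoders import STANDARD_AA


class TestGeneratePeptides:
    def test_task_one_shape(self):
        ds = generate_peptides(89, 9, seed=0)
        assert ds.n == 89
        assert all(len(s) == 9 for s in ds.sequences)

    def test_seed_reproducibility(self):
        a = generate_peptides(10, 8, seed=5)
        b = generate_peptides(10, 8, seed=5)
        assert a.sequences == b.sequences and a.ids == b.ids
        c = generate_peptides(10, 8, seed=6)
        assert a.sequences != c.sequences

    def test_alphabet_is_standard(self):
        ds = generate_peptides(50, 9, seed=1)
        assert set("".join(ds.sequences)) <= set(STANDARD_AA)


class TestGenerateDescriptorTable:
    def test_643_properties_give_6219_combined_features(self):
        table = generate_descriptor_table(643, seed=0)
        ds = generate_peptides(3, 9, seed=0)
        assert build_feature_matrix(ds, table).n_features == 6219

    def test_no_redundancy_no_duplicate_columns(self):
        table = generate_descriptor_table(20, seed=0, redundancy=0.0)
        mat = np.array([table.values[aa] for aa in STANDARD_AA])
        corr = np.corrcoef(mat.T)
        off = corr[~np.eye(20, dtype=bool)]
        assert np.max(np.abs(off)) < 0.95

    def test_redundant_columns_strongly_correlated(self):
        table = generate_descriptor_table(40, seed=3, redundancy=0.5)
        mat = np.array([table.values[aa] for aa in STANDARD_AA])
        # duplicated properties are named prop<i>_dup<source>
        n_dup = 0
        for j, name in enumerate(table.property_names):
            if "_dup" in name:
                src = int(name.split("_dup")[1]) - 1
                r = np.corrcoef(mat[:, j], mat[:, src])[0, 1]
                assert abs(r) >= 0.95
                n_dup += 1
        assert n_dup == 20

    def test_pure_function_of_seed(self):
        a = generate_descriptor_table(10, seed=9, redundancy=0.3)
        b = generate_descriptor_table(10, seed=9, redundancy=0.3)
        for aa in STANDARD_AA:
            assert np.array_equal(a.values[aa], b.values[aa])


class TestGenerateRegressionDataset:
    def test_dimension_law_holds(self, small_table):
        ds, _ = generate_regression_dataset(
            20, 6, small_table, 3, 1.0, 0.1, seed=0
        )
        fm = build_feature_matrix(ds, small_table)
        assert fm.n_features == (small_table.n_properties + 48) * 6

    def test_truth_support_matches_weights(self, small_table):
        _, truth = generate_regression_dataset(
            30, 5, small_table, 4, 1.0, 0.1, seed=1
        )
        assert np.array_equal(
            np.flatnonzero(truth.true_weights), truth.informative_indices
        )
        assert truth.informative_indices.size == 4

    def test_noiseless_targets_exactly_linear(self, small_table):
        """With zero noise, refitting on the true support by least squares
        recovers the targets exactly."""
        ds, truth = generate_regression_dataset(
            40, 5, small_table, 3, 1.0, 0.0, seed=2
        )
        fm = build_feature_matrix(ds, small_table)
        norm = fit_normalizer(fm)
        z = apply_normalizer(norm, fm).values
        kept_pos = {c: i for i, c in enumerate(norm.kept_indices)}
        cols = [kept_pos[c] for c in truth.informative_indices]
        a = np.hstack([z[:, cols], np.ones((ds.n, 1))])
        coef, *_ = np.linalg.lstsq(a, ds.targets, rcond=None)
        np.testing.assert_allclose(a @ coef, ds.targets, atol=1e-8)

    def test_support_size_validation(self, small_table):
        with pytest.raises(InputError):
            generate_regression_dataset(
                10, 2, small_table, 10_000, 1.0, 0.1, seed=0
            )

    def test_seeded_determinism(self, small_table):
        a, ta = generate_regression_dataset(
            15, 4, small_table, 2, 1.0, 0.2, seed=11
        )
        b, tb = generate_regression_dataset(
            15, 4, small_table, 2, 1.0, 0.2, seed=11
        )
        assert a.sequences == b.sequences
        np.testing.assert_array_equal(a.targets, b.targets)
        np.testing.assert_array_equal(ta.true_weights, tb.true_weights)


class TestShiftedSplit:
    def test_shift_applies_to_test_targets_only(self, small_table):
        train, test, _ = generate_shifted_split(
            30, 20, 5, small_table, 3, 1.0, 0.05, seed=4, shift=3.0
        )
        train0, test0, _ = generate_shifted_split(
            30, 20, 5, small_table, 3, 1.0, 0.05, seed=4, shift=0.0
        )
        np.testing.assert_array_equal(train.targets, train0.targets)
        np.testing.assert_allclose(test.targets, test0.targets + 3.0)

    def test_shift_breaks_q2_not_rank_correlation(self, small_table):
        """An oracle predictor trained without the shift shows the
        range-mismatch signature: q^2 collapses, rank correlation holds."""
        train, test, truth = generate_shifted_split(
            40, 30, 5, small_table, 3, 1.0, 0.05, seed=5, shift=3.0
        )
        preds = test.targets - 3.0  # a perfect un-shifted predictor
        assert q_squared(test.targets, preds) < 0
        assert spearman_rcc(test.targets, preds) > 0.99


def test_recovery_degrades_with_noise(small_table):
    """Support-recovery quality is non-increasing in the noise level."""
    from twostep import ObjectiveConfig, rprop_minimize

    ranks = []
    for noise in (0.05, 0.5, 2.0):
        ds, truth = generate_regression_dataset(
            50, 5, small_table, 3, 1.0, noise, seed=8
        )
        fm = build_feature_matrix(ds, small_table)
        norm = fit_normalizer(fm)
        z = apply_normalizer(norm, fm).values
        fit = rprop_minimize(
            z, ds.targets, ObjectiveConfig(lambda1=0.05)
        )
        kept_pos = {c: i for i, c in enumerate(norm.kept_indices)}
        cols = [kept_pos[c] for c in truth.informative_indices]
        w = np.abs(fit.model.w)
        # fraction of planted features ranking inside the top-|support|
        top = set(np.argsort(w)[-len(cols):].tolist())
        ranks.append(len(top & set(cols)) / len(cols))
    assert ranks[0] >= ranks[-1]
    assert ranks[0] == 1.0
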