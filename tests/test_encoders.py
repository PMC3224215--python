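"""Encoders: one-hot, BLOSUM62 and physico-chemical blocks, normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twostep import (
    EncodingError,
    FeatureMatrix,
    InputError,
    PeptideDataset,
    apply_normalizer,
    blosum_encode,
    build_feature_matrix,
    fit_normalizer,
    physchem_encode,
    sparse_encode,
)
from twostep.blosum62 import BLOSUM62_MATRIX, BLOSUM62_ORDER
from twostep.encoders import SPARSE_ORDER, STANDARD_AA

peptides = st.text(alphabet=STANDARD_AA, min_size=1, max_size=12)


class TestSparseEncode:
    def test_nine_mer_has_216_components(self):
        assert sparse_encode("ACDEFGHIK").size == 216

    def test_single_alanine_one_hot(self):
        v = sparse_encode("A")
        assert v.size == 24
        assert v[0] == 1.0
        assert np.sum(v) == 1.0

    @settings(derandomize=True, max_examples=50)
    @given(peptides)
    def test_each_residue_subvector_sums_to_one(self, seq):
        v = sparse_encode(seq)
        sums = v.reshape(len(seq), 24).sum(axis=1)
        assert np.all(sums == 1.0)

    @settings(derandomize=True, max_examples=50)
    @given(peptides)
    def test_exactly_length_nonzeros_all_one(self, seq):
        v = sparse_encode(seq)
        nz = v[v != 0]
        assert nz.size == len(seq) and np.all(nz == 1.0)

    def test_placeholder_letters_are_legal(self):
        v = sparse_encode("*BXZ")
        assert np.flatnonzero(v).tolist() == [20, 24 + 21, 48 + 22, 72 + 23]

    def test_unknown_character_names_position(self):
        with pytest.raises(EncodingError, match="position 2"):
            sparse_encode("ACJ")


class TestBlosumEncode:
    def test_eight_mer_has_192_components(self):
        assert blosum_encode("ACDEFGHI").size == 192

    def test_alanine_diagonal_is_four(self):
        v = blosum_encode("A")
        assert v[BLOSUM62_ORDER.index("A")] == 4.0

    def test_matches_biopython_blosum62(self):
        """The embedded matrix must agree with the NCBI BLOSUM62 shipped
        with biopython (independent oracle)."""
        from Bio.Align import substitution_matrices

        ref = substitution_matrices.load("BLOSUM62")
        for i, a in enumerate(BLOSUM62_ORDER):
            for j, b in enumerate(BLOSUM62_ORDER):
                assert BLOSUM62_MATRIX[i, j] == ref[a][b]

    def test_deterministic(self):
        assert np.array_equal(blosum_encode("WYVAC"), blosum_encode("WYVAC"))

    def test_unknown_character_rejected(self):
        with pytest.raises(EncodingError):
            blosum_encode("AO")


class TestPhyschemEncode:
    def test_643_properties_nine_mer_gives_5787(self, table_643):
        assert physchem_encode("ACDEFGHIK", table_643).size == 5787

    def test_643_properties_eight_mer_gives_5144(self, table_643):
        assert physchem_encode("ACDEFGHI", table_643).size == 5144

    def test_length_is_p_times_l(self, small_table):
        assert physchem_encode("WYV", small_table).size == 15

    def test_repeated_letter_repeats_block(self, small_table):
        v = physchem_encode("AAA", small_table).reshape(3, 5)
        assert np.array_equal(v[0], v[1]) and np.array_equal(v[1], v[2])

    def test_placeholder_rejected_with_position(self, small_table):
        with pytest.raises(EncodingError, match="position 1"):
            physchem_encode("AXC", small_table)


class TestBuildFeatureMatrix:
    @pytest.mark.parametrize(
        "length,expected", [(9, 6219), (8, 5528), (2, 643 * 2 + 96)]
    )
    def test_combined_dimension_law(self, table_643, length, expected):
        ds = PeptideDataset(
            ids=["a", "b"],
            sequences=["ACDEFGHIK"[:length], "WYVACDEFG"[:length]],
        )
        fm = build_feature_matrix(ds, table_643)
        assert fm.values.shape == (2, expected)
        assert len(fm.feature_names) == expected

    def test_block_order_physchem_sparse_blosum(self, small_table):
        ds = PeptideDataset(ids=["a"], sequences=["AC"])
        fm = build_feature_matrix(ds, small_table)
        assert fm.feature_names[0].startswith("physchem_pos0")
        assert fm.feature_names[10].startswith("sparse_pos0")
        assert fm.feature_names[10 + 48].startswith("blosum_pos0")
        np.testing.assert_array_equal(
            fm.values[0, :10], physchem_encode("AC", small_table)
        )
        np.testing.assert_array_equal(
            fm.values[0, 10:58], sparse_encode("AC")
        )
        np.testing.assert_array_equal(
            fm.values[0, 58:], blosum_encode("AC")
        )


class TestNormalizer:
    def test_hand_computed_example(self):
        fm = FeatureMatrix(
            values=np.array([[0.0, 1.0], [0.0, 2.0], [0.0, 3.0]]),
            feature_names=["c0", "c1"],
        )
        norm = fit_normalizer(fm)
        assert norm.kept_indices.tolist() == [1]
        assert norm.means[0] == pytest.approx(2.0)
        assert norm.sds[0] == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_constant_column_dropped(self):
        x = np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 4.0]])
        assert fit_normalizer(x).kept_indices.tolist() == [1]

    def test_no_constant_columns_keeps_all(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((10, 4))
        assert fit_normalizer(x).kept_indices.tolist() == [0, 1, 2, 3]

    def test_single_sample_rejected(self):
        with pytest.raises(InputError):
            fit_normalizer(np.array([[1.0, 2.0]]))

    def test_apply_to_fitting_matrix_standardizes(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((20, 6)) * 3 + 5
        norm = fit_normalizer(x)
        z = apply_normalizer(norm, x).values
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=0), 1.0, atol=1e-9)

    def test_normalization_idempotent(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((15, 5))
        z = apply_normalizer(fit_normalizer(x), x).values
        norm2 = fit_normalizer(z)
        assert norm2.kept_indices.size == 5
        np.testing.assert_allclose(norm2.means, 0.0, atol=1e-9)
        np.testing.assert_allclose(norm2.sds, 1.0, atol=1e-9)

    def test_train_parameters_govern_test_columns(self):
        x = np.array([[0.0, 1.0], [0.0, 3.0], [0.0, 5.0]])
        norm = fit_normalizer(x)
        test = np.array([[9.0, 7.0], [9.0, 7.0]])
        z = apply_normalizer(norm, test).values
        # constant test column is mapped, not re-dropped
        assert z.shape == (2, 1)
        np.testing.assert_allclose(z[:, 0], (7.0 - 3.0) / norm.sds[0])

    def test_dimension_mismatch_rejected(self):
        norm = fit_normalizer(np.random.default_rng(0).random((5, 4)))
        with pytest.raises(InputError):
            apply_normalizer(norm, np.zeros((2, 2)))


class TestDatasetValidation:
    def test_mixed_lengths_rejected(self):
        with pytest.raises(InputError, match="length"):
            PeptideDataset(ids=["a", "b"], sequences=["ACD", "AC"])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(InputError, match="duplicate"):
            PeptideDataset(ids=["a", "a"], sequences=["AC", "CD"])

    def test_target_count_must_match(self):
        with pytest.raises(InputError):
            PeptideDataset(
                ids=["a", "b"], sequences=["AC", "CD"], targets=[1.0]
            )
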