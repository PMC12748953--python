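"""Domain types, CSV round trips, and the titration normalization identities."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import array_shapes, arrays

from cisimc.core import (
    BarcodingMatrix,
    CompositeMatrix,
    Dictionary,
    ExpressionMatrix,
    FormatError,
    ModuleActivity,
    NormalizationSpec,
    ValidationError,
    l2_normalize_proteins,
    load_matrix,
    save_matrix,
    weighted_normalize,
)


class TestTypeInvariants:
    def test_expression_rejects_negative_and_nonfinite(self):
        with pytest.raises(ValidationError, match="negative"):
            ExpressionMatrix([[1.0, -0.1]], ["p0"], ["c0", "c1"])
        with pytest.raises(ValidationError, match="NaN|Inf"):
            ExpressionMatrix([[1.0, np.nan]], ["p0"], ["c0", "c1"])

    def test_identifier_rules(self):
        with pytest.raises(ValidationError, match="unique"):
            ExpressionMatrix([[1.0, 2.0]], ["p0"], ["c", "c"])
        with pytest.raises(ValidationError, match="empty"):
            ExpressionMatrix([[1.0, 2.0]], [""], ["c0", "c1"])
        with pytest.raises(ValidationError, match="expected 2"):
            ExpressionMatrix([[1.0, 2.0]], ["p0"], ["c0"])

    def test_dictionary_requires_unit_norm_modules(self):
        with pytest.raises(ValidationError, match="unit-norm"):
            Dictionary([[0.5], [0.5]], ["p0", "p1"], ["m0"])
        ok = Dictionary([[0.6], [0.8]], ["p0", "p1"], ["m0"])
        assert ok.n_modules == 1
        # all-zero module columns are tolerated (pruned upstream)
        Dictionary([[0.6, 0.0], [0.8, 0.0]], ["p0", "p1"], ["m0", "m1"])

    def test_barcoding_channel_count_limits(self):
        # three channels for one protein violates the labeling constraint
        values = np.array([[1.0, 1], [1, 0], [1, 0]])
        with pytest.raises(ValidationError, match="3 channels, max is 2"):
            BarcodingMatrix(values, ["ch0", "ch1", "ch2"], ["FoxP3", "CD3"])

    def test_barcoding_rejects_duplicate_barcodes_and_empty_rows(self):
        dup = np.array([[1.0, 1], [1, 1]])
        with pytest.raises(ValidationError, match="share the same barcode"):
            BarcodingMatrix(dup, ["ch0", "ch1"], ["a", "b"])
        # toggle allows duplicates
        BarcodingMatrix(dup, ["ch0", "ch1"], ["a", "b"], require_unique_barcodes=False)
        empty_row = np.array([[1.0, 1], [0, 0], [0, 1]])
        with pytest.raises(ValidationError, match="labels no protein"):
            BarcodingMatrix(empty_row, ["ch0", "ch1", "ch2"], ["a", "b"])

    def test_barcoding_single_channel_budget(self):
        # 3 single-channel proteins with a budget of 2
        values = np.eye(3)
        with pytest.raises(ValidationError, match="single channel"):
            BarcodingMatrix(
                values, [f"ch{i}" for i in range(3)], list("abc"),
                max_single_channel_proteins=2,
            )

    def test_barcoding_validation_is_exact_for_tiny_designs(self):
        """Exhaustive p=3, m=2: accepted iff all stated rules hold."""
        m, p = 2, 3
        for flat in itertools.product([0.0, 1.0], repeat=m * p):
            A = np.array(flat).reshape(m, p)
            col = A.sum(axis=0)
            expected_ok = (
                ((col >= 1) & (col <= 2)).all()
                and (col == 1).sum() <= 4
                and (A.sum(axis=1) >= 1).all()
                and len({tuple(A[:, j]) for j in range(p)}) == p
            )
            try:
                BarcodingMatrix(A, ["ch0", "ch1"], list("abc"))
                ok = True
            except ValidationError:
                ok = False
            assert ok == expected_ok, f"disagreement for {A.tolist()}"

    def test_normalization_spec_bounds(self):
        with pytest.raises(ValidationError):
            NormalizationSpec(-0.1)
        with pytest.raises(ValidationError):
            NormalizationSpec(1.5)


class TestTableIO:
    @pytest.mark.parametrize(
        "role,matrix",
        [
            ("expression", ExpressionMatrix([[1.0, 2], [3, 4]], ["p0", "p1"], ["c0", "c1"])),
            ("dictionary", Dictionary([[0.6, 1.0], [0.8, 0.0]], ["p0", "p1"], ["m0", "m1"])),
            ("activity", ModuleActivity([[0.1, 0], [2.5, 3]], ["m0", "m1"], ["c0", "c1"])),
            ("barcoding", BarcodingMatrix([[1.0, 0], [1, 1]], ["ch0", "ch1"], ["a", "b"])),
            ("composite", CompositeMatrix([[0.0, 5.125]], ["ch0"], ["c0", "c1"])),
        ],
    )
    def test_round_trip_preserves_values_and_ids(self, tmp_path, role, matrix):
        path = tmp_path / f"{role}.csv"
        save_matrix(matrix, path)
        back = load_matrix(path, role)
        assert type(back) is type(matrix)
        np.testing.assert_allclose(back.values, matrix.values, rtol=0, atol=1e-12)

    def test_round_trip_full_precision(self, tmp_path):
        values = np.random.default_rng(0).gamma(1.0, 1.0, size=(5, 7))
        X = ExpressionMatrix(values, [f"p{i}" for i in range(5)], [f"c{i}" for i in range(7)])
        save_matrix(X, tmp_path / "x.csv")
        back = load_matrix(tmp_path / "x.csv", "expression")
        np.testing.assert_allclose(back.values, values, rtol=0, atol=1e-12)
        assert back.protein_ids == X.protein_ids
        assert back.cell_ids == X.cell_ids

    def test_load_validates_role_invariants(self, tmp_path):
        path = tmp_path / "bad_barcode.csv"
        path.write_text("id,a,b\nch0,1,1\nch1,1,1\nch2,1,0\n")
        with pytest.raises(ValidationError, match="3 channels"):
            load_matrix(path, "barcoding")

    def test_parse_failure_names_problem(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,c0,c1\np0,1.0,oops\np1,2,3\n")
        with pytest.raises(FormatError, match="line 2|non-numeric"):
            load_matrix(path, "expression")

    def test_role_header_mismatch_is_rejected(self, tmp_path):
        path = tmp_path / "x.csv"
        save_matrix(ExpressionMatrix([[1.0]], ["p0"], ["c0"]), path)
        with pytest.raises(ValidationError, match="role"):
            load_matrix(path, "composite")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FormatError, match="nope.csv"):
            load_matrix(tmp_path / "nope.csv", "expression")


class TestNormalization:
    def test_three_four_five_row(self):
        X = ExpressionMatrix([[3.0, 4.0]], ["p0"], ["c0", "c1"])
        out = l2_normalize_proteins(X)
        np.testing.assert_allclose(out.values, [[0.6, 0.8]], atol=1e-15)

    def test_zero_row_unchanged_with_warning(self):
        X = ExpressionMatrix([[0.0, 0.0], [3.0, 4.0]], ["p0", "p1"], ["c0", "c1"])
        with pytest.warns(UserWarning, match="p0"):
            out = l2_normalize_proteins(X)
        np.testing.assert_array_equal(out.values[0], [0.0, 0.0])
        np.testing.assert_allclose(out.values[1], [0.6, 0.8])

    def test_weight_limits(self, small_expression):
        X = small_expression
        out0 = weighted_normalize(X, NormalizationSpec(0.0))
        np.testing.assert_array_equal(out0.values, X.values)
        out1 = weighted_normalize(X, NormalizationSpec(1.0))
        np.testing.assert_allclose(
            out1.values, l2_normalize_proteins(X).values, atol=1e-15
        )

    def test_half_weight_hand_value(self):
        X = ExpressionMatrix([[3.0, 4.0]], ["p0"], ["c0", "c1"])
        out = weighted_normalize(X, NormalizationSpec(0.5))
        np.testing.assert_allclose(out.values, [[1.8, 2.4]], atol=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        values=arrays(
            np.float64,
            array_shapes(min_dims=2, max_dims=2, min_side=1, max_side=6),
            elements=st.floats(0, 100, allow_nan=False),
        ),
        wt=st.floats(0, 1),
    )
    def test_linearity_in_weight(self, values, wt):
        """output(wt) == wt*output(1) + (1-wt)*output(0) to 1e-12."""
        p, n = values.shape
        X = ExpressionMatrix(values, [f"p{i}" for i in range(p)], [f"c{i}" for i in range(n)])
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = weighted_normalize(X, NormalizationSpec(wt)).values
            lim0 = weighted_normalize(X, NormalizationSpec(0.0)).values
            lim1 = weighted_normalize(X, NormalizationSpec(1.0)).values
        np.testing.assert_allclose(out, wt * lim1 + (1 - wt) * lim0, atol=1e-12)

    def test_unit_norms_on_random_matrix(self, rng):
        values = rng.gamma(2.0, 3.0, size=(8, 30))
        out = l2_normalize_proteins(
            ExpressionMatrix(values, [f"p{i}" for i in range(8)], [f"c{i}" for i in range(30)])
        )
        np.testing.assert_allclose(np.linalg.norm(out.values, axis=1), 1.0, atol=1e-12)
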