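"""Correlation metrics and the dictionary-selection harnesses."""

import warnings

import numpy as np
import pytest

from cisimc.core import CompositeMatrix, ExpressionMatrix, ValidationError
from cisimc.evaluate import (
    channel_agreement,
    correlation_report,
    export_aligned_tables,
    leave_one_group_out,
    sweep_dictionary_params,
)
from cisimc.smaf import SmafConfig


def em(values, prefix_p="p", prefix_c="c"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        [f"{prefix_p}{i}" for i in range(values.shape[0])],
        [f"{prefix_c}{i}" for i in range(values.shape[1])],
    )


class TestCorrelationReport:
    def test_identical_matrices_all_ones(self, rng):
        X = em(rng.gamma(2.0, 1.0, size=(5, 12)))
        report = correlation_report(X, X)
        assert report.mean_protein_r == pytest.approx(1.0)
        assert report.min_protein_r == pytest.approx(1.0)
        assert report.mean_cell_r == pytest.approx(1.0)

    def test_affine_invariance_per_protein(self, rng):
        X = em(rng.gamma(2.0, 1.0, size=(4, 15)))
        hat = ExpressionMatrix(2.0 * X.values + 3.0, X.protein_ids, X.cell_ids)
        report = correlation_report(X, hat)
        assert report.min_protein_r == pytest.approx(1.0)

    def test_matches_textbook_covariance_formula(self, rng):
        Xv = rng.gamma(2.0, 1.0, size=(6, 20))
        Hv = rng.gamma(2.0, 1.0, size=(6, 20))
        report = correlation_report(em(Xv), em(Hv))
        for i, pid in enumerate([f"p{i}" for i in range(6)]):
            x, h = Xv[i], Hv[i]
            num = ((x - x.mean()) * (h - h.mean())).mean()
            den = x.std() * h.std()
            assert report.per_protein_r[pid] == pytest.approx(num / den, abs=1e-12)

    def test_symmetry_and_cell_permutation_invariance(self, rng):
        Xv = rng.gamma(2.0, 1.0, size=(4, 10))
        Hv = rng.gamma(2.0, 1.0, size=(4, 10))
        r1 = correlation_report(em(Xv), em(Hv))
        r2 = correlation_report(em(Hv), em(Xv))
        assert r1.mean_protein_r == pytest.approx(r2.mean_protein_r, abs=1e-12)
        perm = rng.permutation(10)
        X = em(Xv)
        Xp = ExpressionMatrix(Xv[:, perm], X.protein_ids, [X.cell_ids[i] for i in perm])
        Hp = ExpressionMatrix(Hv[:, perm], X.protein_ids, [X.cell_ids[i] for i in perm])
        r3 = correlation_report(Xp, Hp)
        assert r3.mean_protein_r == pytest.approx(r1.mean_protein_r, abs=1e-12)

    def test_alignment_by_ids(self, rng):
        Xv = rng.gamma(2.0, 1.0, size=(3, 8))
        X = em(Xv)
        # same data, shuffled rows and columns, same ids
        rperm = [2, 0, 1]
        cperm = list(reversed(range(8)))
        hat = ExpressionMatrix(
            Xv[np.ix_(rperm, cperm)],
            [X.protein_ids[i] for i in rperm],
            [X.cell_ids[i] for i in cperm],
        )
        report = correlation_report(X, hat)
        assert report.min_protein_r == pytest.approx(1.0)

    def test_zero_variance_protein_flagged_as_zero(self):
        X = em([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])
        report = correlation_report(X, X)
        assert report.per_protein_r["p1"] == 0.0
        assert any("p1" in f for f in report.flags)
        assert report.mean_protein_r >= report.min_protein_r

    def test_mean_at_least_min_always(self, rng):
        for _ in range(5):
            a = em(rng.gamma(1.0, 1.0, size=(5, 9)))
            b = em(rng.gamma(1.0, 1.0, size=(5, 9)))
            report = correlation_report(a, b)
            assert report.mean_protein_r >= report.min_protein_r

    def test_id_mismatch_errors(self, rng):
        X = em(rng.gamma(1.0, 1.0, size=(3, 4)))
        other = ExpressionMatrix(X.values, ["a", "b", "c"], X.cell_ids)
        with pytest.raises(ValidationError, match="protein ids"):
            correlation_report(X, other)


class TestChannelAgreement:
    def test_identical_composites(self, rng):
        Yv = rng.gamma(2.0, 1.0, size=(4, 10))
        Y = CompositeMatrix(Yv, [f"ch{i}" for i in range(4)], [f"c{i}" for i in range(10)])
        r = channel_agreement(Y, Y)
        assert all(v == pytest.approx(1.0) for v in r.values())

    def test_constant_channel_flagged(self):
        Y1 = CompositeMatrix([[1.0, 1.0], [1.0, 2.0]], ["ch0", "ch1"], ["c0", "c1"])
        Y2 = CompositeMatrix([[1.0, 3.0], [1.0, 2.0]], ["ch0", "ch1"], ["c0", "c1"])
        with pytest.warns(UserWarning, match="ch0"):
            r = channel_agreement(Y1, Y2)
        assert r["ch0"] == 0.0
        assert r["ch1"] == pytest.approx(1.0)

    def test_matches_formula_oracle(self, rng):
        Av = rng.gamma(2.0, 1.0, size=(3, 12))
        Bv = rng.gamma(2.0, 1.0, size=(3, 12))
        ids = ["ch0", "ch1", "ch2"]
        cids = [f"c{i}" for i in range(12)]
        r = channel_agreement(CompositeMatrix(Av, ids, cids), CompositeMatrix(Bv, ids, cids))
        for i, cid in enumerate(ids):
            expected = np.corrcoef(Av[i], Bv[i])[0, 1]
            assert r[cid] == pytest.approx(expected, abs=1e-12)


def _modular_expression(seed=0, n=160, p=6, n_tissues=2):
    """Small module-structured data with tissue labels for the harnesses."""
    from cisimc.synthetic import GeneratorConfig, generate_dataset

    config = GeneratorConfig(
        p=p, d_true=3, n_cells=n, n_tissues=n_tissues, noise_cv=0.05,
        module_size_range=(1, 3), seed=seed,
    )
    X, W, U, labels = generate_dataset(config)
    return X, labels


class TestHarnesses:
    def test_sweep_reduction_counts(self):
        X, _ = _modular_expression()
        grid = [SmafConfig(d0=4, iterations=3, seed=0)]
        table = sweep_dictionary_params(X, grid, n_random_A=2, m=4, seed=0)
        assert len(table) == 2
        assert {"mean_protein_r", "min_protein_r"} <= set(table.columns)

    def test_sweep_seeded_reproducible(self):
        X, _ = _modular_expression(seed=1)
        grid = [SmafConfig(d0=4, iterations=3, seed=0)]
        t1 = sweep_dictionary_params(X, grid, n_random_A=2, m=4, seed=5)
        t2 = sweep_dictionary_params(X, grid, n_random_A=2, m=4, seed=5)
        np.testing.assert_array_equal(
            t1["min_protein_r"].values, t2["min_protein_r"].values
        )

    def test_sweep_empty_grid_errors(self):
        X, _ = _modular_expression()
        with pytest.raises(ValidationError, match="nonempty"):
            sweep_dictionary_params(X, [], n_random_A=1)

    def test_leave_one_group_out_identical_groups_agree(self):
        """Two copies of the same cells as 'tissues' score alike."""
        X, _ = _modular_expression(seed=3, n=80, n_tissues=1)
        values = np.concatenate([X.values, X.values], axis=1)
        cells = [f"c{i}" for i in range(values.shape[1])]
        X2 = ExpressionMatrix(values, X.protein_ids, cells)
        groups = ["g0"] * X.n_cells + ["g1"] * X.n_cells
        table = leave_one_group_out(
            X2, groups, SmafConfig(d0=4, iterations=3, seed=0),
            n_random_A=3, m=4, seed=2,
        )
        means = table.groupby("group")["mean_protein_r"].mean()
        assert abs(means["g0"] - means["g1"]) < 0.1

    def test_leave_one_group_out_shared_modules_transfer(self):
        """Tissues drawing from one dictionary: held-out scores near pooled."""
        X, labels = _modular_expression(seed=4, n=180, n_tissues=3)
        table = leave_one_group_out(
            X, labels, SmafConfig(d0=5, iterations=4, seed=0),
            n_random_A=4, m=4, seed=0,
        )
        assert table["mean_protein_r"].mean() > 0.5

    def test_single_group_errors(self):
        X, _ = _modular_expression(seed=5, n=40, n_tissues=1)
        with pytest.raises(ValidationError, match="2 groups"):
            leave_one_group_out(X, ["g"] * X.n_cells, n_random_A=1)


class TestExport:
    def test_tables_written_aligned(self, tmp_path, rng):
        from cisimc.core import load_matrix

        Xv = rng.gamma(2.0, 1.0, size=(3, 5))
        X = em(Xv)
        hat = ExpressionMatrix(
            Xv[:, ::-1], X.protein_ids, list(reversed(X.cell_ids))
        )
        export_aligned_tables(X, hat, tmp_path / "t.csv", tmp_path / "h.csv")
        t = load_matrix(tmp_path / "t.csv", "expression")
        h = load_matrix(tmp_path / "h.csv", "expression")
        assert t.cell_ids == h.cell_ids
        np.testing.assert_allclose(t.values, h.values, atol=1e-12)
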