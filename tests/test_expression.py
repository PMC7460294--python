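"""Expression I/O, the out-of-range discriminant, and booleanization."""

import numpy as np
import pytest

from genegames import (
    MES,
    ExpressionMatrix,
    apply_discriminant,
    booleanize,
    load_expression_matrix,
)
from genegames.datasets import five_gene_mes


def write_tsv(path, text):
    path.write_text(text)
    return path


class TestLoadExpressionMatrix:
    def test_preserves_file_order_and_values(self, tmp_path):
        p = write_tsv(
            tmp_path / "m.tsv",
            "\ts1\ts2\ts3\ts4\n"
            "1\t0.4\t0.2\t0.3\t0.6\n"
            "2\t-12\t10\t4\t5\n"
            "3\t4.8\t3.5\t5.5\t6.3\n"
            "4\t12\t14\t17\t19\n"
            "5\t3.1\t4.6\t7.2\t5.6\n",
        )
        m = load_expression_matrix(p)
        assert m.gene_ids == ("1", "2", "3", "4", "5")
        assert m.sample_ids == ("s1", "s2", "s3", "s4")
        assert np.allclose(m.values[0], (0.4, 0.2, 0.3, 0.6))

    def test_minimal_one_by_one(self, tmp_path):
        m = load_expression_matrix(write_tsv(tmp_path / "m.tsv", "\ta\ng\t0\n"))
        assert m.shape == (1, 1) and m.values[0, 0] == 0.0

    def test_non_numeric_cell_names_location(self, tmp_path):
        p = write_tsv(tmp_path / "m.tsv", "\ta\tb\ng1\t1.0\tNA\n")
        with pytest.raises(ValueError, match=r"'NA'.*'g1'.*'b'"):
            load_expression_matrix(p)

    def test_duplicate_gene_id_rejected(self, tmp_path):
        p = write_tsv(tmp_path / "m.tsv", "\ta\ng1\t1\ng1\t2\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_expression_matrix(p)

    def test_empty_cell_rejected(self, tmp_path):
        p = write_tsv(tmp_path / "m.tsv", "\ta\tb\ng1\t1.0\t\n")
        with pytest.raises(ValueError):
            load_expression_matrix(p)

    def test_csv_dialect_and_transpose(self, tmp_path):
        p = write_tsv(tmp_path / "m.csv", ",g1,g2\ns1,1,2\ns2,3,4\n")
        m = load_expression_matrix(p, delimiter=",", transpose=True)
        assert m.gene_ids == ("g1", "g2")
        assert np.allclose(m.values, [[1, 3], [2, 4]])


class TestApplyDiscriminant:
    def test_five_gene_rows(self, mes5, disc5):
        # range over ALL reference samples; kept entries verbatim
        expected = np.array(
            [
                [0.9, 0.0, 0.1],
                [0.0, 13.0, 18.0],
                [2.7, 1.9, 0.0],
                [10.0, 20.0, 0.0],
                [2.1, 0.0, 1.9],
            ]
        )
        assert np.array_equal(disc5.values, expected)

    def test_nonzero_entries_equal_disease_bit_for_bit(self, mes5, disc5):
        keep = disc5.values != 0
        assert np.array_equal(disc5.values[keep], mes5.disease.values[keep])

    def test_disease_column_inside_range_zeroed(self):
        ref = ExpressionMatrix(("a", "b"), ("r1", "r2"), [[1.0, 3.0], [5.0, 9.0]])
        dis = ExpressionMatrix(("a", "b"), ("d1",), [[2.0], [7.0]])
        d = apply_discriminant(MES(ref, dis))
        assert np.array_equal(d.values, [[0.0], [0.0]])

    def test_reference_sample_order_irrelevant(self, mes5, disc5):
        shuffled = ExpressionMatrix(
            mes5.genes,
            tuple(reversed(mes5.reference.sample_ids)),
            mes5.reference.values[:, ::-1],
        )
        d2 = apply_discriminant(MES(shuffled, mes5.disease))
        assert np.array_equal(d2.values, disc5.values)

    def test_out_of_range_value_kept_even_when_typo_variant_used(self, mes5):
        # swap the last disease entry for 1.6: still outside [3.1, 7.2],
        # so it is retained verbatim, never rounded or replaced
        values = mes5.disease.values.copy()
        values[4, 2] = 1.6
        dis = ExpressionMatrix(mes5.genes, mes5.disease.sample_ids, values)
        d = apply_discriminant(MES(mes5.reference, dis))
        assert d.values[4, 2] == 1.6


class TestBooleanize:
    def test_five_gene_column_supports(self, disc5):
        b = booleanize(disc5)
        assert b.column_supports() == [
            frozenset({"1", "3", "4", "5"}),
            frozenset({"2", "3", "4"}),
            frozenset({"1", "2", "5"}),
        ]

    def test_idempotent_and_binary(self, disc5):
        b = booleanize(disc5)
        assert set(np.unique(b.values)) <= {0, 1}
        assert np.array_equal((b.values != 0).astype(int), b.values)

    @pytest.mark.parametrize(
        "values,n_ones",
        [(np.zeros((3, 2)), 0), (np.eye(3)[:, :2], 2)],
        ids=["all-zero", "single-entries"],
    )
    def test_counts(self, values, n_ones):
        from genegames.expression import DiscriminantMatrix

        d = DiscriminantMatrix(("a", "b", "c"), ("x", "y"), values)
        assert booleanize(d).values.sum() == n_ones


class TestValidation:
    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            ExpressionMatrix(("a",), ("s",), [[np.nan]])

    def test_gene_order_mismatch_rejected(self):
        ref = ExpressionMatrix(("a", "b"), ("r",), [[1.0], [2.0]])
        dis = ExpressionMatrix(("b", "a"), ("d",), [[1.0], [2.0]])
        with pytest.raises(ValueError, match="same gene ids"):
            MES(ref, dis)

    def test_mes_exposes_counts(self, mes5):
        assert (mes5.n_reference, mes5.n_disease) == (4, 3)
        assert five_gene_mes().genes == ("1", "2", "3", "4", "5")
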