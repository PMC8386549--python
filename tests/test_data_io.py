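import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from icipipe.data_io import (
    ExpressionMatrix,
    ParseError,
    fpkm_to_tpm,
    log2_transform,
    merge_cohorts,
    read_clinical,
    read_expression,
    read_gmt,
    read_maf,
    write_clinical,
    write_expression,
    write_gmt,
    write_maf,
)


def _expr(values, unit="FPKM", samples=None):
    df = pd.DataFrame(values)
    if samples is not None:
        df.columns = samples
    df.index = [f"g{i}" for i in range(len(df))]
    return ExpressionMatrix(df.astype(float), unit)


class TestExpressionMatrix:
    def test_rejects_duplicate_ids(self):
        df = pd.DataFrame([[1.0, 2.0]], index=["g1"], columns=["s1", "s1"])
        with pytest.raises(ValueError, match="duplicate sample"):
            ExpressionMatrix(df, "TPM")
        df2 = pd.DataFrame([[1.0], [2.0]], index=["g1", "g1"], columns=["s1"])
        with pytest.raises(ValueError, match="duplicate gene"):
            ExpressionMatrix(df2, "TPM")

    def test_rejects_negative_linear_values(self):
        with pytest.raises(ValueError, match="negative"):
            _expr({"s1": [1.0, -2.0]}, unit="TPM")

    def test_rejects_unknown_unit(self):
        with pytest.raises(ValueError, match="unit"):
            _expr({"s1": [1.0]}, unit="RPKM")


class TestFpkmToTpm:
    def test_column_normalized_to_million(self, toy_expression):
        tpm = fpkm_to_tpm(toy_expression)
        assert tpm.unit == "TPM"
        np.testing.assert_allclose(tpm.values["s1"], [250000, 250000, 500000])
        np.testing.assert_allclose(tpm.values.sum(axis=0), [1e6, 1e6], rtol=1e-9)

    def test_equal_values_split_evenly(self):
        tpm = fpkm_to_tpm(_expr({"s1": [3.0] * 4}))
        np.testing.assert_allclose(tpm.values["s1"], [2.5e5] * 4)

    def test_zero_column_raises_with_sample_name(self):
        with pytest.raises(ValueError, match="s1"):
            fpkm_to_tpm(_expr({"s1": [0.0, 0.0]}))

    def test_idempotent_up_to_scale(self, toy_expression):
        once = fpkm_to_tpm(toy_expression)
        again = ExpressionMatrix(once.values, "FPKM")
        np.testing.assert_allclose(fpkm_to_tpm(again).values, once.values)

    def test_requires_fpkm_unit(self, toy_expression):
        with pytest.raises(ValueError, match="FPKM"):
            fpkm_to_tpm(fpkm_to_tpm(toy_expression))


class TestLog2Transform:
    def test_closed_form_values(self):
        tpm = _expr({"s1": [0.0, 1.0, 1e6]}, unit="TPM")
        log = log2_transform(tpm)
        assert log.unit == "LOG2"
        np.testing.assert_allclose(log.values["s1"], [0.0, 1.0, np.log2(1e6 + 1)])

    def test_refuses_double_transform(self):
        tpm = _expr({"s1": [1.0]}, unit="TPM")
        with pytest.raises(ValueError, match="already"):
            log2_transform(log2_transform(tpm))


class TestMergeCohorts:
    def test_union_of_samples_same_gene_order(self):
        a = _expr(np.ones((4, 3)), unit="TPM", samples=["a1", "a2", "a3"])
        b = _expr(np.ones((4, 2)), unit="TPM", samples=["b1", "b2"])
        merged = merge_cohorts(a, b)
        assert list(merged.sample_ids) == ["a1", "a2", "a3", "b1", "b2"]
        assert list(merged.gene_ids) == list(a.gene_ids)
        assert set(merged.sample_cohort.unique()) == {"cohort_a", "cohort_b"}

    def test_gene_intersection(self):
        rng = np.random.default_rng(0)
        a = ExpressionMatrix(
            pd.DataFrame(rng.random((120, 2)), index=[f"g{i}" for i in range(120)], columns=["a1", "a2"]),
            "TPM",
        )
        b = ExpressionMatrix(
            pd.DataFrame(rng.random((100, 2)), index=[f"g{i}" for i in range(20, 120)], columns=["b1", "b2"]),
            "TPM",
        )
        merged = merge_cohorts(a, b)
        assert merged.shape[0] == 100
        # gene content symmetric in the argument order
        assert set(merged.gene_ids) == set(merge_cohorts(b, a).gene_ids)

    def test_errors(self):
        a = _expr(np.ones((3, 1)), unit="TPM", samples=["s1"])
        b_disjoint = ExpressionMatrix(
            pd.DataFrame(np.ones((3, 1)), index=["x1", "x2", "x3"], columns=["s2"]), "TPM"
        )
        with pytest.raises(ValueError, match="intersection"):
            merge_cohorts(a, b_disjoint)
        b_dup = _expr(np.ones((3, 1)), unit="TPM", samples=["s1"])
        with pytest.raises(ValueError, match="duplicate sample"):
            merge_cohorts(a, b_dup)
        b_log = _expr(np.ones((3, 1)), unit="LOG2", samples=["s2"])
        with pytest.raises(ValueError, match="unit mismatch"):
            merge_cohorts(a, b_log)


class TestFileRoundTrips:
    def test_expression_round_trip(self, tmp_path, rng):
        values = pd.DataFrame(
            rng.random((10, 5)), index=[f"g{i}" for i in range(10)], columns=[f"s{j}" for j in range(5)]
        )
        expr = ExpressionMatrix(values, "TPM")
        path = tmp_path / "expr.tsv"
        write_expression(expr, path)
        back = read_expression(path, unit="TPM")
        pd.testing.assert_frame_equal(back.values, expr.values, check_names=False)

    def test_non_numeric_cell_named_in_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene_id\ts1\ts2\ng1\t1.0\tNA\n")
        with pytest.raises(ParseError, match="g1.*s2"):
            read_expression(path)

    def test_gmt_round_trip_and_format(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("SETA\tdesc\tG1\tG2\nSETB\tdesc\tG3\n")
        sets = read_gmt(path)
        assert sets == {"SETA": {"G1", "G2"}, "SETB": {"G3"}}
        out = tmp_path / "out.gmt"
        write_gmt(sets, out)
        assert read_gmt(out) == sets

    def test_gmt_short_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("SETA\tdesc\n")
        with pytest.raises(ParseError, match=":1"):
            read_gmt(path)

    def test_clinical_round_trip_and_validation(self, tmp_path):
        clin = pd.DataFrame(
            {"sample_id": ["s1", "s2"], "os_time": [100.0, 200.0], "os_event": [1, 0], "age": [60, 70]}
        )
        path = tmp_path / "clin.tsv"
        write_clinical(clin, path)
        pd.testing.assert_frame_equal(read_clinical(path), clin)
        bad = clin.assign(os_event=[1, 2])
        write_clinical(bad, path)
        with pytest.raises(ParseError, match="os_event"):
            read_clinical(path)

    def test_maf_round_trip(self, tmp_path):
        muts = pd.DataFrame(
            {
                "Tumor_Sample_Barcode": ["s1", "s1", "s2"],
                "Hugo_Symbol": ["TP53", "KRAS", "TP53"],
                "Variant_Classification": ["Missense_Mutation", "Silent", "Nonsense_Mutation"],
            }
        )
        path = tmp_path / "muts.maf.tsv"
        write_maf(muts, path)
        pd.testing.assert_frame_equal(read_maf(path), muts)
        with pytest.raises(ParseError, match="missing MAF columns"):
            bad = tmp_path / "bad.tsv"
            bad.write_text("Tumor_Sample_Barcode\tHugo_Symbol\ns1\tTP53\n")
            read_maf(bad)


@settings(max_examples=25, deadline=None)
@given(
    hst.lists(
        hst.lists(hst.floats(min_value=0.01, max_value=1e4), min_size=3, max_size=3),
        min_size=2,
        max_size=6,
    )
)
def test_tpm_columns_always_sum_to_a_million(columns):
    values = pd.DataFrame(
        np.array(columns).T, index=["g0", "g1", "g2"], columns=[f"s{j}" for j in range(len(columns))]
    )
    tpm = fpkm_to_tpm(ExpressionMatrix(values, "FPKM"))
    np.testing.assert_allclose(tpm.values.sum(axis=0), 1e6, rtol=1e-6)
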