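import numpy as np
import pandas as pd
import pytest

from icipipe.data_io import ExpressionMatrix
from icipipe.signature import (
    assign_gene_types,
    boruta_select,
    compute_signature_scores,
    ici_score,
    pca_signature_score,
    split_by_cutpoint,
)


def _expr(matrix, genes=None, samples=None) -> ExpressionMatrix:
    df = pd.DataFrame(
        matrix,
        index=genes or [f"g{i}" for i in range(len(matrix))],
        columns=samples or [f"s{j}" for j in range(matrix.shape[1])],
    )
    return ExpressionMatrix(df, "LOG2")


@pytest.fixture
def binary_clusters():
    samples = [f"s{j}" for j in range(20)]
    return pd.Series(["A"] * 10 + ["B"] * 10, index=samples)


class TestAssignGeneTypes:
    def test_sign_determinism(self, binary_clusters, rng):
        X = rng.normal(5, 1, size=(3, 20))
        X[0, :10] += 4.0  # strictly higher in every cluster-A sample
        X[1] = -X[0] + 20.0  # negated pattern
        res = assign_gene_types(_expr(X), ["g0", "g1"], binary_clusters)
        assert res.loc["g0", "type"] == "I"
        assert res.loc["g0", "correlation"] > 0
        assert res.loc["g1", "type"] == "II"

    def test_null_genes_split_evenly(self, binary_clusters, rng):
        X = rng.normal(size=(500, 20))
        res = assign_gene_types(_expr(X), [f"g{i}" for i in range(500)], binary_clusters)
        frac_type1 = (res["type"] == "I").mean()
        assert 0.4 < frac_type1 < 0.6

    def test_constant_gene_falls_to_type_two_with_warning(self, binary_clusters):
        X = np.vstack([np.full(20, 3.0), np.random.default_rng(0).normal(size=20)])
        with pytest.warns(UserWarning, match="constant"):
            res = assign_gene_types(_expr(X), ["g0"], binary_clusters)
        assert res.loc["g0", "type"] == "II"

    def test_requires_binary_ab_clusters(self, rng):
        X = rng.normal(size=(2, 6))
        labels = pd.Series(["A", "B", "C", "A", "B", "C"], index=[f"s{j}" for j in range(6)])
        with pytest.raises(ValueError, match="binary"):
            assign_gene_types(_expr(X), ["g0"], labels)


class TestBorutaSelect:
    def test_informative_features_confirmed_noise_rejected(self, rng):
        n = 120
        y = rng.integers(0, 2, n)
        X = rng.normal(size=(n, 30))
        X[:, :5] += y[:, None] * 2.0  # 5 informative features, effect 2 sd
        frame = pd.DataFrame(X, columns=[f"f{i}" for i in range(30)])
        res = boruta_select(frame, y, n_trees=100, max_iter=40, seed=3)
        confirmed = set(res.confirmed)
        assert len(confirmed & {f"f{i}" for i in range(5)}) >= 4
        assert len(confirmed - {f"f{i}" for i in range(5)}) <= 2

    def test_decisions_partition_features(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 10)), columns=[f"f{i}" for i in range(10)])
        y = rng.integers(0, 2, 60)
        res = boruta_select(X, y, n_trees=50, max_iter=15, seed=4)
        assert set(res.decisions.unique()) <= {"confirmed", "rejected", "tentative"}
        assert len(res.decisions) == 10
        assert res.n_iterations <= 15

    def test_deterministic_under_seed(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 8)))
        y = rng.integers(0, 2, 50)
        a = boruta_select(X, y, n_trees=50, max_iter=10, seed=5)
        b = boruta_select(X, y, n_trees=50, max_iter=10, seed=5)
        pd.testing.assert_series_equal(a.decisions, b.decisions)

    def test_degenerate_target_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 3)))
        with pytest.raises(ValueError, match="classes"):
            boruta_select(X, np.zeros(20), seed=1)


class TestPcaSignatureScore:
    def test_single_gene_equals_z_scores(self, rng):
        X = rng.normal(3, 2, size=(5, 30))
        expr = _expr(X)
        score = pca_signature_score(expr, ["g2"])
        z = (X[2] - X[2].mean()) / X[2].std(ddof=0)
        np.testing.assert_allclose(score.to_numpy(), z, atol=1e-10)

    def test_two_perfectly_correlated_genes(self, rng):
        base = rng.normal(size=40)
        X = np.vstack([base * 2 + 5, base * 7 - 1])
        score = pca_signature_score(_expr(X), ["g0", "g1"])
        z = (base - base.mean()) / base.std(ddof=0)
        # PC1 of two identical z-profiles is sqrt(2) * common profile
        np.testing.assert_allclose(score.to_numpy(), np.sqrt(2) * z, atol=1e-8)

    def test_sign_orientation_holds_across_seeds(self):
        for seed in range(100):
            local = np.random.default_rng(seed)
            X = local.normal(size=(6, 25))
            score = pca_signature_score(_expr(X), [f"g{i}" for i in range(6)])
            Xz = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=0, keepdims=True)
            assert np.corrcoef(score, Xz.mean(axis=0))[0, 1] >= 0

    def test_affine_rescaling_invariance(self, rng):
        X = rng.normal(size=(4, 20))
        a = pca_signature_score(_expr(X), [f"g{i}" for i in range(4)])
        scaled = X * np.array([[2.0], [5.0], [0.5], [9.0]]) + np.array([[1.0], [-3.0], [7.0], [0.0]])
        b = pca_signature_score(_expr(scaled), [f"g{i}" for i in range(4)])
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-8)

    def test_empty_intersection_rejected(self, rng):
        with pytest.raises(ValueError, match="intersection"):
            pca_signature_score(_expr(rng.normal(size=(3, 5))), ["nope"])


class TestIciScore:
    def test_arithmetic_and_antisymmetry(self, rng):
        idx = [f"s{j}" for j in range(10)]
        s1 = pd.Series(rng.normal(size=10), index=idx)
        s2 = pd.Series(rng.normal(size=10), index=idx)
        assert ici_score(pd.Series([2.0], index=["x"]), pd.Series([0.5], index=["x"])).iloc[0] == 1.5
        np.testing.assert_allclose(ici_score(s1, s1), 0.0)
        np.testing.assert_allclose(ici_score(s1, s2) + ici_score(s2, s1), 0.0, atol=1e-12)

    def test_sample_mismatch_rejected(self):
        s1 = pd.Series([1.0], index=["a"])
        s2 = pd.Series([1.0], index=["b"])
        with pytest.raises(ValueError, match="sample ids"):
            ici_score(s1, s2)


class TestSplitByCutpoint:
    def _cohort(self, rng, n=300, hr=3.0):
        scores = pd.Series(rng.normal(0, 1, n), index=[f"s{j}" for j in range(n)])
        hazard = np.where(scores > 0, 1.0, hr) / 1000.0  # high score protective
        surv = pd.DataFrame(
            {
                "sample_id": scores.index,
                "os_time": rng.exponential(1.0 / hazard) + 1,
                "os_event": 1,
            }
        )
        return scores, surv

    def test_recovers_planted_hazard_step(self, rng):
        scores, surv = self._cohort(rng)
        table = split_by_cutpoint(scores, surv)
        assert abs(table["cutpoint"].iloc[0]) < 0.25
        assert set(table["group"].unique()) == {"high", "low"}

    def test_monotone_transform_preserves_groups(self, rng):
        scores, surv = self._cohort(rng, n=100)
        t1 = split_by_cutpoint(scores, surv)
        t2 = split_by_cutpoint(np.exp(scores), surv)
        pd.testing.assert_series_equal(t1["group"], t2["group"])

    def test_constant_scores_rejected(self, rng):
        scores, surv = self._cohort(rng, n=50)
        with pytest.raises(ValueError):
            split_by_cutpoint(pd.Series(1.0, index=scores.index), surv)


class TestComputeSignatureScores:
    def test_end_to_end_table_shape_and_identity(self, rng):
        n = 60
        samples = [f"s{j}" for j in range(n)]
        group = np.array(["A"] * 30 + ["B"] * 30)
        X = rng.normal(5, 1, size=(40, n))
        X[:10, group == "A"] += 2.0  # type I candidates
        X[10:20, group == "B"] += 2.0  # type II candidates
        expr = _expr(X, samples=samples)
        labels = pd.Series(group, index=samples)
        surv = pd.DataFrame(
            {
                "sample_id": samples,
                "os_time": np.where(group == "A", 2000.0, 300.0) + rng.normal(0, 20, n),
                "os_event": 1,
            }
        )
        out = compute_signature_scores(
            expr, [f"g{i}" for i in range(20)], labels, survival_data=surv,
            n_trees=60, max_iter=25, seed=6,
        )
        np.testing.assert_allclose(out["ici_score"], out["s_pca_1"] - out["s_pca_2"], atol=1e-12)
        assert {"group", "cutpoint"} <= set(out.columns)
        # type-I program tracks cluster A, which survives longer -> ici score higher in A
        assert out.loc[labels == "A", "ici_score"].mean() > out.loc[labels == "B", "ici_score"].mean()
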