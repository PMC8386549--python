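"""ICI score construction: gene typing, shadow-feature selection and PCA scores.

The per-sample immune-infiltration score is built in four steps:

1. ``assign_gene_types`` — each DEG is typed by the sign of its Spearman
   correlation with the gene-cluster indicator (cluster A = 1): positive
   correlation = type I, otherwise type II. Cluster A is the
   better-prognosis gene cluster, so type I genes mark the favorable
   expression program.
2. ``boruta_select`` — characteristic genes are confirmed by an
   all-relevant shadow-feature procedure: permuted copies of every
   candidate compete with the real features inside a random forest, and
   binomial tests on "beat the best shadow" hit counts promote features to
   confirmed or rejected.
3. ``pca_signature_score`` — each type's confirmed genes are summarized per
   sample by the first principal component of the z-scored submatrix, with
   the sign oriented so high score = high mean expression of the set.
4. ``ici_score`` / ``split_by_cutpoint`` — ICI score = S_PCA I - S_PCA II;
   patients are split into high/low groups at the maximally selected
   log-rank cutpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from . import survival as surv
from .data_io import ExpressionMatrix

__all__ = [
    "assign_gene_types",
    "boruta_select",
    "FeatureSelectionResult",
    "pca_signature_score",
    "ici_score",
    "split_by_cutpoint",
    "compute_signature_scores",
]


def _as_values(expr) -> pd.DataFrame:
    return expr.values if isinstance(expr, ExpressionMatrix) else expr


def assign_gene_types(expr, deg_genes, gene_cluster_labels: pd.Series) -> pd.DataFrame:
    """Type DEGs by Spearman correlation with the gene-cluster-A indicator.

    Returns a DataFrame indexed by gene with ``correlation`` and ``type``
    ('I' when the correlation is strictly positive, else 'II'; genes with
    undefined correlation — constant expression — fall to type II with a
    warning).
    """
    values = _as_values(expr)
    deg_genes = pd.Index(deg_genes)
    missing = deg_genes.difference(values.index)
    if len(missing):
        raise ValueError(f"DEG genes absent from expression matrix: {missing.tolist()[:5]}")
    clusters = gene_cluster_labels.reindex(values.columns)
    if clusters.isna().any():
        raise ValueError("every sample needs a gene-cluster label")
    uniq = set(clusters.unique())
    if uniq != {"A", "B"}:
        raise ValueError(f"gene clusters must be binary A/B, got {sorted(uniq)}")
    indicator = (clusters == "A").astype(float).to_numpy()

    rows = []
    for g in deg_genes:
        x = values.loc[g].to_numpy(dtype=float)
        if np.all(x == x[0]):
            warnings.warn(f"gene {g!r} has constant expression; assigned type II", stacklevel=2)
            rows.append((np.nan, "II"))
            continue
        rho = stats.spearmanr(x, indicator).statistic
        rows.append((float(rho), "I" if rho > 0 else "II"))
    return pd.DataFrame(rows, index=deg_genes, columns=["correlation", "type"])


@dataclass
class FeatureSelectionResult:
    """Outcome of the shadow-feature selection loop."""

    decisions: pd.Series  # gene -> {confirmed, rejected, tentative}
    importance_history: pd.DataFrame  # iterations x genes
    n_iterations: int

    @property
    def confirmed(self) -> pd.Index:
        return self.decisions.index[self.decisions == "confirmed"]


def boruta_select(
    X: pd.DataFrame,
    target: pd.Series | np.ndarray,
    n_trees: int = 200,
    max_iter: int = 100,
    alpha: float = 0.01,
    seed: int = 0,
) -> FeatureSelectionResult:
    """All-relevant feature selection against shadow (permuted) features.

    Each iteration appends a column-permuted copy of every undecided (and
    confirmed) feature, fits a random-forest classifier, and scores a *hit*
    for a real feature whose importance exceeds the best shadow importance.
    Two-sided binomial tests on the hit counts (Bonferroni-corrected at
    ``alpha`` over the initial candidates) promote features to confirmed or
    rejected; the loop stops when nothing is tentative or at ``max_iter``.

    The shadow pool is held at its initial size throughout: as features are
    rejected, extra permuted copies of the remaining features are appended,
    so the best-shadow reference bar does not weaken late in the run (a
    shrinking pool lets a chance-correlated survivor outscore a handful of
    shadows almost surely, inflating false confirmations on null data).
    """
    X = X.copy()
    y = np.asarray(target)
    if len(np.unique(y)) < 2:
        raise ValueError("target must have at least 2 classes")
    if X.shape[1] < 1:
        raise ValueError("need at least one candidate feature")
    rng = np.random.default_rng(seed)
    genes = X.columns
    m = len(genes)
    decisions = pd.Series("tentative", index=genes)
    hits = pd.Series(0, index=genes)
    history = []

    it = 0
    for it in range(1, max_iter + 1):
        active = decisions.index[decisions != "rejected"]
        Xa = X[active].to_numpy(dtype=float)
        n_shadow = max(m, 5)
        src = np.concatenate([np.arange(Xa.shape[1])] * (n_shadow // Xa.shape[1] + 1))[:n_shadow]
        shadow = Xa[:, src].copy()
        for j in range(shadow.shape[1]):
            shadow[:, j] = rng.permutation(shadow[:, j])
        design = np.hstack([Xa, shadow])
        forest = RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=int(rng.integers(2**31)),
            n_jobs=1,
        )
        forest.fit(design, y)
        imp = forest.feature_importances_
        real_imp = pd.Series(imp[: len(active)], index=active)
        shadow_max = imp[len(active):].max()
        hits[real_imp.index[real_imp > shadow_max]] += 1
        history.append(real_imp.reindex(genes))

        tentative = decisions.index[decisions == "tentative"]
        if len(tentative):
            upper = stats.binom.sf(hits[tentative] - 1, it, 0.5)  # P(X >= hits)
            lower = stats.binom.cdf(hits[tentative], it, 0.5)  # P(X <= hits)
            decisions[tentative[upper < alpha / m]] = "confirmed"
            decisions[tentative[lower < alpha / m]] = "rejected"
        if (decisions != "tentative").all():
            break

    return FeatureSelectionResult(
        decisions=decisions,
        importance_history=pd.DataFrame(history, index=pd.RangeIndex(1, len(history) + 1, name="iteration")),
        n_iterations=it,
    )


def pca_signature_score(expr, gene_set) -> pd.Series:
    """Per-sample first-principal-component score of a gene set.

    Genes are z-scored across samples; the score is each sample's
    coordinate on PC1 of the samples x genes submatrix, with the sign fixed
    so the score correlates positively with the set's mean z-expression.
    A single-gene set therefore returns exactly that gene's z-scores.
    """
    values = _as_values(expr)
    genes = pd.Index(gene_set).intersection(values.index)
    if len(genes) == 0:
        raise ValueError("gene set has empty intersection with the expression matrix")
    X = values.loc[genes].to_numpy(dtype=float)  # genes x samples
    sd = X.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    # PC1 coordinates of samples: SVD of the samples x genes matrix
    U, S, _ = np.linalg.svd(Z.T, full_matrices=False)
    score = U[:, 0] * S[0]
    mean_z = Z.mean(axis=0)
    orient = np.dot(score, mean_z)
    if orient < 0:
        score = -score
    return pd.Series(score, index=values.columns, name="pca_score")


def ici_score(s1: pd.Series, s2: pd.Series) -> pd.Series:
    """ICI score = type-I signature score minus type-II signature score."""
    if not s1.index.equals(s2.index):
        raise ValueError("sample ids of the two signature scores do not match")
    out = s1 - s2
    out.name = "ici_score"
    return out


def split_by_cutpoint(scores: pd.Series, survival_data: pd.DataFrame, minprop: float = 0.1) -> pd.DataFrame:
    """Split samples into high/low groups at the optimal survival cutpoint.

    The cutpoint maximizes the standardized two-group log-rank statistic
    over admissible candidates (see ``survival.maxstat_cutpoint``); group
    membership depends only on score ranks, so any strictly monotone
    transform of the scores yields the same split.
    """
    sd = survival_data.set_index("sample_id") if "sample_id" in survival_data.columns else survival_data
    shared = scores.index.intersection(sd.index)
    if len(shared) < 20:
        raise ValueError("cutpoint split needs at least 20 samples with survival data")
    aligned = sd.loc[shared]
    cut = surv.maxstat_cutpoint(scores.loc[shared], aligned, minprop=minprop)
    out = pd.DataFrame(index=scores.index)
    out["ici_score"] = scores
    out["group"] = np.where(scores > cut.cutpoint, "high", "low")
    out["cutpoint"] = cut.cutpoint
    return out


def compute_signature_scores(
    expr,
    deg_genes,
    gene_cluster_labels: pd.Series,
    survival_data: pd.DataFrame | None = None,
    select_features: bool = True,
    n_trees: int = 200,
    max_iter: int = 100,
    alpha: float = 0.01,
    seed: int = 0,
    minprop: float = 0.1,
) -> pd.DataFrame:
    """Full signature scoring: typing -> selection -> PCA scores -> ICI score.

    Returns a per-sample table with ``s_pca_1``, ``s_pca_2``, ``ici_score``
    and, when survival data are supplied, ``group`` and ``cutpoint``.
    """
    values = _as_values(expr)
    types = assign_gene_types(expr, deg_genes, gene_cluster_labels)
    if select_features and len(types) > 1:
        sel = boruta_select(
            values.loc[types.index].T,
            gene_cluster_labels.reindex(values.columns),
            n_trees=n_trees,
            max_iter=max_iter,
            alpha=alpha,
            seed=seed,
        )
        confirmed = sel.confirmed
    else:
        confirmed = types.index
    sets = {}
    for t in ("I", "II"):
        members = types.index[(types["type"] == t)].intersection(confirmed)
        if len(members) == 0:
            members = types.index[types["type"] == t]
            if len(members) == 0:
                raise ValueError(f"no type-{t} genes available for scoring")
            warnings.warn(f"no confirmed type-{t} genes; falling back to all type-{t} DEGs", stacklevel=2)
        sets[t] = members

    s1 = pca_signature_score(expr, sets["I"])
    s2 = pca_signature_score(expr, sets["II"])
    out = pd.DataFrame({"s_pca_1": s1, "s_pca_2": s2})
    out["ici_score"] = ici_score(s1, s2)
    if survival_data is not None:
        split = split_by_cutpoint(out["ici_score"], survival_data, minprop=minprop)
        out["group"] = split["group"]
        out["cutpoint"] = split["cutpoint"]
    return out
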