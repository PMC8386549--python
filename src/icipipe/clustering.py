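"""Consensus K-means clustering of samples with delta-area K selection.

Immunophenotypes ("ICI clusters") are consensus partitions of samples by
immune-cell fractions; "gene clusters" are consensus partitions by DEG
expression. Both ride on the same engine: repeated K-means on random
sample subsets, co-assignment frequencies accumulated into a consensus
matrix per K, final labels from hierarchical clustering of the consensus
distance, and K chosen where the relative gain in area under the
consensus-CDF is largest (caller-overridable; K is capped at 9 by
default, and the cohort-level analysis uses overrides K=3 for ICI
clusters and K=2 for gene clusters).

Cluster letters are anchored to prognosis: when survival data are
supplied, "A" is the cluster with the best (largest restricted-mean)
Kaplan-Meier survival, then "B", "C", ... in worsening order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from . import survival as surv
from .data_io import ExpressionMatrix

__all__ = ["ConsensusResult", "consensus_cluster", "ici_clusters", "gene_clusters"]

DEFAULT_K_MAX = 9
DEFAULT_REPS = 100
DEFAULT_P_ITEM = 0.8


@dataclass
class ConsensusResult:
    """Consensus matrices, per-K labels and the delta-area K choice."""

    sample_ids: pd.Index
    consensus: dict[int, np.ndarray]
    labels: dict[int, pd.Series]
    cdf_area: dict[int, float]
    cdf_delta_area: dict[int, float]
    chosen_k: int

    def labels_for(self, k: int | None = None) -> pd.Series:
        return self.labels[self.chosen_k if k is None else k]


def _cdf_area(consensus: np.ndarray) -> float:
    """Area under the empirical CDF of off-diagonal consensus entries.

    Equals 1 - mean(entries): crisper consensus (entries near 0/1 with many
    zeros) gives larger area.
    """
    iu = np.triu_indices_from(consensus, k=1)
    return float(1.0 - consensus[iu].mean())


def consensus_cluster(
    features: pd.DataFrame | np.ndarray,
    k_max: int = DEFAULT_K_MAX,
    reps: int = DEFAULT_REPS,
    p_item: float = DEFAULT_P_ITEM,
    seed: int = 0,
) -> ConsensusResult:
    """Subsampled consensus K-means over K = 2..k_max.

    Parameters
    ----------
    features
        Samples x features. If a DataFrame, samples are internally sorted by
        id so the partition is invariant to input row order.
    k_max, reps, p_item
        Largest K examined, number of subsampling rounds per K, and the
        fraction of samples drawn (without replacement) per round.
    """
    if isinstance(features, pd.DataFrame):
        ids = features.index
        order = np.argsort(np.asarray(ids.astype(str)))
        X = features.to_numpy(dtype=float)[order]
        ids = ids[order]
    else:
        X = np.asarray(features, dtype=float)
        ids = pd.RangeIndex(len(X))
        order = np.arange(len(X))
    n = len(X)
    if n < 3:
        raise ValueError("consensus clustering needs at least 3 samples")
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if k_max >= n:
        raise ValueError("k_max must be smaller than the number of samples")
    if reps < 2:
        raise ValueError("need at least 2 subsampling rounds")
    if not 0 < p_item <= 1:
        raise ValueError("p_item must lie in (0, 1]")

    n_sub = max(2, int(round(p_item * n)))
    consensus: dict[int, np.ndarray] = {}
    labels: dict[int, pd.Series] = {}
    for k in range(2, k_max + 1):
        rng = np.random.default_rng((seed, k))
        co_assigned = np.zeros((n, n))
        co_sampled = np.zeros((n, n))
        for _ in range(reps):
            idx = rng.choice(n, size=n_sub, replace=False)
            km = KMeans(n_clusters=k, n_init=1, random_state=int(rng.integers(2**31)))
            part = km.fit_predict(X[idx])
            ind = np.zeros((n,), dtype=int) - 1
            ind[idx] = part
            sampled = ind >= 0
            co_sampled[np.ix_(idx, idx)] += 1
            for c in range(k):
                members = np.flatnonzero(sampled & (ind == c))
                co_assigned[np.ix_(members, members)] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.where(co_sampled > 0, co_assigned / np.maximum(co_sampled, 1), 0.0)
        np.fill_diagonal(M, 1.0)
        M = (M + M.T) / 2.0
        consensus[k] = M
        final = fcluster(linkage(squareform(1.0 - M, checks=False), method="average"), k, criterion="maxclust")
        labels[k] = pd.Series(final - 1, index=ids, name="cluster")

    area = {k: _cdf_area(consensus[k]) for k in consensus}
    delta = {}
    for k in sorted(area):
        if k == 2:
            delta[k] = area[k]
        else:
            prev = area[k - 1]
            delta[k] = (area[k] - prev) / prev if prev > 0 else 0.0
    chosen = max(sorted(delta), key=lambda k: delta[k])
    return ConsensusResult(
        sample_ids=ids,
        consensus=consensus,
        labels=labels,
        cdf_area=area,
        cdf_delta_area=delta,
        chosen_k=chosen,
    )


def _letter_by_prognosis(labels: pd.Series, survival_data: pd.DataFrame | None) -> pd.Series:
    """Relabel integer clusters as letters; 'A' = best restricted-mean survival."""
    clusters = sorted(labels.unique())
    if survival_data is not None:
        sd = survival_data.set_index("sample_id") if "sample_id" in survival_data.columns else survival_data
        sd = sd.loc[sd.index.intersection(labels.index)]
        horizon = float(sd["os_time"].max())
        rmst = {}
        for c in clusters:
            members = labels.index[labels == c].intersection(sd.index)
            rmst[c] = surv.restricted_mean_survival(sd.loc[members], horizon=horizon) if len(members) else -np.inf
        clusters = sorted(clusters, key=lambda c: -rmst[c])
    else:
        sizes = labels.value_counts()
        clusters = sorted(clusters, key=lambda c: (-sizes[c], c))
    letter = {c: chr(ord("A") + i) for i, c in enumerate(clusters)}
    return labels.map(letter)


def ici_clusters(
    fractions: pd.DataFrame,
    k: int | None = 3,
    survival_data: pd.DataFrame | None = None,
    k_max: int = DEFAULT_K_MAX,
    reps: int = DEFAULT_REPS,
    p_item: float = DEFAULT_P_ITEM,
    seed: int = 0,
    honor_screen: bool = True,
) -> pd.Series:
    """Immunophenotype samples by their cell-fraction profiles.

    Samples flagged ``excluded`` by the deconvolution permutation screen are
    dropped (``honor_screen=False`` keeps them). ``k=None`` lets the
    delta-area rule choose; the cohort-level default is the three-cluster
    phenotyping (A/B/C, A = best prognosis when survival data are given).
    Fractions are used un-rescaled: they already live on the simplex.
    """
    feats = fractions
    if honor_screen and "excluded" in feats.columns:
        feats = feats[~feats["excluded"].astype(bool)]
    feats = feats.drop(columns=[c for c in ("rmse", "pearson_r", "perm_p", "excluded") if c in feats.columns])
    if feats.empty:
        raise ValueError("no samples left after the permutation screen")
    res = consensus_cluster(feats, k_max=k_max, reps=reps, p_item=p_item, seed=seed)
    labels = res.labels_for(k)
    return _letter_by_prognosis(labels, survival_data)


def gene_clusters(
    deg_expr: ExpressionMatrix | pd.DataFrame,
    k: int | None = 2,
    survival_data: pd.DataFrame | None = None,
    k_max: int = DEFAULT_K_MAX,
    reps: int = DEFAULT_REPS,
    p_item: float = DEFAULT_P_ITEM,
    seed: int = 0,
) -> pd.Series:
    """Partition samples by DEG expression (rows z-scored before clustering)."""
    values = deg_expr.values if isinstance(deg_expr, ExpressionMatrix) else deg_expr
    if values.empty:
        raise ValueError("no DEG rows supplied")
    X = values.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    Xz = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    feats = pd.DataFrame(Xz.T, index=values.columns, columns=values.index)
    res = consensus_cluster(feats, k_max=k_max, reps=reps, p_item=p_item, seed=seed)
    labels = res.labels_for(k)
    return _letter_by_prognosis(labels, survival_data)
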