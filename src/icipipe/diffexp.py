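"""Differential expression with empirical-Bayes moderated statistics.

``moderated_anova`` fits a one-way layout per gene across sample clusters
and tests the omnibus group effect with a moderated F statistic: the
per-gene residual variance s_g^2 (d residual df) is shrunk toward a
common prior s0^2 (d0 prior df) fitted by matching the moments of
log s_g^2 to a scaled inverse-chi-square distribution, and the moderated
F = (between-group mean square) / posterior variance is referred to an
F(k-1, d + d0) distribution. Genes are called differentially expressed at
|log2 fold-change| > 1 (largest absolute pairwise group-mean difference)
and Benjamini-Hochberg FDR < 0.05.

``group_difference_tests`` exposes the nonparametric comparisons used for
per-feature group contrasts: Kruskal-Wallis H (tie-corrected) with a
rank-sum (Wilcoxon) p in the two-group case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = ["moderated_anova", "bh_adjust", "group_difference_tests", "GroupTestResult"]

LFC_THRESHOLD = 1.0
FDR_THRESHOLD = 0.05


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the inverse scale)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_variance_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior (s0^2, d0) on log s^2.

    Var(log s^2) = trigamma(d/2) + trigamma(d0/2); an empirical variance not
    exceeding trigamma(d/2) means no detectable gene-to-gene variance
    heterogeneity and yields d0 = inf (complete shrinkage).
    """
    s2 = np.maximum(s2, 1e-300)
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    n = len(e)
    if n < 2:
        return float(np.exp(e.mean())), np.inf
    evar = e.var(ddof=1) - special.polygamma(1, d / 2.0)
    if evar <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(e.mean()))
    else:
        d0 = 2.0 * _trigamma_inverse(float(evar))
        s0_2 = float(np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return s0_2, d0


def moderated_anova(
    expr,
    labels: pd.Series | np.ndarray,
    lfc_threshold: float = LFC_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Moderated one-way F test per gene across sample clusters.

    Parameters
    ----------
    expr
        Log2-scale ExpressionMatrix or genes x samples DataFrame.
    labels
        Cluster label per sample (>= 2 groups, each of size >= 2).
    prior_df
        Override the fitted prior df d0. ``prior_df=0`` disables shrinkage
        and reproduces the ordinary one-way F exactly.

    Returns
    -------
    DataFrame per gene: one ``mean_<group>`` column per cluster, ``log2fc``
    (largest absolute pairwise group-mean difference), ``moderated_F``,
    ``p_value``, ``fdr`` and ``is_deg``.
    """
    from .data_io import ExpressionMatrix

    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if isinstance(expr, ExpressionMatrix) and expr.unit != "LOG2":
        raise ValueError("moderated_anova expects log2-scale expression")
    labels = pd.Series(np.asarray(labels), index=values.columns)
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    sizes = labels.value_counts()
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise ValueError(f"group(s) with fewer than 2 samples: {small}")

    X = values.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    k = len(groups)
    masks = [labels.to_numpy() == g for g in groups]
    ns = np.array([m.sum() for m in masks], dtype=float)
    means = np.column_stack([X[:, m].mean(axis=1) for m in masks])  # genes x k
    grand = X.mean(axis=1)

    ss_between = ((means - grand[:, None]) ** 2 * ns[None, :]).sum(axis=1)
    ss_total = ((X - grand[:, None]) ** 2).sum(axis=1)
    ss_within = np.maximum(ss_total - ss_between, 0.0)
    d = float(n_samples - k)
    s2 = ss_within / d
    msb = ss_between / (k - 1)

    if prior_df is None:
        s0_2, d0 = _fit_variance_prior(s2, d)
    else:
        d0 = float(prior_df)
        s0_2, _ = _fit_variance_prior(s2, d) if d0 > 0 else (0.0, 0.0)
    if np.isinf(d0):
        post_var = np.full_like(s2, s0_2)
        df_denom = np.inf
    else:
        post_var = (d0 * s0_2 + d * s2) / (d0 + d)
        df_denom = d + d0
    post_var = np.maximum(post_var, 1e-300)
    F = msb / post_var
    if np.isinf(df_denom):
        p = stats.chi2.sf(F * (k - 1), k - 1)
    else:
        p = stats.f.sf(F, k - 1, df_denom)

    # largest absolute pairwise mean difference = range of the group means
    log2fc = means.max(axis=1) - means.min(axis=1)
    fdr = bh_adjust(p)
    out = pd.DataFrame(index=values.index)
    for g, col in zip(groups, means.T):
        out[f"mean_{g}"] = col
    out["log2fc"] = log2fc
    out["moderated_F"] = F
    out["p_value"] = p
    out["fdr"] = fdr
    out["is_deg"] = (log2fc > lfc_threshold) & (fdr < fdr_threshold)
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class GroupTestResult:
    statistic: float  # Kruskal-Wallis H (tie-corrected)
    p: float  # chi-square approximation
    wilcoxon_p: float | None  # two-group rank-sum p (two-sided), else None


def group_difference_tests(values, labels) -> GroupTestResult:
    """Kruskal-Wallis test across groups; adds a Wilcoxon rank-sum p for 2 groups."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in np.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group needs at least one observation")
    if all(np.array_equal(np.sort(g), np.sort(groups[0])) for g in groups[1:]):
        h, p = 0.0, 1.0  # identical multisets: no rank separation
    else:
        h, p = stats.kruskal(*groups)
    wp = None
    if len(groups) == 2:
        method = "exact" if (len(groups[0]) <= 25 and len(groups[1]) <= 25) else "asymptotic"
        try:
            wp = float(stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided", method=method).pvalue)
        except ValueError:  # ties preclude the exact distribution
            wp = float(stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided", method="asymptotic").pvalue)
    return GroupTestResult(statistic=float(h), p=float(p), wilcoxon_p=wp)
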