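"""End-to-end orchestration of the ICI scoring workflow.

Given a bulk expression cohort (TPM), a cell-type reference signature and a
clinical table, ``run_ici_pipeline`` chains the full analysis:

1. deconvolve immune-cell fractions (optional permutation screen),
2. consensus-cluster samples into ICI clusters (default K=3, A/B/C),
3. moderated one-way F across ICI clusters -> DEGs (|log2FC|>1, FDR<0.05),
4. consensus-cluster samples on DEG expression into gene clusters
   (default K=2, A = better prognosis),
5. type DEGs (I/II), select characteristic genes, compute S_PCA I/II and
   the ICI score, and split high/low at the optimal survival cutpoint.

Survival inputs are filtered to >= 30 days of follow-up before any
Kaplan-Meier, log-rank or cutpoint computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import clustering, deconvolution, diffexp, signature, survival
from .data_io import ExpressionMatrix, log2_transform

__all__ = ["PipelineResult", "run_ici_pipeline"]


@dataclass
class PipelineResult:
    fractions: pd.DataFrame
    ici_cluster: pd.Series
    deg: pd.DataFrame
    gene_cluster: pd.Series
    scores: pd.DataFrame  # s_pca_1, s_pca_2, ici_score, group, cutpoint
    survival_used: pd.DataFrame

    @property
    def deg_genes(self) -> pd.Index:
        return self.deg.index[self.deg["is_deg"]]


def run_ici_pipeline(
    expression: ExpressionMatrix,
    clinical: pd.DataFrame,
    reference_signature: ExpressionMatrix | pd.DataFrame,
    n_perm: int = 0,
    ici_k: int | None = 3,
    gene_k: int | None = 2,
    reps: int = 100,
    select_features: bool = True,
    min_followup: float = 30.0,
    seed: int = 0,
) -> PipelineResult:
    """Run the whole workflow on one cohort; see the module docstring."""
    if expression.unit == "LOG2":
        raise ValueError("pipeline expects linear-scale (TPM) expression input")
    surv_data = survival.filter_min_followup(clinical, min_days=min_followup).set_index("sample_id")

    fractions = deconvolution.deconvolve(expression, reference_signature, n_perm=n_perm, seed=seed)
    ici_labels = clustering.ici_clusters(
        fractions, k=ici_k, survival_data=surv_data, reps=reps, seed=seed
    )

    # samples dropped by the permutation screen leave the analysis here
    kept = ici_labels.index
    log_all = log2_transform(expression)
    log_expr = ExpressionMatrix(log_all.values[kept], "LOG2")
    deg = diffexp.moderated_anova(log_expr, ici_labels.reindex(log_expr.sample_ids))
    deg_genes = deg.index[deg["is_deg"]]
    if len(deg_genes) == 0:
        raise ValueError("no DEGs pass |log2FC| > 1 and FDR < 0.05")

    deg_matrix = ExpressionMatrix(log_expr.values.loc[deg_genes], "LOG2")
    gene_labels = clustering.gene_clusters(
        deg_matrix, k=gene_k, survival_data=surv_data, reps=reps, seed=seed
    )

    scores = signature.compute_signature_scores(
        log_expr,
        deg_genes,
        gene_labels.reindex(log_expr.sample_ids),
        survival_data=surv_data,
        select_features=select_features,
        seed=seed,
    )
    return PipelineResult(
        fractions=fractions,
        ici_cluster=ici_labels,
        deg=deg,
        gene_cluster=gene_labels,
        scores=scores,
        survival_used=surv_data,
    )
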