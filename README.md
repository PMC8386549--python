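# icipipe

Immune-cell-infiltration (ICI) scoring for tumor expression cohorts.

Bulk tumor transcriptomes mix malignant cells with infiltrating immune and
stromal cells, and the composition of that infiltrate carries prognostic
information: immune-rich colon tumors, for example, tend to have better
overall survival. `icipipe` implements the full workflow that turns a bulk
expression cohort into a per-patient prognostic immune score:

1. **Deconvolution** — per-sample immune-cell fractions by linear ν-support-
   vector regression against a cell-type reference signature
   (ν ∈ {0.25, 0.5, 0.75}, best-RMSE fit, simplex-projected coefficients),
   with a gene-permutation p-value screen (p < 0.05) and rank-based
   immune/stromal enrichment scores.
2. **Immunophenotyping** — consensus K-means over subsampled cohorts
   (100 reps, 80% of samples per rep, K ≤ 9, delta-area K selection) defines
   *ICI clusters* from cell fractions.
3. **Differential expression** — an empirical-Bayes moderated one-way F test
   across ICI clusters; DEGs pass |log₂FC| > 1 and BH FDR < 0.05.
4. **Gene clusters and gene types** — consensus clustering of samples on DEG
   expression (*gene clusters*, A = better prognosis); each DEG is *type I*
   if positively correlated with gene-cluster A membership, else *type II*.
5. **ICI score** — characteristic genes are selected by a shadow-feature
   random-forest procedure; each type's genes are summarized by the first
   principal component of the z-scored expression submatrix
   (S<sub>PCA I</sub>, S<sub>PCA II</sub>), and

   **ICI score = S<sub>PCA I</sub> − S<sub>PCA II</sub>**

   Patients are split into high/low ICI-score groups at the maximally
   selected log-rank cutpoint; survival comparisons use Kaplan–Meier curves
   and the log-rank test, excluding patients followed < 30 days.
6. **Tumor mutation burden** — TMB as the per-sample nonsynonymous mutation
   count from a MAF-like table, high/low TMB splits, TMB × ICI combined
   subgroups, Spearman correlation of TMB with the ICI score and per-gene
   Fisher exact frequency contrasts between ICI-score groups.

A first-class synthetic-cohort generator (`icipipe.synthetic_data`) emulates
every input with known ground truth — cell fractions, planted sample
clusters, signed DEGs, a latent protective immune score driving exponential
survival, and per-sample mutation counts — so every stage is testable
without any external download.

## Worked example

```python
import numpy as np
from scipy import stats
from icipipe import SimulationConfig, simulate_cohort, run_ici_pipeline
from icipipe.data_io import ExpressionMatrix
from icipipe.synthetic_data import make_reference_signature, marker_gene_ids
from icipipe.survival import logrank_test

cfg = SimulationConfig(seed=42)          # 300 samples, 8 cell types, 3 clusters
expr, clinical, muts, truth = simulate_cohort(cfg)
ref = make_reference_signature(cfg)
sig = ExpressionMatrix(ref.values.loc[marker_gene_ids(cfg)], "TPM")

result = run_ici_pipeline(expr, clinical, sig, seed=42)
ici = result.scores["ici_score"]
print("DEGs:", int(result.deg["is_deg"].sum()))
print("Spearman(ICI score, latent truth):",
      round(stats.spearmanr(ici, truth.latent_score[ici.index]).statistic, 3))
shared = result.scores.index.intersection(result.survival_used.index)
print("log-rank p (high vs low):",
      logrank_test(result.survival_used.loc[shared],
                   result.scores.loc[shared, "group"]).p)
```

prints

```
DEGs: 300
Spearman(ICI score, latent truth): 0.963
log-rank p (high vs low): 7.412192139333382e-50
```

i.e. the pipeline recovers the planted immune score almost perfectly
(rank correlation 0.963 between the computed ICI score and the latent
ground truth), the 300 genes whose expression separates the planted
immunophenotypes are called as DEGs, and the high-ICI group's survival
advantage is overwhelming at the planted protective effect.

The same steps are available from a shell:

```bash
icipipe simulate --config sim.yaml --outdir cohort/
icipipe deconvolve --expr cohort/expression.tsv --signature cohort/signature.tsv --out fractions.tsv
icipipe cluster --mode ici --input fractions.tsv --clinical cohort/clinical.tsv --out ici_labels.tsv
icipipe deg --expr cohort/expression.tsv --labels ici_labels.tsv --out deg.tsv
icipipe tmb --maf cohort/mutations.maf.tsv --ici-scores ici_scores.tsv --out tmb/
```

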