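"""Synthetic tumor cohorts with known immune ground truth.

Generates every input the pipeline consumes — a cell-type reference
signature, bulk expression as non-negative mixtures of those profiles, a
clinical table with survival driven by a latent immune score, and a
MAF-like mutation table — together with the ground truth (cell fractions,
planted sample clusters, DEG signs, latent scores, mutation counts) needed
to test each downstream stage.

Model
-----
* Reference profiles: each cell type owns a disjoint block of marker genes
  with 8-fold elevated mean abundance over a shared log-normal baseline.
* Cell fractions: Dirichlet draws around cluster-specific archetypes, so
  the planted sample clusters are visible to fraction-based clustering.
* Expression: ``signature @ fractions.T`` scaled to a 1e6 library size,
  then cluster-specific DEG shifts and Gaussian noise applied on the log2
  scale (multiplicative log-normal noise on the linear scale, matching
  RNA-seq heteroskedasticity and keeping values non-negative).
* Latent score: mean z-expression of positive-sign DEGs minus mean
  z-expression of negative-sign DEGs, mirroring the structure of the ICI
  score so parameter-recovery tests are meaningful.
* Survival: exponential times with hazard ``lambda0 * exp(-hazard_beta *
  latent)`` — ``hazard_beta`` is protective per unit latent score, so high
  immune infiltration means better prognosis. Censoring replaces the event
  with a uniform draw on (0, T) at rate ``censor_rate``.
* Mutations: per-sample Poisson counts with means uniform over
  ``mutation_rate_range``, expanded to MAF-like rows with ~70%
  nonsynonymous variant classes (exercising the TMB filter).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "make_reference_signature",
    "marker_gene_ids",
    "simulate_cohort",
]

#: MAF Variant_Classification values counted as nonsynonymous (~70% of draws).
NONSYNONYMOUS_CLASSES = (
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "In_Frame_Del",
    "In_Frame_Ins",
    "Splice_Site",
)

SILENT_CLASSES = ("Silent", "3'UTR", "5'UTR", "Intron")

MARKER_FOLD = 8.0  # marker elevation over baseline
MARKERS_PER_TYPE_CAP = 30  # keeps the marker signature compact (LM22-sized)
BASELINE_LOG_MEAN = 3.0  # natural-log mean of baseline abundance
BASELINE_LOG_SD = 1.0
LIBRARY_SIZE = 1e6
BASE_HAZARD = np.log(2) / 730.0  # median survival ~2 years at latent score 0


class ConfigurationError(ValueError):
    """Degenerate simulation configuration."""


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a desk-scale analogue of a merged bulk colon-cancer
    cohort: 300 tumors, 8 immune cell types, 3 infiltration clusters, 10%
    cluster-informative genes shifted by 2 log2 units, log-scale noise
    sd 0.2, ~30% censoring and 5-80 expected mutations per sample.
    """

    n_genes: int = 1200
    n_samples: int = 300
    n_cell_types: int = 8
    n_clusters: int = 3
    cluster_proportions: tuple[float, ...] | None = None
    deg_fraction: float = 0.10
    deg_log2_effect: float = 2.0
    noise_sd: float = 0.2
    hazard_beta: float = 1.0
    censor_rate: float = 0.3
    mutation_rate_range: tuple[float, float] = (5.0, 80.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_samples", "n_cell_types", "n_clusters"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.cluster_proportions is None:
            self.cluster_proportions = tuple([1.0 / self.n_clusters] * self.n_clusters)
        props = np.asarray(self.cluster_proportions, dtype=float)
        if len(props) != self.n_clusters or not np.isclose(props.sum(), 1.0):
            raise ConfigurationError("cluster_proportions must have n_clusters entries summing to 1")
        if not 0.0 <= self.deg_fraction <= 1.0:
            raise ConfigurationError("deg_fraction must lie in [0, 1]")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ConfigurationError("censor_rate must lie in [0, 1)")
        lo, hi = self.mutation_rate_range
        if lo < 0 or hi < lo:
            raise ConfigurationError("mutation_rate_range must be 0 <= lo <= hi")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a simulated cohort."""

    true_fractions: pd.DataFrame  # samples x cell types, rows on the simplex
    true_cluster: pd.Series  # sample -> cluster id (0..K-1)
    true_deg_genes: pd.Series  # gene -> sign (+1 / -1)
    latent_score: pd.Series  # sample -> real
    true_mutcount: pd.Series  # sample -> nonsynonymous count

    def to_json(self, path) -> None:
        payload = {
            "true_fractions": self.true_fractions.to_dict(orient="index"),
            "true_cluster": self.true_cluster.astype(int).to_dict(),
            "true_deg_genes": self.true_deg_genes.astype(int).to_dict(),
            "latent_score": self.latent_score.to_dict(),
            "true_mutcount": self.true_mutcount.astype(int).to_dict(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)


def _gene_ids(n: int) -> pd.Index:
    return pd.Index([f"G{i:05d}" for i in range(n)], name="gene_id")


def _sample_ids(n: int) -> pd.Index:
    return pd.Index([f"S{i:04d}" for i in range(n)], name="sample_id")


def _markers_per_type(config: SimulationConfig) -> int:
    return min(config.n_genes // (2 * config.n_cell_types), MARKERS_PER_TYPE_CAP)


def marker_gene_ids(config: SimulationConfig) -> pd.Index:
    """Gene ids of the disjoint marker blocks (the compact signature genes)."""
    m = _markers_per_type(config)
    return _gene_ids(config.n_genes)[: m * config.n_cell_types]


def make_reference_signature(config: SimulationConfig) -> ExpressionMatrix:
    """Cell-type reference profiles with disjoint marker blocks.

    Each of the ``n_cell_types`` profiles shares a log-normal baseline and
    elevates its own block of marker genes 8-fold, which keeps the marker
    submatrix well conditioned and the profiles mutually distinguishable.
    """
    if config.n_cell_types < 2:
        raise ConfigurationError("need at least 2 cell types")
    if config.n_genes < 10 * config.n_cell_types:
        raise ConfigurationError(
            f"n_genes={config.n_genes} too small for {config.n_cell_types} cell types "
            f"(need >= {10 * config.n_cell_types})"
        )
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    types = [f"CellType{k + 1}" for k in range(config.n_cell_types)]
    markers_per_type = _markers_per_type(config)

    baseline = rng.lognormal(BASELINE_LOG_MEAN, BASELINE_LOG_SD, size=config.n_genes)
    # per-type multiplicative jitter decorrelates the non-marker portions
    profiles = baseline[:, None] * rng.lognormal(0.0, 0.25, size=(config.n_genes, config.n_cell_types))
    for k in range(config.n_cell_types):
        block = slice(k * markers_per_type, (k + 1) * markers_per_type)
        profiles[block, k] *= MARKER_FOLD
    return ExpressionMatrix(pd.DataFrame(profiles, index=genes, columns=types), "TPM")


def _cluster_archetypes(n_clusters: int, n_cell_types: int) -> np.ndarray:
    """Dirichlet concentration vectors: cluster k strongly favors a round-robin
    pair of cell types, keeping archetypes roughly symmetric."""
    alphas = np.full((n_clusters, n_cell_types), 0.4)
    for k in range(n_clusters):
        alphas[k, k % n_cell_types] = 8.0
        alphas[k, (k + n_clusters) % n_cell_types] = 6.0
    return alphas


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate a full cohort: expression, clinical, mutations and truth.

    Returns
    -------
    expression : ExpressionMatrix (unit TPM)
    clinical : DataFrame with sample_id, os_time (days), os_event, age, sex, stage
    mutations : MAF-like DataFrame (Tumor_Sample_Barcode, Hugo_Symbol,
        Variant_Classification)
    truth : SyntheticTruth
    """
    rng = np.random.default_rng(config.seed)
    signature = make_reference_signature(config)
    genes = signature.gene_ids
    samples = _sample_ids(config.n_samples)
    n_types = config.n_cell_types

    # --- planted clusters and cell fractions -------------------------------
    clusters = rng.choice(config.n_clusters, size=config.n_samples, p=np.asarray(config.cluster_proportions))
    alphas = _cluster_archetypes(config.n_clusters, n_types)
    fractions = np.vstack([rng.dirichlet(alphas[c]) for c in clusters])

    # --- expression ---------------------------------------------------------
    mix = signature.values.to_numpy() @ fractions.T  # genes x samples
    mix = mix / mix.sum(axis=0, keepdims=True) * LIBRARY_SIZE
    log_expr = np.log2(mix + 1.0)

    # cluster-informative genes: drawn outside the marker blocks so DEG shifts
    # do not corrupt deconvolution markers
    n_marker = _markers_per_type(config) * n_types
    n_deg = int(round(config.deg_fraction * config.n_genes))
    free = np.arange(n_marker, config.n_genes)
    n_deg = min(n_deg, len(free))
    deg_idx = rng.choice(free, size=n_deg, replace=False)
    deg_sign = rng.choice([1.0, -1.0], size=n_deg)
    # cluster weights span +1..-1 so DEGs separate the planted clusters
    weights = np.linspace(1.0, -1.0, config.n_clusters) if config.n_clusters > 1 else np.array([1.0])
    shift = np.zeros_like(log_expr)
    shift[deg_idx, :] = deg_sign[:, None] * config.deg_log2_effect * weights[clusters][None, :]
    log_expr = log_expr + shift
    if config.noise_sd > 0:
        log_expr = log_expr + rng.normal(0.0, config.noise_sd, size=log_expr.shape)
    expr_values = np.maximum(np.exp2(log_expr) - 1.0, 0.0)
    expression = ExpressionMatrix(pd.DataFrame(expr_values, index=genes, columns=samples), "TPM")

    # --- latent score: type-I-minus-type-II aggregate of the planted DEGs ---
    log_final = np.log2(expr_values + 1.0)
    if n_deg > 0:
        sub = log_final[deg_idx, :]
        sd = sub.std(axis=1, ddof=0)
        sd[sd == 0] = 1.0
        z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        pos, neg = deg_sign > 0, deg_sign < 0
        latent = (z[pos].mean(axis=0) if pos.any() else 0.0) - (z[neg].mean(axis=0) if neg.any() else 0.0)
        latent = np.asarray(latent, dtype=float)
    else:
        latent = np.zeros(config.n_samples)

    # --- survival -----------------------------------------------------------
    hazard = BASE_HAZARD * np.exp(-config.hazard_beta * latent)
    event_time = rng.exponential(1.0 / hazard)
    censored = rng.random(config.n_samples) < config.censor_rate
    os_time = np.where(censored, rng.uniform(0.0, event_time), event_time)
    os_time = np.maximum(os_time, 1.0)
    clinical = pd.DataFrame(
        {
            "sample_id": samples,
            "os_time": os_time,
            "os_event": (~censored).astype(int),
            "age": rng.integers(35, 90, size=config.n_samples),
            "sex": rng.choice(["F", "M"], size=config.n_samples),
            "stage": rng.choice(["I", "II", "III", "IV"], size=config.n_samples),
        }
    )

    # --- mutations ----------------------------------------------------------
    lo, hi = config.mutation_rate_range
    mut_mean = rng.uniform(lo, hi, size=config.n_samples)
    nonsyn_counts = rng.poisson(mut_mean)
    gene_pool = np.asarray(genes)
    # Zipf-like weights make a handful of genes recurrently mutated
    pool_w = 1.0 / np.arange(1, len(gene_pool) + 1)
    pool_w /= pool_w.sum()
    records: list[tuple[str, str, str]] = []
    for i, sid in enumerate(samples):
        n_nonsyn = int(nonsyn_counts[i])
        n_silent = rng.binomial(max(n_nonsyn, 1), 0.43)  # ~70% of all records nonsynonymous
        hit_genes = rng.choice(gene_pool, size=n_nonsyn + n_silent, replace=True, p=pool_w)
        classes = np.concatenate(
            [
                rng.choice(NONSYNONYMOUS_CLASSES, size=n_nonsyn),
                rng.choice(SILENT_CLASSES, size=n_silent),
            ]
        )
        records.extend(zip([sid] * (n_nonsyn + n_silent), hit_genes, classes))
    mutations = pd.DataFrame(records, columns=["Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification"])

    truth = SyntheticTruth(
        true_fractions=pd.DataFrame(fractions, index=samples, columns=signature.sample_ids),
        true_cluster=pd.Series(clusters, index=samples, name="true_cluster"),
        true_deg_genes=pd.Series(deg_sign.astype(int), index=genes[deg_idx], name="sign"),
        latent_score=pd.Series(latent, index=samples, name="latent_score"),
        true_mutcount=pd.Series(nonsyn_counts, index=samples, name="true_mutcount"),
    )
    return expression, clinical, mutations, truth
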