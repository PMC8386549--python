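"""Tumor mutation burden and its interplay with the ICI score.

TMB is the raw per-sample count of nonsynonymous somatic records in a
MAF-like table (no per-megabase scaling: the count definition). Samples
are split into high/low TMB groups (median rule by default, optimal
survival cutpoint as an option), crossed with the high/low ICI-score
groups into four combined subgroups, correlated with the ICI score by
Spearman rank correlation, and compared per gene with Fisher exact tests
on mutated/unmutated 2x2 tables (BH-adjusted across genes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_adjust

__all__ = [
    "NONSYNONYMOUS_CLASSES",
    "MAF_VOCABULARY",
    "compute_tmb",
    "split_tmb",
    "combined_subgroups",
    "tmb_ici_correlation",
    "mutation_frequency_tests",
    "MutationFrequencyComparison",
]

#: Variant_Classification values counted toward TMB.
NONSYNONYMOUS_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
    }
)

#: Recognized MAF Variant_Classification vocabulary (nonsynonymous + silent).
MAF_VOCABULARY = NONSYNONYMOUS_CLASSES | {
    "Silent",
    "3'UTR",
    "5'UTR",
    "3'Flank",
    "5'Flank",
    "Intron",
    "RNA",
    "IGR",
    "Targeted_Region",
}


def compute_tmb(muts: pd.DataFrame, samples) -> pd.DataFrame:
    """Per-sample TMB = count of nonsynonymous mutation records.

    Samples absent from the table get TMB 0; records with a classification
    outside the MAF vocabulary are excluded with a warning.
    """
    samples = pd.Index(samples)
    if len(muts):
        unknown = ~muts["Variant_Classification"].isin(MAF_VOCABULARY)
        if unknown.any():
            bad = muts.loc[unknown, "Variant_Classification"].unique().tolist()
            warnings.warn(f"unknown Variant_Classification value(s) excluded: {bad[:5]}", stacklevel=2)
            muts = muts[~unknown]
        nonsyn = muts[muts["Variant_Classification"].isin(NONSYNONYMOUS_CLASSES)]
        counts = nonsyn.groupby("Tumor_Sample_Barcode").size()
    else:
        counts = pd.Series(dtype=int)
    tmb = counts.reindex(samples, fill_value=0).astype(int)
    return pd.DataFrame({"tmb": tmb}, index=samples.rename("sample_id"))


def split_tmb(
    tmb: pd.DataFrame,
    rule: str = "median",
    survival_data: pd.DataFrame | None = None,
    minprop: float = 0.1,
) -> pd.DataFrame:
    """Assign high/low TMB groups.

    ``median`` rule: high iff tmb > median. ``maxstat`` rule: split at the
    optimal survival cutpoint (requires survival data).
    """
    out = tmb.copy()
    values = out["tmb"].to_numpy(dtype=float)
    if len(np.unique(values)) < 2:
        raise ValueError("constant TMB; no split exists")
    if rule == "median":
        cut = float(np.median(values))
    elif rule == "maxstat":
        if survival_data is None:
            raise ValueError("maxstat TMB split requires survival data")
        from . import survival as surv

        sd = survival_data.set_index("sample_id") if "sample_id" in survival_data.columns else survival_data
        shared = out.index.intersection(sd.index)
        cut = surv.maxstat_cutpoint(out.loc[shared, "tmb"], sd.loc[shared], minprop=minprop).cutpoint
    else:
        raise ValueError(f"unknown TMB split rule {rule!r}")
    out["tmb_group"] = np.where(out["tmb"] > cut, "high", "low")
    out["tmb_cutpoint"] = cut
    return out


def combined_subgroups(tmb_groups: pd.Series, ici_groups: pd.Series) -> pd.Series:
    """Cross TMB and ICI-score groups into the four combined labels.

    Labels follow the H-TMB+H-ICI / H-TMB+L-ICI / L-TMB+H-ICI / L-TMB+L-ICI
    convention; samples missing either label are dropped (count logged).
    """
    shared = tmb_groups.index.intersection(ici_groups.index)
    if len(shared) == 0:
        raise ValueError("no samples carry both a TMB and an ICI-score group")
    dropped = len(tmb_groups.index.union(ici_groups.index)) - len(shared)
    if dropped:
        import logging

        logging.getLogger(__name__).info("combined_subgroups: dropped %d samples missing a label", dropped)
    t = tmb_groups.loc[shared].map({"high": "H", "low": "L"})
    i = ici_groups.loc[shared].map({"high": "H", "low": "L"})
    if t.isna().any() or i.isna().any():
        raise ValueError("group labels must be 'high'/'low'")
    out = t + "-TMB+" + i + "-ICI"
    out.name = "subgroup"
    return out


def tmb_ici_correlation(tmb_values, ici_scores) -> tuple[float, float]:
    """Spearman correlation (midrank ties, t-approximation p) of TMB vs ICI score."""
    x = np.asarray(tmb_values, dtype=float)
    y = np.asarray(ici_scores, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector; correlation undefined")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class MutationFrequencyComparison:
    """Per-gene mutation-frequency contrast between ICI-score groups."""

    table: pd.DataFrame  # per gene: counts, frequencies, fisher p, fdr
    top_genes: pd.Index  # top_k genes by overall alteration frequency
    indicator: pd.DataFrame  # samples x top genes 0/1 mutation matrix


def mutation_frequency_tests(
    muts: pd.DataFrame,
    ici_groups: pd.Series,
    top_k: int = 25,
) -> MutationFrequencyComparison:
    """Fisher exact tests of per-gene mutation frequency between ICI groups.

    For every gene mutated in at least one grouped sample, a 2x2 table of
    (mutated, unmutated) x (high, low) is tested two-sided; BH adjustment
    runs across the tested genes. Genes are ranked by overall alteration
    frequency and the ``top_k`` reported with a per-sample 0/1 indicator
    matrix for waterfall-style summaries. Duplicate gene symbols in the
    input collapse to one record per gene/sample.
    """
    groups = ici_groups.dropna()
    high = set(groups.index[groups == "high"])
    low = set(groups.index[groups == "low"])
    if not high or not low:
        raise ValueError("both ICI-score groups must be non-empty")
    grouped_samples = high | low

    relevant = muts[muts["Tumor_Sample_Barcode"].isin(grouped_samples)]
    mutated: dict[str, set[str]] = (
        relevant.groupby("Hugo_Symbol")["Tumor_Sample_Barcode"].agg(set).to_dict()
    )

    rows = []
    for gene, carriers in mutated.items():
        mh = len(carriers & high)
        ml = len(carriers & low)
        if mh + ml == 0:
            continue
        table = np.array([[mh, len(high) - mh], [ml, len(low) - ml]])
        p = stats.fisher_exact(table, alternative="two-sided")[1]
        rows.append(
            {
                "gene": gene,
                "mut_high": mh,
                "unmut_high": len(high) - mh,
                "mut_low": ml,
                "unmut_low": len(low) - ml,
                "freq_high": mh / len(high),
                "freq_low": ml / len(low),
                "freq_overall": (mh + ml) / len(grouped_samples),
                "p": float(p),
            }
        )
    if not rows:
        raise ValueError("no mutated genes among the grouped samples")
    table = pd.DataFrame(rows).set_index("gene")
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    table = table.sort_values(["freq_overall", "p"], ascending=[False, True])

    top = table.index[: top_k]
    sample_index = pd.Index(sorted(grouped_samples))
    indicator = pd.DataFrame(0, index=sample_index, columns=top, dtype=int)
    for gene in top:
        carriers = mutated[gene] & grouped_samples
        indicator.loc[sorted(carriers), gene] = 1
    return MutationFrequencyComparison(table=table, top_genes=top, indicator=indicator)
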