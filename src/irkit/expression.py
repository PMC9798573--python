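"""Expression-side screens: normalization, fold changes, cancer-type
specificity, and the IR-frequency / expression correlation scan.

Counts are normalized by median-of-ratios size factors. Cancer-type
specificity of a gene's differential expression is summarized as a z-score of
the reference condition's log2 fold change against the distribution of that
gene's fold changes across all conditions. The correlation screen relates
each gene's normalized expression to the per-sample number of IR events on a
log10 scale, ranking genes as candidate positive or negative retention
regulators.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample, rescaled to unit geometric mean.

    ``counts`` is genes x samples. Only genes with positive counts in every
    sample enter the pseudo-reference; if none exists the cohort cannot be
    normalized this way and a pseudocount strategy is suggested.
    """
    mat = counts.to_numpy(float)
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("no gene has positive counts in all samples; add a pseudocount first")
    log_mat = np.log(mat[all_pos])
    log_ref = log_mat.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(log_mat - log_ref, axis=0))
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, sf: pd.Series | None = None) -> pd.DataFrame:
    sf = size_factors(counts) if sf is None else sf
    return counts / sf


def log2_fold_change(
    counts: pd.DataFrame,
    groups: pd.Series,
    sf: pd.Series | None = None,
    case: str = "cancer",
    control: str = "normal",
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene log2((mean normalized case + c) / (mean normalized control + c))."""
    norm = normalize_counts(counts, sf)
    case_cols = groups[groups == case].index
    control_cols = groups[groups == control].index
    if len(case_cols) == 0 or len(control_cols) == 0:
        raise ValueError(f"both groups {case!r} and {control!r} must be present")
    lfc = np.log2(
        (norm[case_cols].mean(axis=1) + pseudocount)
        / (norm[control_cols].mean(axis=1) + pseudocount)
    )
    return lfc.rename("log2_fc")


def mean_count_filter(counts: pd.DataFrame, min_mean: float = 10.0) -> pd.Index:
    """Genes whose mean raw count across all samples strictly exceeds min_mean."""
    return counts.index[counts.mean(axis=1) > min_mean]


def exclusive_de_genes(de_tables: Mapping[str, set], reference: str) -> set:
    """Genes differentially expressed in the reference condition and nowhere else."""
    if reference not in de_tables:
        raise ValueError(f"reference condition {reference!r} missing from DE tables")
    others: set = set()
    for name, genes in de_tables.items():
        if name != reference:
            others |= set(genes)
    return set(de_tables[reference]) - others


def specificity_zscore(lfc: Sequence[float], reference_index: int, include_reference: bool = True) -> float:
    """z-score of the reference condition's LFC against all conditions.

    (lfc[ref] - mean) / sd with the n-1 denominator; mean and sd are taken
    over all conditions (set ``include_reference=False`` to use only the
    others). A zero sd yields z = 0 with a warning.
    """
    lfc = np.asarray(lfc, float)
    if len(lfc) < 3:
        raise ValueError("need at least 3 conditions")
    pool = lfc if include_reference else np.delete(lfc, reference_index)
    sd = float(np.std(pool, ddof=1))
    if sd == 0:
        warnings.warn("zero cross-condition sd; z-score defined as 0")
        return 0.0
    return float((lfc[reference_index] - np.mean(pool)) / sd)


def specificity_table(
    lfc_table: pd.DataFrame, reference: str, exclusive: set | None = None
) -> pd.DataFrame:
    """Per-gene specificity z-scores from a genes x conditions LFC table."""
    if reference not in lfc_table.columns:
        raise ValueError(f"reference condition {reference!r} not a column of the LFC table")
    ref_idx = list(lfc_table.columns).index(reference)
    z = lfc_table.apply(lambda row: specificity_zscore(row.to_numpy(), ref_idx), axis=1)
    out = lfc_table.copy()
    out["z"] = z
    out["exclusive"] = out.index.isin(exclusive) if exclusive is not None else False
    return out


def correlate_ir_expression(
    event_counts: pd.Series, expr: pd.DataFrame, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Pearson r between log10(IR events + 1) and log10(normalized count + 1).

    ``expr`` is genes x samples (already normalized); samples are aligned by
    label with ``event_counts``. Genes with zero variance on the transformed
    scale get r = 0 and a ``degenerate`` flag.
    """
    samples = [s for s in expr.columns if s in event_counts.index]
    if len(samples) < 3:
        raise ValueError("need at least 3 shared samples")
    x = np.log10(event_counts.loc[samples].to_numpy(float) + pseudocount)
    mat = np.log10(expr[samples].to_numpy(float) + pseudocount)
    xc = x - x.mean()
    mc = mat - mat.mean(axis=1, keepdims=True)
    row_ss = (mc**2).sum(axis=1)
    x_ss = float((xc**2).sum())
    # centring a constant row leaves ~1e-16 residue, so test variance
    # against a relative tolerance rather than exact zero
    row_scale = (mat**2).sum(axis=1) + 1.0
    degenerate = (row_ss <= 1e-18 * row_scale) | (x_ss <= 1e-18 * ((x**2).sum() + 1.0))
    denom = np.sqrt(row_ss * x_ss)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(degenerate, 0.0, (mc @ xc) / np.where(degenerate, 1.0, denom))
    return pd.DataFrame({"r": r, "degenerate": degenerate}, index=expr.index)


def top_percentile_genes(r: pd.Series, fraction: float = 0.05) -> tuple[list[str], list[str]]:
    """The ceil(fraction*n) genes with the largest and the smallest r.

    Ties are broken by gene identifier so the selection is deterministic.
    """
    if not (0 < fraction < 0.5):
        raise ValueError("fraction must lie in (0, 0.5)")
    k = math.ceil(fraction * len(r))
    ordered = sorted(r.items(), key=lambda kv: (-kv[1], kv[0]))
    top = [g for g, _ in ordered[:k]]
    ordered_low = sorted(r.items(), key=lambda kv: (kv[1], kv[0]))
    bottom = [g for g, _ in ordered_low[:k]]
    return top, bottom
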