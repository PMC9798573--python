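"""Cohort-level intron filtering and per-sample IR event counting.

An intron is eligible for event counting only if, across the cohort:

1. its junction reads are balanced (0.7 <= SL/SR <= 1.3) in at least half of
   the samples — a proxy for constitutive flanking exons;
2. junction support is adequate, (SL+SR) > 10, in at least half of the
   samples — poorly expressed flanks produce false retention calls;
3. intronic coverage exceeds 0.5 in at least half of the samples;
4. its IR ratio exceeds 0.05 in at least half of the samples of at least one
   group — a 5% inclusion rate is taken as the floor of biological relevance.

An IR *event* is then a filtered intron with IR ratio > 0.1 in a given
sample. Comparison boundaries follow the rules exactly: the 50% sample
fractions are inclusive, the >10 / >0.5 / >0.05 / >0.1 cut-offs strict, and
the balance window inclusive at both ends.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .quantify import SampleQuant

MASK_COLUMNS = ["pass_balance", "pass_junction_support", "pass_coverage", "pass_ir_floor", "pass_all"]


@dataclass
class FilterParams:
    balance_low: float = 0.7
    balance_high: float = 1.3
    min_junction: float = 10.0       # (SL+SR) must exceed this (strict)
    min_coverage: float = 0.5        # coverage must exceed this (strict)
    ir_floor: float = 0.05           # ir_ratio must exceed this (strict)
    sample_fraction: float = 0.5     # "in >= 50% of samples" (inclusive)
    floor_groups: tuple[str, ...] | None = None  # groups eligible for rule 4; None = all


class CohortMatrix:
    """Introns x samples grids of every metric plus per-sample group labels."""

    def __init__(self, metric_frames: dict[str, pd.DataFrame], groups: pd.Series):
        self.ID = metric_frames["ID"]
        self.coverage = metric_frames["coverage"]
        self.SL = metric_frames["SL"]
        self.SR = metric_frames["SR"]
        self.SE = metric_frames["SE"]
        self.ir_ratio = metric_frames["ir_ratio"]
        self.groups = groups.loc[self.ID.columns]
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ValueError(f"samples without group label: {missing}")

    @property
    def intron_ids(self) -> pd.Index:
        return self.ID.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.ID.columns

    @classmethod
    def from_quants(cls, quants: Sequence[SampleQuant], groups: pd.Series) -> "CohortMatrix":
        """Assemble a cohort from per-sample quantifications.

        Introns missing from a sample are encoded as all-zero metrics.
        """
        if not quants:
            raise ValueError("need at least one sample")
        all_introns = quants[0].metrics.index
        for q in quants[1:]:
            all_introns = all_introns.union(q.metrics.index)
        frames = {}
        for col in ("ID", "coverage", "SL", "SR", "SE", "ir_ratio"):
            frames[col] = pd.DataFrame(
                {q.sample_id: q.metrics[col].reindex(all_introns, fill_value=0) for q in quants}
            )
        return cls(frames, groups)


def splice_balance(SL: float, SR: float, low: float = 0.7, high: float = 1.3) -> bool:
    """True iff SR > 0 and low <= SL/SR <= high (both bounds inclusive)."""
    if SR <= 0:
        return False
    return low <= SL / SR <= high


def apply_cohort_filters(cohort: CohortMatrix, params: FilterParams | None = None) -> pd.DataFrame:
    """Compute the four-filter mask per intron; returns a boolean DataFrame."""
    p = params or FilterParams()
    n = len(cohort.sample_ids)
    need = p.sample_fraction * n

    SL, SR = cohort.SL.to_numpy(float), cohort.SR.to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(SR > 0, SL / np.where(SR > 0, SR, 1.0), np.nan)
    ok_balance = (SR > 0) & (ratio >= p.balance_low) & (ratio <= p.balance_high)
    pass_balance = ok_balance.sum(axis=1) >= need

    pass_junction = ((SL + SR > p.min_junction).sum(axis=1)) >= need
    pass_coverage = ((cohort.coverage.to_numpy(float) > p.min_coverage).sum(axis=1)) >= need

    groups = p.floor_groups if p.floor_groups is not None else tuple(pd.unique(cohort.groups))
    present = set(cohort.groups)
    missing = [g for g in groups if g not in present]
    if missing:
        raise ValueError(f"IR-floor rule references absent group(s): {missing}")
    ir = cohort.ir_ratio.to_numpy(float)
    pass_floor = np.zeros(ir.shape[0], dtype=bool)
    for g in groups:
        cols = (cohort.groups == g).to_numpy()
        need_g = p.sample_fraction * cols.sum()
        pass_floor |= (ir[:, cols] > p.ir_floor).sum(axis=1) >= need_g

    mask = pd.DataFrame(
        {
            "pass_balance": pass_balance,
            "pass_junction_support": pass_junction,
            "pass_coverage": pass_coverage,
            "pass_ir_floor": pass_floor,
        },
        index=cohort.intron_ids,
    )
    mask["pass_all"] = mask.all(axis=1)
    return mask


def count_ir_events(
    cohort: CohortMatrix, mask: pd.DataFrame, threshold: float = 0.1
) -> pd.Series:
    """Per-sample count of filtered introns with ir_ratio strictly above threshold."""
    passing = mask["pass_all"]
    ir = cohort.ir_ratio.loc[passing[passing].index]
    return (ir > threshold).sum(axis=0).rename("n_ir_events")


def sample_qc(quants: Sequence[SampleQuant], min_reads: int = 40_000_000) -> list[str]:
    """Sample IDs with at least ``min_reads`` aligned reads (depth QC)."""
    return [q.sample_id for q in quants if q.total_aligned_reads >= min_reads]
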