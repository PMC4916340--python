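"""Relative qPCR quantification by the delta-delta-Ct method.

Expression of a target gene is normalised against a reference gene
(GAPDH by convention in peach) within each sample, then compared
between treatment and control:

    dCt   = Ct_gene - Ct_reference          (per biological replicate,
                                             technical replicates
                                             averaged first)
    ddCt  = mean dCt_treatment - mean dCt_control
    fold  = 2^(-ddCt)

assuming an amplification efficiency of 2 (doubling per cycle).  The
module also measures directional concordance between qPCR fold changes
and sequencing log2 ratios, the standard validation of tag-profiling
calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "CT_COLUMNS",
    "FoldChangeRecord",
    "ddct_fold_change",
    "ddct_table",
    "concordance",
    "read_ct_csv",
]

CT_COLUMNS = ("gene", "group", "bio_rep", "tech_rep", "ct")
CONTROL, TREATMENT = "control", "treatment"


@dataclass(frozen=True)
class FoldChangeRecord:
    gene: str
    mean_dct_control: float
    mean_dct_treatment: float
    ddct: float
    fold_change: float
    log2_fold: float
    agreement: Optional[bool] = None  # sign agreement vs sequencing ratio


def _validate(table: pd.DataFrame, reference: str) -> None:
    missing = set(CT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"Ct table is missing columns: {sorted(missing)}")
    for group in (CONTROL, TREATMENT):
        sub = table[table["group"] == group]
        if sub.empty:
            raise ValueError(f"no rows for group {group!r}")
        if not (sub["gene"] == reference).any():
            raise ValueError(f"reference gene {reference!r} absent from {group!r}")


def _mean_dct(table: pd.DataFrame, gene: str, reference: str, group: str) -> float:
    """Mean dCt over biological replicates; technical replicates are
    averaged within each biological replicate first."""
    sub = table[table["group"] == group]
    gene_ct = sub[sub["gene"] == gene].groupby("bio_rep")["ct"].mean()
    ref_ct = sub[sub["gene"] == reference].groupby("bio_rep")["ct"].mean()
    dct = (gene_ct - ref_ct).dropna()
    if dct.empty:
        raise ValueError(
            f"gene {gene!r} and reference {reference!r} share no "
            f"biological replicate in group {group!r}"
        )
    return float(dct.mean())


def ddct_fold_change(
    table: pd.DataFrame,
    gene: str,
    reference: str = "GAPDH",
    sequencing_log2_ratio: Optional[float] = None,
) -> FoldChangeRecord:
    """Fold change of one gene (treatment vs control) by delta-delta-Ct."""
    _validate(table, reference)
    dct_c = _mean_dct(table, gene, reference, CONTROL)
    dct_t = _mean_dct(table, gene, reference, TREATMENT)
    ddct = dct_t - dct_c
    fold = float(2.0 ** (-ddct))
    agreement = None
    if sequencing_log2_ratio is not None:
        agreement = np.sign(-ddct) == np.sign(sequencing_log2_ratio)
    return FoldChangeRecord(
        gene=gene,
        mean_dct_control=dct_c,
        mean_dct_treatment=dct_t,
        ddct=ddct,
        fold_change=fold,
        log2_fold=-ddct,
        agreement=agreement,
    )


def ddct_table(
    table: pd.DataFrame,
    reference: str = "GAPDH",
    sequencing_log2_ratios: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """delta-delta-Ct fold changes for every non-reference gene."""
    genes = sorted(g for g in table["gene"].unique() if g != reference)
    records = []
    for gene in genes:
        seq_ratio = (
            sequencing_log2_ratios.get(gene)
            if sequencing_log2_ratios is not None
            else None
        )
        records.append(
            ddct_fold_change(table, gene, reference, seq_ratio).__dict__
        )
    return pd.DataFrame(records)


def concordance(
    fold_changes: Mapping[str, float], sequencing_log2_ratios: Mapping[str, float]
) -> float:
    """Fraction of shared genes whose qPCR fold-change direction matches
    the sequencing log2 ratio; genes with a zero sequencing ratio are
    excluded from the denominator."""
    shared = [
        g
        for g in fold_changes
        if g in sequencing_log2_ratios and sequencing_log2_ratios[g] != 0
    ]
    if not shared:
        raise ValueError("no shared genes with nonzero sequencing ratio")
    agree = sum(
        1
        for g in shared
        if np.sign(np.log2(fold_changes[g])) == np.sign(sequencing_log2_ratios[g])
    )
    return agree / len(shared)


def read_ct_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _cols = [c for c in CT_COLUMNS if c in df.columns]
    if len(_cols) != len(CT_COLUMNS):
        raise ValueError(f"Ct CSV must have columns {CT_COLUMNS}")
    return df
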