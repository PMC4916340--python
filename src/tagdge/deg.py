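"""Differential expression between two tag libraries.

The significance model is the Audic-Claverie exact test for count data:
given that a gene produced ``x`` tags in a library of ``N1`` clean tags,
the probability of observing ``y`` tags in a second library of ``N2``
clean tags under equal expression is

    P(y|x) = (N2/N1)^y * (x+y)! / (x! y!) * (1 + N2/N1)^-(x+y+1)

which is the negative-binomial distribution with ``x+1`` successes and
success probability ``N1/(N1+N2)``; tail sums therefore come from the
negative-binomial CDF while the point probability is evaluated in log
space with log-gamma.  Counts are normalised to TPM (tags per million
clean tags); genes below a TPM floor in both libraries are excluded
before testing, zero counts are replaced by a default of one tag (so
ratios are finite), and p-values are Bonferroni-adjusted over the genes
actually tested.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import nbinom

__all__ = [
    "tpm_normalize",
    "audic_claverie_point",
    "audic_claverie_pvalue",
    "bonferroni_adjust",
    "bh_adjust",
    "call_degs",
    "categorize_degs",
]


def tpm_normalize(count, total_clean: int):
    """Tags per million clean tags: count / total * 1e6."""
    if total_clean <= 0:
        raise ValueError("total_clean must be positive")
    count = np.asarray(count, dtype=float)
    if np.any(count < 0):
        raise ValueError("counts must be non-negative")
    result = count / total_clean * 1e6
    return float(result) if result.ndim == 0 else result


def _validate_counts(x, y, n1: float, n2: float) -> None:
    if np.any(np.asarray(x) < 0) or np.any(np.asarray(y) < 0):
        raise ValueError("tag counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")


def audic_claverie_point(x, y, n1: float, n2: float):
    """P(y|x): probability of y tags in library 2 given x in library 1,
    under equal expression.  Evaluated in log space."""
    _validate_counts(x, y, n1, n2)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    log_ratio = np.log(n2) - np.log(n1)
    logp = (
        y * log_ratio
        + gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        - (x + y + 1) * np.log1p(n2 / n1)
    )
    result = np.exp(logp)
    return float(result) if result.ndim == 0 else result


def audic_claverie_pvalue(
    x, y, n1: float, n2: float, alternative: str = "two_sided"
):
    """Tail p-value of the equal-expression model.

    ``greater`` is the upper tail sum_{k>=y} P(k|x), computed as
    1 - sum_{k<y} via the CDF; ``less`` is the lower tail
    sum_{k<=y} P(k|x).  ``two_sided`` doubles the smaller tail and caps
    at 1, using the conditional form of the same model: given the total
    x + y, the count x is Binomial(x+y, N1/(N1+N2)), whose tails equal
    the corresponding tag-count tails (sum_{k>=y} P(k|x) is exactly
    P(Bin <= x)) and make the two-sided p exactly invariant under
    swapping the libraries, (x, y, N1, N2) -> (y, x, N2, N1).
    """
    _validate_counts(x, y, n1, n2)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    p_success = n1 / (n1 + n2)  # y | x ~ NB(x+1, N1/(N1+N2))
    if alternative == "two_sided":
        from scipy.stats import binom

        n = x + y
        result = np.minimum(
            1.0,
            2.0
            * np.minimum(
                binom.cdf(x, n, p_success), binom.sf(x - 1, n, p_success)
            ),
        )
    elif alternative == "greater":
        result = nbinom.sf(y - 1, x + 1, p_success)
    elif alternative == "less":
        result = nbinom.cdf(y, x + 1, p_success)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    result = np.asarray(result)
    return float(result) if result.ndim == 0 else result


def bonferroni_adjust(p_values, m: Optional[int] = None):
    """Multiply each p-value by the family size m (default: vector
    length), cap at 1; input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be at least the number of tests")
    return np.minimum(1.0, p * m)


def bh_adjust(p_values):
    """Benjamini-Hochberg step-up adjusted p-values, order preserved."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(1.0, ranked)
    return out


CountsLike = Union[Mapping[str, int], pd.DataFrame, pd.Series]


def _as_count_series(counts: CountsLike) -> pd.Series:
    if isinstance(counts, pd.DataFrame):
        return counts.set_index("gene_id")["count"].astype(int)
    return pd.Series(counts, dtype=int)


def call_degs(
    counts1: CountsLike,
    counts2: CountsLike,
    n1: int,
    n2: int,
    tpm_floor: float = 10.0,
    fdr_threshold: float = 0.001,
    lfc_threshold: float = 1.0,
    zero_default: int = 1,
    adjust: str = "bonferroni",
    alternative: str = "two_sided",
) -> pd.DataFrame:
    """Call differentially expressed genes between two libraries.

    Genes below ``tpm_floor`` TPM in both libraries are excluded before
    testing; zero counts are replaced by ``zero_default`` for both the
    log2 ratio and the test input; the adjustment family size is the
    number of genes actually tested.  A gene is called up/down when its
    adjusted p-value is below ``fdr_threshold`` and |log2 ratio| is at
    least ``lfc_threshold``; the sign follows the TPM ratio library 2 /
    library 1.

    Returns one row per gene: counts, TPMs, log2_ratio, p_raw, p_adj
    (labelled FDR in written outputs) and the call.
    """
    s1 = _as_count_series(counts1)
    s2 = _as_count_series(counts2)
    genes = sorted(set(s1.index) | set(s2.index))
    if not genes:
        return pd.DataFrame(
            columns=[
                "gene_id", "x", "y", "tpm1", "tpm2",
                "log2_ratio", "p_raw", "p_adj", "call",
            ]
        )
    x = s1.reindex(genes, fill_value=0).to_numpy(dtype=int)
    y = s2.reindex(genes, fill_value=0).to_numpy(dtype=int)

    tpm1 = tpm_normalize(x, n1)
    tpm2 = tpm_normalize(y, n2)
    excluded = (tpm1 < tpm_floor) & (tpm2 < tpm_floor)

    x_eff = np.maximum(x, zero_default)
    y_eff = np.maximum(y, zero_default)
    log2_ratio = np.log2(tpm_normalize(y_eff, n2) / tpm_normalize(x_eff, n1))

    tested = ~excluded
    m = int(tested.sum())
    p_raw = np.full(len(genes), np.nan)
    p_adj = np.full(len(genes), np.nan)
    if m:
        p = audic_claverie_pvalue(
            x_eff[tested], y_eff[tested], n1, n2, alternative=alternative
        )
        p_raw[tested] = p
        if adjust == "bonferroni":
            p_adj[tested] = bonferroni_adjust(p, m)
        elif adjust == "bh":
            p_adj[tested] = bh_adjust(p)
        else:
            raise ValueError(f"unknown adjust method {adjust!r}")

    call = np.where(
        excluded,
        "excluded",
        np.where(
            tested
            & (p_adj < fdr_threshold)
            & (np.abs(log2_ratio) >= lfc_threshold),
            np.where(log2_ratio > 0, "up", "down"),
            "not_significant",
        ),
    )
    return pd.DataFrame(
        {
            "gene_id": genes,
            "x": x,
            "y": y,
            "tpm1": tpm1,
            "tpm2": tpm2,
            "log2_ratio": log2_ratio,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "call": call,
        }
    )


def categorize_degs(
    deg_table: pd.DataFrame, mapping: Mapping[str, str]
) -> pd.DataFrame:
    """Tabulate up/down DEG counts over a gene -> functional-category
    mapping; percentages are over categorised DEGs, to 1 decimal.
    Unmapped DEGs appear in an ``unassigned`` row with no percentage."""
    degs = deg_table[deg_table["call"].isin(["up", "down"])]
    if degs.empty:
        return pd.DataFrame(columns=["category", "n_degs", "pct", "n_up", "n_down"])
    cat = degs["gene_id"].map(lambda g: mapping.get(g))
    assigned = degs[cat.notna()].assign(category=cat.dropna())
    n_assigned = len(assigned)
    rows = []
    for label, grp in assigned.groupby("category", sort=True):
        rows.append(
            {
                "category": label,
                "n_degs": len(grp),
                "pct": round(100.0 * len(grp) / n_assigned, 1),
                "n_up": int((grp["call"] == "up").sum()),
                "n_down": int((grp["call"] == "down").sum()),
            }
        )
    n_unassigned = len(degs) - n_assigned
    if n_unassigned:
        unmapped = degs[cat.isna()]
        rows.append(
            {
                "category": "unassigned",
                "n_degs": n_unassigned,
                "pct": np.nan,
                "n_up": int((unmapped["call"] == "up").sum()),
                "n_down": int((unmapped["call"] == "down").sum()),
            }
        )
    return pd.DataFrame(rows)
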