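"""Tissue-specificity (tau) profiling.

For a gene g with tissue-mean expression x_{g,t} over T tissues,

    tau_g = sum_t (1 - xhat_{g,t}) / (T - 1),   xhat_{g,t} = x_{g,t} / max_t x_{g,t}

tau ranges from 0 (uniform expression) to 1 (expression in exactly one
tissue). A gene is called tissue-specific for tau >= 0.95 and is assigned
to its Top1 (highest-expression) tissue; the Top1/Top2 fold change and the
Top1-TPM expression tier (< 1 vs >= 1) are reported alongside.

tau is computed on raw tissue-mean TPM. ``log_transform`` switches the
input to log2(TPM+1) and ``zero_below`` zeroes sub-threshold entries, for
compatibility with variants used in the tissue-specificity literature.
All-zero genes have no defined maximum and are excluded (tau undefined),
not assigned tau = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas import ExpressionMatrix, EXPRESSED_TPM

TAU_SPECIFIC = 0.95
TIER_TPM = 1.0


def tau(x: Sequence[float]) -> float:
    """Tau of one expression vector; NaN (undefined) for an all-zero vector."""
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("tau needs a vector over >= 2 tissues")
    if (arr < 0).any():
        raise ValueError("negative expression value")
    mx = arr.max()
    if mx == 0:
        return float("nan")
    return float((1.0 - arr / mx).sum() / (arr.size - 1))


def tau_matrix(values: pd.DataFrame, log_transform: bool = False,
               zero_below: float | None = None) -> pd.Series:
    """Vectorized tau per row of a gene x tissue table."""
    x = values.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("negative expression value")
    if x.shape[1] < 2:
        raise ValueError("tau needs >= 2 tissues")
    if zero_below is not None:
        x = np.where(x < zero_below, 0.0, x)
    if log_transform:
        x = np.log2(x + 1.0)
    mx = x.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        xhat = x / mx[:, None]
    t = (1.0 - xhat).sum(axis=1) / (x.shape[1] - 1)
    t = np.where(mx == 0, np.nan, t)
    return pd.Series(t, index=values.index, name="tau")


@dataclass
class TauResult:
    gene_id: str
    tau: float  # NaN when undefined (all-zero profile)
    top1_tissue: str
    top1_tpm: float
    top2_tissue: str
    top2_tpm: float
    fold_change: float  # top1/top2; NaN when top2 == 0
    n_tissues_expressed: int
    tissue_specific: bool
    expression_tier: str  # "lt1" | "ge1" by top1_tpm
    top1_tie: bool = False


def top_tissues(
    x: Sequence[float], labels: Sequence[str]
) -> tuple[str, float, str, float, float, bool]:
    """Top1/Top2 tissues and the Top1/Top2 fold change.

    Ties are broken by tissue-label input order; the returned flag marks a
    Top1 tie. Fold change is NaN when Top2 is zero.
    """
    arr = np.asarray(x, dtype=float)
    if arr.size < 2 or arr.size != len(labels):
        raise ValueError("need >= 2 tissues and matching labels")
    order = np.argsort(-arr, kind="stable")  # stable: label order breaks ties
    i1, i2 = int(order[0]), int(order[1])
    fold = arr[i1] / arr[i2] if arr[i2] > 0 else float("nan")
    tie = bool(np.sum(arr == arr[i1]) > 1)
    return labels[i1], float(arr[i1]), labels[i2], float(arr[i2]), float(fold), tie


def specificity_table(
    m: ExpressionMatrix,
    tau_threshold: float = TAU_SPECIFIC,
    expr_threshold: float = EXPRESSED_TPM,
    tier_threshold: float = TIER_TPM,
    log_transform: bool = False,
    zero_below: float | None = None,
) -> pd.DataFrame:
    """Per-gene tau/Top1/Top2 table for genes expressed in >= 1 tissue.

    Columns: tau, top1_tissue, top1_tpm, top2_tissue, top2_tpm, fold_change,
    n_tissues_expressed, tissue_specific, expression_tier, top1_tie.
    """
    taus = tau_matrix(m.values, log_transform=log_transform, zero_below=zero_below)
    rows = []
    for gene_id in m.genes:
        x = m.values.loc[gene_id].to_numpy(dtype=float)
        n_expr = int((x >= expr_threshold).sum())
        if n_expr == 0:
            continue
        t1, v1, t2, v2, fold, tie = top_tissues(x, m.tissues)
        tg = float(taus.loc[gene_id])
        rows.append(
            {
                "gene_id": gene_id,
                "tau": tg,
                "top1_tissue": t1,
                "top1_tpm": v1,
                "top2_tissue": t2,
                "top2_tpm": v2,
                "fold_change": fold,
                "n_tissues_expressed": n_expr,
                "tissue_specific": bool(not math.isnan(tg) and tg >= tau_threshold),
                "expression_tier": "ge1" if v1 >= tier_threshold else "lt1",
                "top1_tie": tie,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def specific_counts_by_tissue(table: pd.DataFrame) -> pd.Series:
    """Tissue-specific gene counts per Top1 tissue."""
    spec = table[table["tissue_specific"]]
    return spec.groupby("top1_tissue").size().sort_index()


def intersect_specific(
    table_a: pd.DataFrame, table_b: pd.DataFrame, tissue: str
) -> set[str]:
    """Genes tissue-specific for the same Top1 tissue in two datasets."""
    a = set(table_a[(table_a["tissue_specific"]) & (table_a["top1_tissue"] == tissue)].index)
    b = set(table_b[(table_b["tissue_specific"]) & (table_b["top1_tissue"] == tissue)].index)
    return a & b
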