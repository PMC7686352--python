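"""Pairwise Spearman co-expression across tissues, Benjamini-Hochberg FDR
control, and configuration/distance enrichment statistics.

Each classified LNC:PCG pair (or PCG:PCG pair) expressed in at least one
tissue contributes one Spearman test over the tissue-mean profiles; raw
p-values are BH-adjusted within one family per pair kind and a pair is
significant when p_fdr < the FDR level (0.05 by default). Enrichment of
significantly correlated pairs in one genomic configuration versus a
reference configuration (convergent) — and of close (<=5 kb) versus distant
(>5 kb) pairs within a configuration — is scored with one-sided Fisher
exact tests; distance distributions are compared with two-sided
Mann-Whitney tests.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .atlas import ExpressionMatrix, EXPRESSED_TPM

logger = logging.getLogger(__name__)

FDR_LEVEL = 0.05
HOST_RHO_MIN = 0.8
HOST_FDR_LEVEL = 0.01
EXACT_PERMUTATION_MAX_N = 9  # exact permutation p below this; t-approximation above


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho (average ranks) with a two-sided p-value.

    p is a t-approximation for n >= 10 and an exact full-permutation p for
    smaller n. A constant vector makes rho undefined: returns (NaN, 1.0)
    with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    n = x.size
    if n < 4:
        raise ValueError("need n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant vector in Spearman correlation; rho undefined")
        return float("nan"), 1.0
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n > EXACT_PERMUTATION_MAX_N:
        p = float(stats.spearmanr(x, y).pvalue)
    else:
        # exact: enumerate all n! pairings of the observed ranks
        target = abs(rho) - 1e-12
        hits = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            hits += abs(r) >= target
            total += 1
        p = hits / total
    return rho, float(min(p, 1.0))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order kept."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class CorrelationResult:
    lnc_gene_id: str
    partner_id: str
    pair_kind: str  # "LNC:PCG" | "PCG:PCG" | "hostLNC:PCG"
    rho: float
    p: float
    p_fdr: float = float("nan")
    significant: bool = False
    n_tissues_used: int = 0


def pair_correlations(
    pairs: pd.DataFrame,
    m: ExpressionMatrix,
    fdr_level: float = FDR_LEVEL,
    pair_kind: str = "LNC:PCG",
    expr_threshold: float = EXPRESSED_TPM,
    id_cols: tuple[str, str] = ("lnc_gene_id", "pcg_gene_id"),
) -> pd.DataFrame:
    """Spearman test per expressed pair, BH over the family.

    ``pairs`` needs the two id columns; pairs with a member missing from the
    matrix are skipped with a warning, pairs with a member not expressed
    (max TPM < threshold) are excluded from the family. Constant-profile
    pairs stay in the family as not-significant (rho NaN, p = 1).
    """
    a_col, b_col = id_cols
    rows = []
    maxes = m.values.max(axis=1)
    for rec in pairs.itertuples(index=False):
        a = getattr(rec, a_col)
        b = getattr(rec, b_col)
        if b is None or (isinstance(b, float) and math.isnan(b)):
            continue
        if a not in m.values.index or b not in m.values.index:
            logger.warning("pair (%s, %s): member absent from matrix, skipped", a, b)
            continue
        if maxes[a] < expr_threshold or maxes[b] < expr_threshold:
            continue
        rho, p = spearman(m.values.loc[a], m.values.loc[b])
        rows.append(
            CorrelationResult(a, b, pair_kind, rho, p, n_tissues_used=len(m.tissues))
        )
    if not rows:
        return pd.DataFrame(
            columns=["lnc_gene_id", "partner_id", "pair_kind", "rho", "p",
                     "p_fdr", "significant", "n_tissues_used"]
        )
    padj = bh_adjust([r.p for r in rows])
    for r, q in zip(rows, padj):
        r.p_fdr = float(q)
        r.significant = bool(q < fdr_level)
    return pd.DataFrame([vars(r) for r in rows])


@dataclass
class EnrichmentResult:
    label: str
    table: tuple[tuple[int, int], tuple[int, int]]  # rows: (test, ref) x (sig, not)
    odds_ratio: float
    p: float
    stars: str
    testable: bool = True


def _stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def _fisher_greater(table, alternative: str = "greater") -> tuple[float, float]:
    odds, p = stats.fisher_exact(table, alternative=alternative)
    return float(odds), float(p)


def configuration_enrichment(
    results: pd.DataFrame,
    reference: str = "convergent",
    direction_col: str = "direction",
    alternative: str = "greater",
) -> list[EnrichmentResult]:
    """Enrichment of significant pairs per configuration vs the reference.

    For each configuration X != reference, a 2x2 table {X, reference} x
    {significant, not} scored with a one-sided (greater) Fisher exact test.
    Star codes: * <= 0.05, ** <= 0.01, *** <= 0.001.
    """
    ref = results[results[direction_col] == reference]
    if ref.empty:
        raise ValueError(f"reference configuration {reference!r} is empty")
    ref_sig = int(ref["significant"].sum())
    ref_not = int(len(ref) - ref_sig)
    out = []
    for config, sub in results.groupby(direction_col):
        if config == reference:
            continue
        if sub.empty:
            out.append(
                EnrichmentResult(f"{config} vs {reference}", ((0, 0), (ref_sig, ref_not)),
                                 float("nan"), float("nan"), "", testable=False)
            )
            continue
        sig = int(sub["significant"].sum())
        table = ((sig, int(len(sub) - sig)), (ref_sig, ref_not))
        odds, p = _fisher_greater(table, alternative)
        out.append(EnrichmentResult(f"{config} vs {reference}", table, odds, p, _stars(p)))
    return out


def distance_enrichment(
    results: pd.DataFrame,
    close_classes: tuple[str, ...] = ("<=1kb", "<=5kb"),
    distance_col: str = "distance_class",
    alternative: str = "greater",
) -> EnrichmentResult:
    """Enrichment of significant pairs at <= 5 kb vs > 5 kb.

    2x2 table {close, distant} x {significant, not}, one-sided Fisher.
    Flagged not-testable when either distance class is empty.
    """
    close = results[results[distance_col].isin(close_classes)]
    far = results[~results[distance_col].isin(close_classes)]
    if close.empty or far.empty:
        return EnrichmentResult("<=5kb vs >5kb", ((0, 0), (0, 0)),
                                float("nan"), float("nan"), "", testable=False)
    c_sig = int(close["significant"].sum())
    f_sig = int(far["significant"].sum())
    table = ((c_sig, len(close) - c_sig), (f_sig, len(far) - f_sig))
    odds, p = _fisher_greater(table, alternative)
    return EnrichmentResult("<=5kb vs >5kb", table, odds, p, _stars(p))


def distance_comparison(
    dist_a: Sequence[float], dist_b: Sequence[float]
) -> dict:
    """Two-sided Mann-Whitney comparison of two distance distributions.

    Exact for small tie-free samples (scipy's default), normal approximation
    with tie correction otherwise. Medians reported alongside.
    """
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    small = a.size <= 20 and b.size <= 20
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {
        "p": float(res.pvalue),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "u_statistic": float(res.statistic),
    }


def host_lnc_screen(
    hosts: pd.DataFrame,
    m: ExpressionMatrix,
    pcg_ids: Sequence[str],
    rho_min: float = HOST_RHO_MIN,
    fdr_level: float = HOST_FDR_LEVEL,
    expr_threshold: float = EXPRESSED_TPM,
) -> pd.DataFrame:
    """Correlated PCG per small-RNA-hosting LNC.

    For each expressed host LNC, Spearman against every expressed PCG with
    BH adjustment within that host's family; partners are kept when
    |rho| >= rho_min and p_fdr <= fdr_level, with the sign recorded.
    """
    maxes = m.values.max(axis=1)
    expressed_pcgs = [
        p for p in pcg_ids if p in m.values.index and maxes[p] >= expr_threshold
    ]
    out_rows = []
    for host in sorted(set(hosts["host_lnc_id"])):
        if host not in m.values.index or maxes[host] < expr_threshold:
            continue
        fam = []
        for pcg in expressed_pcgs:
            rho, p = spearman(m.values.loc[host], m.values.loc[pcg])
            fam.append((pcg, rho, p))
        if not fam:
            continue
        padj = bh_adjust([f[2] for f in fam])
        for (pcg, rho, p), q in zip(fam, padj):
            if not math.isnan(rho) and abs(rho) >= rho_min and q <= fdr_level:
                out_rows.append(
                    {
                        "host_lnc_id": host,
                        "pcg_gene_id": pcg,
                        "rho": rho,
                        "p": p,
                        "p_fdr": float(q),
                        "sign": "positive" if rho > 0 else "negative",
                    }
                )
    return pd.DataFrame(
        out_rows,
        columns=["host_lnc_id", "pcg_gene_id", "rho", "p", "p_fdr", "sign"],
    )
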