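"""Expression-matrix construction, expression filters, background-noise
locus shuffling, tissue clustering and per-chromosome gene density.

Expression enters as RSEM-style gene x sample TPM tables plus a
sample -> tissue map; tissue profiles are replicate means. A companion
gene x sample expected-read-count table drives the model-retention filter
(a model must be supported by at least ``min_reads`` reads in the samples
of some tissue, on top of the TPM floor).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .annotation import Catalogue, ChromTable, GenomicInterval

logger = logging.getLogger(__name__)

EXPRESSED_TPM = 0.1  # expressed in a tissue iff TPM >= 0.1
RETENTION_MIN_READS = 5

RETENTION_MODES = ("all_samples", "any_sample", "tissue_sum")


@dataclass
class ExpressionMatrix:
    """Gene x tissue TPM (replicate means) with its sample -> tissue map."""

    values: pd.DataFrame  # genes x tissues
    sample_map: dict[str, str] = field(default_factory=dict)

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def profile(self, gene_id: str) -> pd.Series:
        return self.values.loc[gene_id]


def build_matrix(
    sample_tpm: pd.DataFrame,
    sample_map: Mapping[str, str],
    agg: str = "mean",
) -> ExpressionMatrix:
    """Collapse a gene x sample TPM table to gene x tissue replicate means.

    ``agg`` may be "mean" (default) or "median". Every sample column must be
    mapped to a tissue; NaNs (genes absent from one sample) are refused.
    """
    if agg not in ("mean", "median"):
        raise ValueError("agg must be 'mean' or 'median'")
    unmapped = [s for s in sample_tpm.columns if s not in sample_map]
    if unmapped:
        raise ValueError(f"unmapped samples: {unmapped}")
    if sample_tpm.isna().any().any():
        raise ValueError("ragged input: missing values in sample TPM table")
    if (sample_tpm.values < 0).any():
        raise ValueError("negative TPM values")
    tissues = pd.Series({s: sample_map[s] for s in sample_tpm.columns})
    grouped = sample_tpm.T.groupby(tissues)
    values = (grouped.mean() if agg == "mean" else grouped.median()).T
    # keep tissue order = first appearance in the sample table
    order = list(dict.fromkeys(tissues))
    return ExpressionMatrix(values[order], dict(sample_map))


def expressed_genes(m: ExpressionMatrix, threshold: float = EXPRESSED_TPM) -> pd.DataFrame:
    """Per-gene expressed flag (max tissue TPM >= threshold) and tissue count."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    ge = m.values.ge(threshold)
    return pd.DataFrame(
        {"expressed": ge.any(axis=1), "n_tissues": ge.sum(axis=1)}, index=m.values.index
    )


def retention_filter(
    models: Sequence[str],
    read_counts: pd.DataFrame,
    sample_map: Mapping[str, str],
    tpm: ExpressionMatrix,
    min_tpm: float = EXPRESSED_TPM,
    min_reads: int = RETENTION_MIN_READS,
    mode: str = "all_samples",
) -> list[str]:
    """Keep models expressed (>= min_tpm in some tissue) and read-supported.

    Read support, per tissue, under ``mode``:

    * "all_samples" (default): every sample of the tissue has >= min_reads;
    * "any_sample": some sample of the tissue has >= min_reads;
    * "tissue_sum": the tissue's summed counts reach min_reads.

    A model is retained iff some tissue supports it.
    """
    if mode not in RETENTION_MODES:
        raise ValueError(f"mode must be one of {RETENTION_MODES}")
    tissues = pd.Series({s: sample_map[s] for s in read_counts.columns})
    grouped = read_counts.T.groupby(tissues)
    if mode == "all_samples":
        support = grouped.min().T.ge(min_reads).any(axis=1)
    elif mode == "any_sample":
        support = grouped.max().T.ge(min_reads).any(axis=1)
    else:
        support = grouped.sum().T.ge(min_reads).any(axis=1)
    expr = expressed_genes(tpm, min_tpm)["expressed"]
    return [
        g
        for g in models
        if bool(expr.get(g, False)) and bool(support.get(g, False))
    ]


def shuffle_noise_loci(
    lnc_lengths: Sequence[int],
    transcribed: Sequence[GenomicInterval],
    chroms: ChromTable,
    min_gap: int = 5_000,
    seed: int | None = None,
    max_tries: int = 10_000,
) -> list[GenomicInterval]:
    """Length-matched random background loci away from transcription.

    Each input length is placed uniformly at random on one of the given
    chromosomes (area-weighted by chromosome length), rejecting positions
    closer than ``min_gap`` bp to any transcribed interval or outside the
    chromosome. Reproducible for a fixed seed; an unplaceable length raises
    after ``max_tries`` rejections.
    """
    rng = np.random.default_rng(seed)
    chrom_names = list(chroms.lengths)
    weights = np.array([chroms.lengths[c] for c in chrom_names], dtype=float)
    weights /= weights.sum()
    # forbidden zones: transcribed intervals padded by min_gap
    forbidden: dict[str, list[tuple[int, int]]] = {}
    for iv in transcribed:
        forbidden.setdefault(iv.chrom, []).append(
            (iv.start - min_gap, iv.end + min_gap)
        )
    loci: list[GenomicInterval] = []
    for length in lnc_lengths:
        placed = None
        for _ in range(max_tries):
            chrom = chrom_names[rng.choice(len(chrom_names), p=weights)]
            clen = chroms.lengths[chrom]
            if clen < length:
                continue
            start = int(rng.integers(1, clen - length + 2))
            end = start + length - 1
            if any(
                start <= fe and fs <= end for fs, fe in forbidden.get(chrom, ())
            ):
                continue
            placed = GenomicInterval(chrom, start, end, ".")
            break
        if placed is None:
            raise RuntimeError(
                f"could not place a locus of length {length} after {max_tries} tries"
            )
        loci.append(placed)
    return loci


def cluster_tissues(
    m: ExpressionMatrix,
    gene_subset: Sequence[str] | None = None,
    log_transform: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Hierarchical clustering of tissues: 1 - Pearson distance, Ward linkage.

    Profiles are log10(TPM+1) by default. Returns the scipy linkage matrix
    and the tissue labels in leaf-input order. A zero-variance tissue
    profile gets correlation 0 against everything (with a warning).
    """
    if len(m.tissues) < 2:
        raise ValueError("need >= 2 tissues to cluster")
    vals = m.values if gene_subset is None else m.values.loc[list(gene_subset)]
    if vals.empty:
        raise ValueError("empty gene subset")
    x = np.log10(vals.to_numpy(dtype=float) + 1.0) if log_transform else vals.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(x.T)
    bad = ~np.isfinite(corr)
    if bad.any():
        logger.warning("zero-variance tissue profile: correlations set to 0")
        corr = np.where(bad, 0.0, corr)
        np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="ward")
    return z, list(m.tissues)


def linkage_to_newick(z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = to_tree(z)

    def rec(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def density_by_chromosome(
    catalogue: Catalogue,
    chroms: ChromTable,
    biotypes: tuple[str, str] = ("lncRNA", "protein_coding"),
) -> dict:
    """Per-chromosome LNC and PCG densities (genes per Mb), their Spearman
    correlation across chromosomes, and per-size-class aggregate densities.
    """
    lnc_b, pcg_b = biotypes
    counts = {c: {"lnc": 0, "pcg": 0} for c in chroms}
    for gene in catalogue:
        if gene.chrom not in chroms:
            raise ValueError(f"gene {gene.gene_id} on unknown chromosome {gene.chrom}")
        if gene.biotype == lnc_b:
            counts[gene.chrom]["lnc"] += 1
        elif gene.biotype == pcg_b:
            counts[gene.chrom]["pcg"] += 1
    rows = []
    for chrom in chroms:
        mb = chroms.lengths[chrom] / 1e6
        rows.append(
            {
                "chrom": chrom,
                "size_class": chroms.size_classes[chrom],
                "length_mb": mb,
                "lnc_per_mb": counts[chrom]["lnc"] / mb,
                "pcg_per_mb": counts[chrom]["pcg"] / mb,
            }
        )
    per_chrom = pd.DataFrame(rows).set_index("chrom")
    rho, p = spearmanr(per_chrom["lnc_per_mb"], per_chrom["pcg_per_mb"])
    by_class = {}
    for cls, sub in per_chrom.groupby("size_class"):
        total_mb = sub["length_mb"].sum()
        by_class[cls] = {
            "lnc_per_mb": float((sub["lnc_per_mb"] * sub["length_mb"]).sum() / total_mb),
            "pcg_per_mb": float((sub["pcg_per_mb"] * sub["length_mb"]).sum() / total_mb),
        }
    return {
        "per_chrom": per_chrom,
        "spearman_rho": float(rho),
        "spearman_p": float(p),
        "by_class": by_class,
    }
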