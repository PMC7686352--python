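"""Seeded generators for synthetic annotation sources, CAGE peaks, planted
LNC:PCG configurations and expression matrices with known ground truth.

The generators emulate the structure of a multi-source lncRNA-catalogue
study: a base (reference) annotation plus several partially overlapping
candidate sources with controlled same-strand overlap fractions, CAGE peaks
covering a controlled fraction of each source's transcript 5' ends, planted
LNC:PCG pairs of every classifiable geometry at chosen gap distances, and a
tissue x gene TPM matrix (21 tissues, 8 replicates per tissue by default)
with planted tau profiles and planted Spearman-correlated pairs.

Every generator is a pure function of the configuration: the same seed
yields byte-identical outputs. Noise-free expression is the default so
planted values are recovered exactly; the replicate noise scale is explicit
for robustness experiments. Gene ids encode their ground truth (e.g.
``inra.ov.L0003``) purely for debuggability — no consumer relies on it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .annotation import (
    Catalogue,
    ChromTable,
    Gene,
    GenomicInterval,
    Transcript,
    write_bed,
    write_gtf,
)

#: 21-tissue panel abbreviations used for default expression simulations.
TISSUES_21 = (
    "burs", "cctl", "crbl", "duod", "fatG", "hard", "hert", "ileu", "kdny",
    "livr", "lung", "mscB", "optc", "ovry", "pcrs", "pvtc", "skin", "spln",
    "thym", "thyr", "trch",
)

#: CAGE support fractions reported for the four external sources (+-30 bp).
DEFAULT_CAGE_FRACTIONS = {
    "inra": 0.073,
    "aldb": 0.055,
    "ncbi": 0.053,
    "noncode": 0.042,
}

INTERGENIC_KINDS = ("same_strand", "divergent", "convergent")
GENIC_KINDS = (
    "genic_sense_exonic",
    "genic_antisense_nested_intronic",
    "genic_sense_containing",
    "genic_antisense_nested_exonic",
)

_SLOT = 10_000       # one gene per slot in source catalogues
_PAIR_BLOCK = 300_000  # isolation block per planted pair (> closest-PCG window)


@dataclass
class PairSpec:
    kind: str  # one of INTERGENIC_KINDS or GENIC_KINDS or "unclassified"
    distance_bp: int = 0  # gap for intergenic kinds; ignored for genic
    count: int = 1


@dataclass
class TauSpec:
    target_tau: float
    count: int = 1
    tier: str = "ge1"  # "ge1": Top1 >= 1 TPM; "lt1": Top1 < 1 TPM


@dataclass
class RhoSpec:
    target_rho: float
    count: int = 1


@dataclass
class SimulationConfig:
    """Study conditions for all generators."""

    seed: int = 0
    # genome
    chrom_length: int = 50_000_000
    # base + sources
    n_base_genes: int = 120
    base_biotype_mix: dict = field(
        default_factory=lambda: {"protein_coding": 0.6, "lncRNA": 0.3, "other": 0.1}
    )
    source_counts: dict = field(
        default_factory=lambda: {"inra": 1000, "aldb": 1000, "ncbi": 1000, "noncode": 1000}
    )
    overlap_fractions: dict = field(
        default_factory=lambda: {"inra": 0.05, "aldb": 0.05, "ncbi": 0.05, "noncode": 0.05}
    )
    cage_fractions: dict = field(default_factory=lambda: dict(DEFAULT_CAGE_FRACTIONS))
    # planted pairs
    pair_specs: list = field(
        default_factory=lambda: [
            PairSpec("divergent", 3_957, 2),
            PairSpec("divergent", 1_000, 1),
            PairSpec("convergent", 5_000, 1),
            PairSpec("convergent", 6_005, 1),
            PairSpec("same_strand", 5_001, 1),
            PairSpec("same_strand", 500, 1),
            PairSpec("genic_sense_exonic", 0, 1),
            PairSpec("genic_antisense_nested_intronic", 0, 1),
            PairSpec("genic_sense_containing", 0, 1),
            PairSpec("genic_antisense_nested_exonic", 0, 1),
            PairSpec("unclassified", 0, 1),
        ]
    )
    # expression
    tissues: tuple = TISSUES_21
    replicates_per_tissue: int = 8
    tau_specs: list = field(
        default_factory=lambda: [
            TauSpec(1.0, 3, "ge1"),
            TauSpec(0.9875, 3, "ge1"),
            TauSpec(0.0, 3, "ge1"),
            TauSpec(1.0, 2, "lt1"),
        ]
    )
    rho_specs: list = field(default_factory=lambda: [RhoSpec(1.0, 3), RhoSpec(-1.0, 1)])
    n_independent_pairs: int = 20
    n_low_support_genes: int = 3  # expressed >= 0.1 TPM but <= 2 reads everywhere
    noise_scale: float = 0.0  # sd of multiplicative log-normal replicate noise
    read_depth_factor: float = 50.0  # counts ~= TPM * factor

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, klass in (("pair_specs", PairSpec), ("tau_specs", TauSpec),
                           ("rho_specs", RhoSpec)):
            if key in raw:
                raw[key] = [klass(**d) for d in raw[key]]
        if "tissues" in raw:
            raw["tissues"] = tuple(raw["tissues"])
        return cls(**raw)


@dataclass
class GroundTruth:
    """Planted facts, kept consistent with the emitted files."""

    gene_source: dict = field(default_factory=dict)
    gene_biotype: dict = field(default_factory=dict)
    overlap_partner: dict = field(default_factory=dict)  # candidate -> base gene
    cage_supported: dict = field(default_factory=dict)  # transcript_id -> bool
    pairs: list = field(default_factory=list)  # dicts with planted classification
    hosts: list = field(default_factory=list)
    tau: dict = field(default_factory=dict)  # gene -> {"tau", "top1_tissue", "tier"}
    correlations: list = field(default_factory=list)  # dicts with planted rho
    retained: dict = field(default_factory=dict)  # gene -> bool (retention filter)
    sample_map: dict = field(default_factory=dict)  # sample -> tissue


def _two_exon_transcript(tid: str, gid: str, chrom: str, start: int, end: int,
                         strand: str) -> Transcript:
    third = (end - start + 1) // 3
    exons = [
        GenomicInterval(chrom, start, start + third - 1, strand),
        GenomicInterval(chrom, end - third + 1, end, strand),
    ]
    return Transcript(tid, gid, exons)


def _single_gene(gid: str, biotype: str, source: str, chrom: str, start: int,
                 end: int, strand: str, single_exon: bool = False) -> Gene:
    if single_exon:
        tx = Transcript(f"{gid}.t1", gid,
                        [GenomicInterval(chrom, start, end, strand)])
    else:
        tx = _two_exon_transcript(f"{gid}.t1", gid, chrom, start, end, strand)
    return Gene(gid, biotype, source, [tx])


def make_catalogues(
    cfg: SimulationConfig,
) -> tuple[Catalogue, dict[str, Catalogue], GroundTruth]:
    """Base annotation plus candidate sources with planted overlap fractions.

    For each source, exactly ``round(overlap_fraction * count)`` genes
    same-strand-overlap a base gene (by >= 1 bp); every other gene sits in a
    coordinate region reserved for that source, clear of all other genes.
    """
    truth = GroundTruth()
    chrom = "1"
    total_demand = (cfg.n_base_genes + sum(cfg.source_counts.values()) + 1) * _SLOT
    if total_demand > cfg.chrom_length:
        raise ValueError("infeasible config: chromosome too short for gene demand")

    # base genes on "+" in consecutive slots
    base = Catalogue()
    mix = list(cfg.base_biotype_mix.items())
    boundaries = np.cumsum([frac for _, frac in mix]) * cfg.n_base_genes
    for i in range(cfg.n_base_genes):
        biotype = mix[int(np.searchsorted(boundaries, i + 0.5))][0]
        start = 1 + i * _SLOT
        gid = f"ens.G{i:04d}"
        base.add_gene(_single_gene(gid, biotype, "ensembl", chrom, start,
                                   start + 1_999, "+"))
        truth.gene_source[gid] = "ensembl"
        truth.gene_biotype[gid] = biotype

    sources: dict[str, Catalogue] = {}
    region = (cfg.n_base_genes + 1) * _SLOT
    for k, (label, count) in enumerate(sorted(cfg.source_counts.items())):
        frac = cfg.overlap_fractions.get(label, 0.0)
        n_overlap = round(frac * count)
        if n_overlap > cfg.n_base_genes:
            raise ValueError(f"infeasible config: source {label} wants {n_overlap} "
                             f"overlaps but base has {cfg.n_base_genes} genes")
        cat = Catalogue()
        for j in range(count):
            gid = f"{label}.{'ov' if j < n_overlap else 'cl'}.L{j:04d}"
            if j < n_overlap:
                # start on the base gene's last bp, shifted per source so the
                # planted TSSs of different sources never coincide
                partner = base[f"ens.G{j:04d}"]
                start = partner.span.end - 250 * k
                gene = _single_gene(gid, "lncRNA", label, chrom, start,
                                    start + 1_999, "+")
                truth.overlap_partner[gid] = partner.gene_id
            else:
                start = 1 + region + j * _SLOT
                gene = _single_gene(gid, "lncRNA", label, chrom, start,
                                    start + 1_999, "+")
                truth.overlap_partner[gid] = None
            cat.add_gene(gene)
            truth.gene_source[gid] = label
            truth.gene_biotype[gid] = "lncRNA"
        sources[label] = cat
        region += (count + 1) * _SLOT
    return base, sources, truth


def make_cage(
    cfg: SimulationConfig,
    sources: dict[str, Catalogue],
    truth: GroundTruth,
) -> list[GenomicInterval]:
    """CAGE peaks covering the planted fraction of each source's TSSs.

    Exactly ``round(cage_fraction * n_transcripts)`` transcripts per source
    get a peak centred on their TSS (well within +-30 bp); no other peak
    falls near any transcript 5' end.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    peaks: list[GenomicInterval] = []
    for label in sorted(sources):
        cat = sources[label]
        txs = sorted(cat.transcripts(), key=lambda t: t.transcript_id)
        n_sup = round(cfg.cage_fractions.get(label, 0.0) * len(txs))
        chosen = rng.choice(len(txs), size=n_sup, replace=False)
        chosen_set = set(int(c) for c in chosen)
        for i, tx in enumerate(txs):
            supported = i in chosen_set
            truth.cage_supported[tx.transcript_id] = supported
            if supported:
                peaks.append(
                    GenomicInterval(tx.chrom, max(1, tx.tss - 5), tx.tss + 5, ".")
                )
    return peaks


def _plant_pair(kind: str, distance: int, chrom: str, offset: int,
                lnc_id: str, pcg_id: str) -> tuple[Gene, Gene | None, dict]:
    """Build one LNC(:PCG) pair with the stated planted classification."""
    o = offset
    rec = {"lnc_gene_id": lnc_id, "pcg_gene_id": pcg_id, "distance_bp": distance}
    if kind == "unclassified":
        lnc = _single_gene(lnc_id, "lncRNA", "sim", chrom, o + 1_000, o + 3_000, "+")
        return lnc, None, {"lnc_gene_id": lnc_id, "pcg_gene_id": None,
                           "ptype": "unclassified", "direction": None,
                           "subtype": None, "location": None, "distance_bp": None,
                           "distance_class": None}
    if kind in INTERGENIC_KINDS:
        # LNC left [o+1000, o+2999], PCG right at the stated gap
        lnc_start, lnc_end = o + 1_000, o + 2_999
        pcg_start = lnc_end + distance + 1
        pcg_end = pcg_start + 2_999
        if kind == "same_strand":
            lnc_strand = pcg_strand = "+"
            location = "upstream"
        elif kind == "divergent":  # 5'-to-5': left gene transcribes leftward
            lnc_strand, pcg_strand = "-", "+"
            location = "upstream"
        else:  # convergent, 3'-to-3'
            lnc_strand, pcg_strand = "+", "-"
            location = "downstream"
        lnc = _single_gene(lnc_id, "lncRNA", "sim", chrom, lnc_start, lnc_end,
                           lnc_strand)
        pcg = _single_gene(pcg_id, "protein_coding", "sim", chrom, pcg_start,
                           pcg_end, pcg_strand)
        rec.update(ptype="intergenic", direction=kind, subtype=None,
                   location=location,
                   distance_class=("<=1kb" if distance <= 1_000
                                   else "<=5kb" if distance <= 5_000 else ">5kb"))
        return lnc, pcg, rec

    # genic geometries: PCG "+" [o+10000, o+13000], exons [10000-10200] and
    # [12500-13000]
    pcg = Gene(pcg_id, "protein_coding", "sim", [Transcript(
        f"{pcg_id}.t1", pcg_id,
        [GenomicInterval(chrom, o + 10_000, o + 10_200, "+"),
         GenomicInterval(chrom, o + 12_500, o + 13_000, "+")],
    )])
    if kind == "genic_sense_exonic":
        # LNC "+" straddles the PCG 5' end and shares exon bases
        lnc = _single_gene(lnc_id, "lncRNA", "sim", chrom, o + 9_000, o + 10_100,
                           "+", single_exon=True)
        rec.update(direction="sense", subtype="overlapping", location="exonic")
    elif kind == "genic_antisense_nested_intronic":
        lnc = _single_gene(lnc_id, "lncRNA", "sim", chrom, o + 10_500, o + 10_800,
                           "-", single_exon=True)
        rec.update(direction="antisense", subtype="nested", location="intronic")
    elif kind == "genic_sense_containing":
        lnc = Gene(lnc_id, "lncRNA", "sim", [Transcript(
            f"{lnc_id}.t1", lnc_id,
            [GenomicInterval(chrom, o + 9_000, o + 10_100, "+"),
             GenomicInterval(chrom, o + 13_900, o + 14_000, "+")],
        )])
        rec.update(direction="sense", subtype="containing", location="exonic")
    elif kind == "genic_antisense_nested_exonic":
        lnc = _single_gene(lnc_id, "lncRNA", "sim", chrom, o + 12_600, o + 12_900,
                           "-", single_exon=True)
        rec.update(direction="antisense", subtype="nested", location="exonic")
    else:
        raise ValueError(f"unknown pair kind {kind!r}")
    rec.update(ptype="genic", distance_bp=0, distance_class="<=1kb")
    return lnc, pcg, rec


def make_pairs(cfg: SimulationConfig) -> tuple[Catalogue, Catalogue, GroundTruth]:
    """Planted LNC:PCG configurations, one isolated block per pair.

    Returns the LNC catalogue, the PCG catalogue and the ground truth with
    one planted classification record per LNC.
    """
    truth = GroundTruth()
    lncs, pcgs = Catalogue(), Catalogue()
    chrom = "P1"
    block = 0
    for spec in cfg.pair_specs:
        for c in range(spec.count):
            lnc_id = f"sim.{spec.kind}.{spec.distance_bp}.L{block:03d}"
            pcg_id = f"sim.{spec.kind}.{spec.distance_bp}.P{block:03d}"
            lnc, pcg, rec = _plant_pair(spec.kind, spec.distance_bp, chrom,
                                        block * _PAIR_BLOCK, lnc_id, pcg_id)
            lncs.add_gene(lnc)
            if pcg is not None:
                pcgs.add_gene(pcg)
            truth.pairs.append(rec)
            truth.gene_biotype[lnc_id] = "lncRNA"
            if pcg is not None:
                truth.gene_biotype[pcg_id] = "protein_coding"
            block += 1
    return lncs, pcgs, truth


def make_hosted_small_rnas(
    cfg: SimulationConfig,
    specs: Sequence[tuple[str, str]] = (
        ("sense", "intronic"), ("antisense", "intronic"), ("sense", "exonic"),
    ),
) -> tuple[Catalogue, Catalogue, GroundTruth]:
    """Host LNCs with planted miRNAs inside (plus one non-hosted decoy)."""
    truth = GroundTruth()
    lncs, smalls = Catalogue(), Catalogue()
    chrom = "H1"
    for i, (strand_rel, location) in enumerate(specs):
        o = i * 100_000
        host_id = f"host.{strand_rel}.{location}.L{i}"
        host = Gene(host_id, "lncRNA", "sim", [Transcript(
            f"{host_id}.t1", host_id,
            [GenomicInterval(chrom, o + 5_000, o + 5_500, "+"),
             GenomicInterval(chrom, o + 7_500, o + 8_000, "+")],
        )])
        lncs.add_gene(host)
        strand = "+" if strand_rel == "sense" else "-"
        if location == "intronic":
            start, end = o + 6_000, o + 6_080
        else:
            start, end = o + 5_100, o + 5_180
        mir_id = f"mir.{strand_rel}.{location}.M{i}"
        smalls.add_gene(_single_gene(mir_id, "miRNA", "sim", chrom, start, end,
                                     strand, single_exon=True))
        truth.hosts.append(
            {"host_lnc_id": host_id, "small_rna_id": mir_id,
             "small_rna_biotype": "miRNA", "strand_relation": strand_rel,
             "location": location}
        )
    # decoy straddling the next LNC boundary: not a host
    o = len(specs) * 100_000
    decoy_host = Gene("host.decoy.L", "lncRNA", "sim", [Transcript(
        "host.decoy.L.t1", "host.decoy.L",
        [GenomicInterval(chrom, o + 5_000, o + 8_000, "+")],
    )])
    lncs.add_gene(decoy_host)
    smalls.add_gene(_single_gene("mir.decoy.M", "miRNA", "sim", chrom,
                                 o + 7_900, o + 8_100, "+", single_exon=True))
    return lncs, smalls, truth


def _tau_profile(target_tau: float, n_tissues: int, top1_idx: int,
                 top_tpm: float) -> np.ndarray:
    """Invert the tau formula into a two-level profile (x, x/r, 0, ..., 0)."""
    T = n_tissues
    x = np.zeros(T)
    if target_tau >= 1.0:
        x[top1_idx] = top_tpm
        return x
    if target_tau <= 0.0:
        return np.full(T, top_tpm)
    inv_r = (T - 1) * (1.0 - target_tau)
    if inv_r > 1.0:
        raise ValueError(
            f"tau target {target_tau} unattainable with a two-level profile "
            f"over {T} tissues (needs tau >= {(T - 2) / (T - 1):.4f})"
        )
    x[top1_idx] = top_tpm
    x[(top1_idx + 1) % T] = top_tpm * inv_r
    return x


def make_expression(
    cfg: SimulationConfig,
    extra_gene_ids: Sequence[str] = (),
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Sample-level TPM and read-count tables with planted tau and rho.

    tau-planted genes get two-level tissue-mean profiles that invert the tau
    formula exactly; rho-planted pairs get Gaussian-copula profiles whose
    rank correlation targets the requested Spearman rho (exact at +-1);
    independent pairs are sampled independently. ``extra_gene_ids`` (e.g.
    planted pair members without their own tau spec) get independent
    profiles so every classified pair is expressed. Replicates multiply the
    tissue mean by log-normal noise of scale ``noise_scale`` (0 = noise-free).
    Read counts follow TPM at ``read_depth_factor``, except for the planted
    low-support genes which never exceed 2 reads.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    T = len(cfg.tissues)
    if T < 2:
        raise ValueError("need >= 2 tissues")
    truth = GroundTruth()
    profiles: dict[str, np.ndarray] = {}

    gi = 0
    for spec in cfg.tau_specs:
        top_tpm = 8.0 if spec.tier == "ge1" else 0.8
        for _ in range(spec.count):
            gid = f"tau.{spec.target_tau:g}.{spec.tier}.G{gi:03d}"
            top1 = gi % T
            profiles[gid] = _tau_profile(spec.target_tau, T, top1, top_tpm)
            truth.tau[gid] = {
                "tau": spec.target_tau,
                "top1_tissue": cfg.tissues[top1] if spec.target_tau > 0 else None,
                "tier": spec.tier,
            }
            gi += 1

    def copula_tpm(z: np.ndarray) -> np.ndarray:
        return 5.0 * np.exp(0.6 * z)

    pi = 0
    for spec in cfg.rho_specs:
        rho_p = 2.0 * math.sin(math.pi * spec.target_rho / 6.0)
        for _ in range(spec.count):
            a, b = f"rho.{spec.target_rho:g}.A{pi:03d}", f"rho.{spec.target_rho:g}.B{pi:03d}"
            z1 = rng.standard_normal(T)
            if spec.target_rho >= 1.0:
                z2 = z1
            elif spec.target_rho <= -1.0:
                z2 = -z1
            else:
                z2 = rho_p * z1 + math.sqrt(1 - rho_p**2) * rng.standard_normal(T)
            profiles[a] = copula_tpm(z1)
            profiles[b] = copula_tpm(z2)
            truth.correlations.append(
                {"a": a, "b": b, "rho": spec.target_rho, "kind": "planted"}
            )
            pi += 1
    for _ in range(cfg.n_independent_pairs):
        a, b = f"null.A{pi:03d}", f"null.B{pi:03d}"
        profiles[a] = copula_tpm(rng.standard_normal(T))
        profiles[b] = copula_tpm(rng.standard_normal(T))
        truth.correlations.append({"a": a, "b": b, "rho": 0.0, "kind": "independent"})
        pi += 1

    for gid in extra_gene_ids:
        if gid not in profiles:
            profiles[gid] = copula_tpm(rng.standard_normal(T))

    low_support = []
    for j in range(cfg.n_low_support_genes):
        gid = f"lowsup.G{j:03d}"
        profiles[gid] = np.full(T, 0.15)
        low_support.append(gid)

    genes = list(profiles)
    samples = [f"{t}_r{j + 1}" for t in cfg.tissues
               for j in range(cfg.replicates_per_tissue)]
    sample_map = {f"{t}_r{j + 1}": t for t in cfg.tissues
                  for j in range(cfg.replicates_per_tissue)}
    mean = np.vstack([np.repeat(profiles[g], cfg.replicates_per_tissue)
                      for g in genes])
    if cfg.noise_scale > 0:
        noise = np.exp(cfg.noise_scale * rng.standard_normal(mean.shape))
        tpm = mean * noise
    else:
        tpm = mean
    tpm_df = pd.DataFrame(tpm, index=genes, columns=samples)

    counts = np.rint(tpm * cfg.read_depth_factor)
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    for gid in low_support:
        counts_df.loc[gid] = np.minimum(counts_df.loc[gid], 2.0)
    for g in genes:
        truth.retained[g] = g not in low_support
    truth.sample_map = sample_map
    return tpm_df, counts_df, truth


def write_fixture_set(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Emit a full fixture set (GTFs, CAGE BED, TSV matrices, ground truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    base, sources, cat_truth = make_catalogues(cfg)
    paths["base"] = outdir / "base.gtf"
    write_gtf(base, paths["base"])
    for label, cat in sources.items():
        paths[label] = outdir / f"{label}.gtf"
        write_gtf(cat, paths[label])
    peaks = make_cage(cfg, sources, cat_truth)
    paths["cage"] = outdir / "cage_peaks.bed"
    write_bed(peaks, paths["cage"])

    lncs, pcgs, pair_truth = make_pairs(cfg)
    merged_pairs = Catalogue(list(lncs) + list(pcgs))
    paths["pairs"] = outdir / "pairs.gtf"
    write_gtf(merged_pairs, paths["pairs"])

    pair_gene_ids = [r["lnc_gene_id"] for r in pair_truth.pairs] + [
        r["pcg_gene_id"] for r in pair_truth.pairs if r["pcg_gene_id"]
    ]
    tpm, counts, expr_truth = make_expression(cfg, extra_gene_ids=pair_gene_ids)
    paths["tpm"] = outdir / "sample_tpm.tsv"
    tpm.to_csv(paths["tpm"], sep="\t", index_label="gene_id")
    paths["counts"] = outdir / "sample_counts.tsv"
    counts.to_csv(paths["counts"], sep="\t", index_label="gene_id")
    paths["sample_map"] = outdir / "sample_map.tsv"
    pd.DataFrame(
        {"sample": list(expr_truth.sample_map),
         "tissue": list(expr_truth.sample_map.values())}
    ).to_csv(paths["sample_map"], sep="\t", index=False)

    paths["pair_truth"] = outdir / "truth_pairs.tsv"
    pd.DataFrame(pair_truth.pairs).to_csv(paths["pair_truth"], sep="\t", index=False)
    paths["tau_truth"] = outdir / "truth_tau.tsv"
    pd.DataFrame(
        [{"gene_id": g, **v} for g, v in expr_truth.tau.items()]
    ).to_csv(paths["tau_truth"], sep="\t", index=False)
    return paths
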