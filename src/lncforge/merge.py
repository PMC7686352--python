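"""CAGE-ranked source ordering and sequential, overlap-rejecting aggregation.

Annotation sources are added one at a time to a growing catalogue; a
candidate gene enters only if none of its transcripts overlaps, same-strand
and by at least one nucleotide, any transcript already in the catalogue.
The order of addition ranks sources by the fraction of their lncRNA
transcripts whose 5' end lies within +-window_bp of a CAGE peak — a proxy
for the quality of 5'-end modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .annotation import Catalogue, Gene, GenomicInterval, Transcript

OVERLAP_LEVELS = ("span", "exon")


@dataclass
class CageSupport:
    """CAGE support of one source's transcripts of a given biotype."""

    source: str
    window_bp: int
    n_transcripts: int
    n_supported: int

    @property
    def fraction(self) -> float:
        return self.n_supported / self.n_transcripts


@dataclass
class SourceMergeStats:
    source: str
    n_candidate: int = 0
    n_added: int = 0
    n_rejected: int = 0
    rejected_gene_ids: list[str] = field(default_factory=list)


@dataclass
class MergeReport:
    per_source: list[SourceMergeStats] = field(default_factory=list)
    source_order: list[str] = field(default_factory=list)


def _intervals_intersect(a: GenomicInterval, b: GenomicInterval) -> bool:
    return a.start <= b.end and b.start <= a.end


def transcripts_overlap(a: Transcript, b: Transcript, level: str = "span") -> bool:
    """Same-strand >=1 bp overlap between two transcripts.

    level="span" compares transcript extents; level="exon" requires an
    exon-pair intersection. Strand "." never matches anything.
    """
    if level not in OVERLAP_LEVELS:
        raise ValueError(f"level must be one of {OVERLAP_LEVELS}")
    if a.chrom != b.chrom or a.strand != b.strand or a.strand == ".":
        return False
    if not _intervals_intersect(a.span, b.span):
        return False
    if level == "span":
        return True
    return any(
        _intervals_intersect(ea, eb) for ea in a.exons for eb in b.exons
    )


def cage_support_fraction(
    catalogue: Catalogue,
    peaks: Sequence[GenomicInterval],
    window_bp: int = 30,
    biotype: str = "lncRNA",
    match_strand: bool = False,
) -> CageSupport:
    """Fraction of transcripts (of ``biotype`` genes) with a CAGE-supported TSS.

    A transcript is supported iff its TSS lies within some peak extended by
    ``window_bp`` on both sides (both endpoints inclusive, i.e. +-30 means
    |tss - nearest peak bp| <= 30). Peak strand is ignored unless
    ``match_strand`` is set.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    # per-chrom (and optionally strand) trees of extended peaks
    trees: dict[tuple, IntervalTree] = {}
    for p in peaks:
        key = (p.chrom, p.strand) if match_strand else (p.chrom,)
        trees.setdefault(key, IntervalTree()).addi(
            max(1, p.start - window_bp), p.end + window_bp + 1
        )

    n_tx = 0
    n_sup = 0
    label = catalogue.source_order[0] if catalogue.source_order else "catalogue"
    for gene in catalogue:
        if gene.biotype != biotype:
            continue
        for tx in gene.transcripts:
            n_tx += 1
            key = (tx.chrom, tx.strand) if match_strand else (tx.chrom,)
            tree = trees.get(key)
            if tree is not None and tree.overlaps_point(tx.tss):
                n_sup += 1
    if n_tx == 0:
        raise ValueError(f"empty denominator: no {biotype} transcripts in {label}")
    return CageSupport(label, window_bp, n_tx, n_sup)


def order_sources_by_cage(
    sources: Mapping[str, Catalogue],
    peaks: Sequence[GenomicInterval],
    window_bp: int = 30,
    biotype: str = "lncRNA",
) -> list[str]:
    """Order source labels by descending CAGE support fraction.

    Ties are broken lexicographically by label so the order is deterministic.
    """
    if not sources:
        raise ValueError("at least one source required")
    fractions = {
        label: cage_support_fraction(cat, peaks, window_bp, biotype).fraction
        for label, cat in sources.items()
    }
    return sorted(fractions, key=lambda lab: (-fractions[lab], lab))


class _OverlapIndex:
    """Per-(chrom, strand) interval tree over transcripts of admitted genes."""

    def __init__(self, level: str):
        self.level = level
        self.trees: dict[tuple[str, str], IntervalTree] = {}

    def add_gene(self, gene: Gene) -> None:
        for tx in gene.transcripts:
            tree = self.trees.setdefault((tx.chrom, tx.strand), IntervalTree())
            intervals = [tx.span] if self.level == "span" else tx.exons
            for iv in intervals:
                tree.addi(iv.start, iv.end + 1, tx)

    def gene_overlaps(self, gene: Gene) -> bool:
        for tx in gene.transcripts:
            if tx.strand == ".":
                continue
            tree = self.trees.get((tx.chrom, tx.strand))
            if tree is None:
                continue
            intervals = [tx.span] if self.level == "span" else tx.exons
            for iv in intervals:
                for hit in tree.overlap(iv.start, iv.end + 1):
                    if transcripts_overlap(tx, hit.data, self.level):
                        return True
        return False


def merge_catalogues(
    base: Catalogue,
    sources: Sequence[tuple[str, Catalogue]],
    level: str = "span",
) -> tuple[Catalogue, MergeReport]:
    """Sequentially aggregate ``sources`` (in the given order) onto ``base``.

    Base genes of all biotypes are retained unconditionally. A candidate gene
    is added iff no transcript of it overlaps (per :func:`transcripts_overlap`)
    any transcript of any gene already in the growing catalogue; rejection is
    gene-atomic. Gene models are never edited — each output gene is the input
    record. Duplicate gene_ids across inputs are an error.
    """
    if level not in OVERLAP_LEVELS:
        raise ValueError(f"level must be one of {OVERLAP_LEVELS}")
    merged = Catalogue()
    index = _OverlapIndex(level)
    for gene in base:
        merged.add_gene(gene)  # raises on duplicate ids
        index.add_gene(gene)

    report = MergeReport()
    for label, source in sources:
        stats = SourceMergeStats(source=label)
        for gene in source:
            stats.n_candidate += 1
            if gene.gene_id in merged:
                raise ValueError(f"duplicate gene_id {gene.gene_id} in source {label}")
            if index.gene_overlaps(gene):
                stats.n_rejected += 1
                stats.rejected_gene_ids.append(gene.gene_id)
            else:
                merged.add_gene(gene)
                index.add_gene(gene)
                stats.n_added += 1
        report.per_source.append(stats)
        report.source_order.append(label)
    return merged, report


def update_to_new_assembly(
    mapped: Catalogue,
    reference: Catalogue,
    level: str = "span",
) -> tuple[Catalogue, MergeReport]:
    """Carry a catalogue over to a new assembly's reference annotation.

    The output is the reference annotation plus every mapped gene with zero
    same-strand transcript overlap against it; a gene with even one
    overlapping transcript is removed whole. ``mapped`` genes must already
    carry post-mapping coordinates and single chrom/strand placements.
    """
    return merge_catalogues(reference, [("mapped", mapped)], level=level)


def merge_report_frame(report: MergeReport):
    """MergeReport as a tidy DataFrame (source, candidates, added, rejected)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "source": s.source,
                "candidates": s.n_candidate,
                "added": s.n_added,
                "rejected": s.n_rejected,
            }
            for s in report.per_source
        ]
    )
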