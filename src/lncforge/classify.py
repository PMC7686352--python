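"""Positional classification of lncRNA genes against their closest
protein-coding gene, plus small-RNA host detection.

Each lncRNA transcript is classified against the closest protein-coding
transcript found within a window (default 100 kb) on the same chromosome:

* spans overlap -> "genic", direction sense/antisense by strand, subtype
  containing / nested / overlapping by span containment, location
  exonic / intronic by exon-exon intersection;
* spans disjoint -> "intergenic", direction same_strand / divergent
  (5'-to-5', head-to-head) / convergent (3'-to-3', tail-to-tail), location
  upstream / downstream of the protein-coding gene's TSS, with the gap in bp
  and a distance class (<=1kb / <=5kb "close" / >5kb "distant");
* no candidate within the window -> "unclassified".

Transcript-level calls are then collapsed to one gene-level record,
flagging genes whose transcripts disagree.

Distance convention: number of bases strictly between the two spans;
overlapping or bookended spans have distance 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from .annotation import (
    Catalogue,
    Gene,
    GenomicInterval,
    SMALL_RNA_BIOTYPES,
    Transcript,
)

DISTANCE_THRESHOLDS = (1_000, 5_000)
DISTANCE_CLASSES = ("<=1kb", "<=5kb", ">5kb")
DEFAULT_WINDOW_BP = 100_000


@dataclass
class PairClassification:
    """Classification of one LNC (transcript or gene) against its closest PCG."""

    lnc_gene_id: str
    pcg_gene_id: str | None
    ptype: str  # genic | intergenic | unclassified
    direction: str | None  # sense/antisense (genic); same_strand/divergent/convergent
    subtype: str | None  # containing | nested | overlapping (genic only)
    location: str | None  # exonic/intronic (genic); upstream/downstream (intergenic)
    distance_bp: int | None
    distance_class: str | None
    conflict: bool = False
    lnc_transcript_id: str | None = None
    pcg_transcript_id: str | None = None


@dataclass
class HostRelation:
    """A small RNA whose span lies fully within a host lncRNA gene span."""

    host_lnc_id: str
    small_rna_id: str
    small_rna_biotype: str
    strand_relation: str  # sense | antisense
    location: str  # exonic | intronic


def pair_distance(a: GenomicInterval, b: GenomicInterval) -> int:
    """Bases strictly between two intervals; overlap or bookend -> 0."""
    if a.chrom != b.chrom:
        raise ValueError(f"intervals on different chromosomes: {a.chrom}, {b.chrom}")
    if a.start > b.end:
        a, b = b, a
    return max(0, b.start - a.end - 1)


def distance_bin(d: int, thresholds: tuple[int, int] = DISTANCE_THRESHOLDS) -> str:
    """Distance class with boundaries inclusive on the small side."""
    if d < 0:
        raise ValueError("distance must be >= 0")
    lo, hi = thresholds
    if d <= lo:
        return DISTANCE_CLASSES[0]
    if d <= hi:
        return DISTANCE_CLASSES[1]
    return DISTANCE_CLASSES[2]


def _exons_intersect(a: Transcript, b: Transcript) -> bool:
    return any(
        ea.start <= eb.end and eb.start <= ea.end for ea in a.exons for eb in b.exons
    )


def classify_transcript_pair(lnc_t: Transcript, pcg_t: Transcript) -> PairClassification:
    """Classify one LNC transcript against one PCG transcript (same chrom)."""
    if lnc_t.chrom != pcg_t.chrom:
        raise ValueError("transcripts on different chromosomes")
    if lnc_t.strand == "." or pcg_t.strand == ".":
        raise ValueError("unstranded transcript not classifiable")
    ls, ps = lnc_t.span, pcg_t.span
    common = dict(
        lnc_gene_id=lnc_t.gene_id,
        pcg_gene_id=pcg_t.gene_id,
        lnc_transcript_id=lnc_t.transcript_id,
        pcg_transcript_id=pcg_t.transcript_id,
    )
    if ls.start <= ps.end and ps.start <= ls.end:  # genic
        direction = "sense" if lnc_t.strand == pcg_t.strand else "antisense"
        if ls.start <= ps.start and ps.end <= ls.end:
            subtype = "containing"  # LNC contains the PCG
        elif ps.start <= ls.start and ls.end <= ps.end:
            subtype = "nested"  # LNC inside the PCG
        else:
            subtype = "overlapping"
        location = "exonic" if _exons_intersect(lnc_t, pcg_t) else "intronic"
        return PairClassification(
            ptype="genic",
            direction=direction,
            subtype=subtype,
            location=location,
            distance_bp=0,
            distance_class=distance_bin(0),
            **common,
        )
    # intergenic
    d = pair_distance(ls, ps)
    lnc_is_left = ls.end < ps.start
    if lnc_t.strand == pcg_t.strand:
        direction = "same_strand"
    else:
        # left feature transcribing leftward (-) and right feature rightward (+)
        # puts the two 5' ends face to face across the gap: divergent.
        left_strand = lnc_t.strand if lnc_is_left else pcg_t.strand
        direction = "divergent" if left_strand == "-" else "convergent"
    # upstream iff the LNC lies 5' of the PCG TSS
    if pcg_t.strand == "+":
        location = "upstream" if lnc_is_left else "downstream"
    else:
        location = "upstream" if not lnc_is_left else "downstream"
    return PairClassification(
        ptype="intergenic",
        direction=direction,
        subtype=None,
        location=location,
        distance_bp=d,
        distance_class=distance_bin(d),
        **common,
    )


def _unclassified(lnc: Gene) -> PairClassification:
    return PairClassification(
        lnc_gene_id=lnc.gene_id,
        pcg_gene_id=None,
        ptype="unclassified",
        direction=None,
        subtype=None,
        location=None,
        distance_bp=None,
        distance_class=None,
    )


def find_closest_pcg(
    lnc: Gene,
    pcgs: Catalogue,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> list[PairClassification]:
    """Per-LNC-transcript classification against the closest PCG transcript.

    Overlapping candidates have distance 0 and take priority. Ties at equal
    gap prefer the upstream candidate (relative to the LNC's own orientation),
    then the lexicographically smaller (gene_id, transcript_id). Transcripts
    with no PCG within the window are omitted; an empty list means the gene
    is unclassified.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    calls: list[PairClassification] = []
    for lnc_t in lnc.transcripts:
        best: tuple | None = None
        for pcg in pcgs:
            if pcg.chrom != lnc_t.chrom:
                continue
            for pcg_t in pcg.transcripts:
                d = pair_distance(lnc_t.span, pcg_t.span)
                if d > window_bp:
                    continue
                # upstream (5' of the LNC) preferred on ties
                if lnc_t.strand == "+":
                    is_upstream = pcg_t.span.start <= lnc_t.span.start
                else:
                    is_upstream = pcg_t.span.end >= lnc_t.span.end
                key = (d, 0 if is_upstream else 1, pcg.gene_id, pcg_t.transcript_id)
                if best is None or key < best[0]:
                    best = (key, pcg_t)
        if best is not None:
            calls.append(classify_transcript_pair(lnc_t, best[1]))
    return calls


def gene_level_classification(
    per_transcript: Sequence[PairClassification],
) -> PairClassification:
    """Collapse transcript-level calls into one gene-level record.

    If all calls agree on (ptype, direction, pcg_gene_id) the shared
    classification is kept with the minimum distance. Otherwise the call of
    the closest transcript wins (genic beats intergenic at equal distance)
    and the record is flagged as a conflict.
    """
    if not per_transcript:
        raise ValueError("no transcript classifications given")
    keys = {(c.ptype, c.direction, c.pcg_gene_id) for c in per_transcript}
    ranked = sorted(
        per_transcript,
        key=lambda c: (
            c.distance_bp,
            0 if c.ptype == "genic" else 1,
            c.pcg_gene_id or "",
        ),
    )
    winner = replace(ranked[0], conflict=len(keys) > 1)
    return winner


def classify_genes(
    lncs: Catalogue,
    pcgs: Catalogue,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> list[PairClassification]:
    """One gene-level record per LNC gene (classified or unclassified)."""
    out = []
    for lnc in lncs:
        calls = find_closest_pcg(lnc, pcgs, window_bp)
        out.append(gene_level_classification(calls) if calls else _unclassified(lnc))
    return out


def classification_frame(records: Iterable[PairClassification]) -> pd.DataFrame:
    """Records as a DataFrame mirroring the per-gene classification table."""
    return pd.DataFrame(
        [
            {
                "lnc_gene_id": r.lnc_gene_id,
                "pcg_gene_id": r.pcg_gene_id,
                "ptype": r.ptype,
                "direction": r.direction,
                "subtype": r.subtype,
                "location": r.location,
                "distance_bp": r.distance_bp,
                "distance_class": r.distance_class,
                "conflict": r.conflict,
            }
            for r in records
        ]
    )


def find_hosts(small_rnas: Catalogue, lncs: Catalogue) -> list[HostRelation]:
    """Small RNAs whose span lies fully within an LNC gene span.

    Strand is ignored for candidacy; the sense/antisense relation and the
    exonic/intronic location (any exon-exon intersection with any host
    transcript) are recorded. A small RNA may have several hosts and a host
    several small RNAs.
    """
    out: list[HostRelation] = []
    for lnc in lncs:
        lspan = lnc.span
        for srna in small_rnas:
            if srna.biotype not in SMALL_RNA_BIOTYPES:
                continue
            if not lspan.contains(srna.span):
                continue
            exonic = any(
                _exons_intersect(st, lt)
                for st in srna.transcripts
                for lt in lnc.transcripts
            )
            out.append(
                HostRelation(
                    host_lnc_id=lnc.gene_id,
                    small_rna_id=srna.gene_id,
                    small_rna_biotype=srna.biotype,
                    strand_relation="sense" if srna.strand == lnc.strand else "antisense",
                    location="exonic" if exonic else "intronic",
                )
            )
    return out


def hosts_frame(relations: Iterable[HostRelation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "host_lnc_id": r.host_lnc_id,
                "small_rna_id": r.small_rna_id,
                "small_rna_biotype": r.small_rna_biotype,
                "strand_relation": r.strand_relation,
                "location": r.location,
            }
            for r in relations
        ]
    )
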