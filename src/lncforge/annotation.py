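"""Gene/transcript/exon data model and GTF/BED/TSV readers and writers.

Internal coordinates are 1-based, fully inclusive (GTF native). BED input is
0-based half-open and converted at the boundary: ``start_internal =
start_bed + 1``, ``end_internal = end_bed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

#: Biotypes the catalogue distinguishes; anything else maps to "other".
BIOTYPES = ("lncRNA", "protein_coding", "miRNA", "snoRNA", "snRNA", "other")

#: Small-RNA biotypes eligible for host detection.
SMALL_RNA_BIOTYPES = ("miRNA", "snoRNA", "snRNA")

STRANDS = ("+", "-", ".")


def normalize_biotype(raw: str) -> str:
    """Map an annotation biotype string onto the six-value vocabulary."""
    return raw if raw in BIOTYPES else "other"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded 1-based inclusive interval on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >=1 bp (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        """True iff ``other`` lies entirely within this interval (same chrom)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class Transcript:
    """One transcript: an exon chain sharing chrom and strand.

    The span is derived from the exons; the TSS is the 5' extremity
    (span.start on "+", span.end on "-").
    """

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"transcript {self.transcript_id}: exons disagree on chrom/strand"
            )
        self.exons = sorted(self.exons, key=lambda e: (e.start, e.end))
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def tss(self) -> int:
        """1-based position of the 5' extremity."""
        return self.span.end if self.strand == "-" else self.span.start


@dataclass
class Gene:
    """A gene: one or more transcripts sharing chrom/strand, with provenance."""

    gene_id: str
    biotype: str
    source: str
    transcripts: list[Transcript]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        self.biotype = normalize_biotype(self.biotype)
        chroms = {t.chrom for t in self.transcripts}
        strands = {t.strand for t in self.transcripts}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"gene {self.gene_id}: transcripts disagree on chrom/strand"
            )

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        start = min(t.span.start for t in self.transcripts)
        end = max(t.span.end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)


class Catalogue:
    """An ordered, provenance-tracked gene set.

    Genes are keyed by gene_id; ``source_order`` records the order in which
    provenance labels entered the catalogue.
    """

    def __init__(self, genes: Iterable[Gene] = (), source_order: list[str] | None = None):
        self.genes: dict[str, Gene] = {}
        self.source_order: list[str] = list(source_order or [])
        for g in genes:
            self.add_gene(g)

    def add_gene(self, gene: Gene) -> None:
        if gene.gene_id in self.genes:
            raise ValueError(f"duplicate gene_id {gene.gene_id}")
        self.genes[gene.gene_id] = gene
        if gene.source not in self.source_order:
            self.source_order.append(gene.source)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __getitem__(self, gene_id: str) -> Gene:
        return self.genes[gene_id]

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes.values())

    def transcripts(self) -> Iterator[Transcript]:
        for g in self:
            yield from g.transcripts

    def subset_biotype(self, biotype: str) -> "Catalogue":
        return Catalogue(
            (g for g in self if g.biotype == biotype), list(self.source_order)
        )

    def biotype_census(self) -> dict[str, int]:
        """Gene counts per biotype (e.g. to summarise a catalogue GTF)."""
        census: dict[str, int] = {}
        for g in self:
            census[g.biotype] = census.get(g.biotype, 0) + 1
        return census

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Catalogue):
            return NotImplemented
        if set(self.genes) != set(other.genes):
            return False
        for gid, g in self.genes.items():
            o = other.genes[gid]
            if (g.biotype, g.source) != (o.biotype, o.source):
                return False
            mine = {t.transcript_id: t.exons for t in g.transcripts}
            theirs = {t.transcript_id: t.exons for t in o.transcripts}
            if mine != theirs:
                return False
        return True


# Default chicken chromosome size classes: macro = chr 1-5, micro = chr 11-33,
# medium = everything else named.
def default_size_class(chrom: str) -> str:
    try:
        n = int(chrom.removeprefix("chr"))
    except ValueError:
        return "medium"
    if 1 <= n <= 5:
        return "macro"
    if 11 <= n <= 33:
        return "micro"
    return "medium"


class ChromTable:
    """Chromosome lengths and size classes (macro/medium/micro)."""

    def __init__(
        self,
        lengths: Mapping[str, int],
        size_classes: Mapping[str, str] | None = None,
    ):
        for chrom, length in lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")
        self.lengths = dict(lengths)
        if size_classes is None:
            self.size_classes = {c: default_size_class(c) for c in lengths}
        else:
            self.size_classes = dict(size_classes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __iter__(self) -> Iterator[str]:
        return iter(self.lengths)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ChromTable":
        df = pd.read_csv(path, sep="\t", dtype={0: str})
        cols = [c.lower() for c in df.columns]
        df.columns = cols
        lengths = dict(zip(df["chrom"], df["length"].astype(int)))
        classes = dict(zip(df["chrom"], df["class"])) if "class" in cols else None
        return cls(lengths, classes)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "chrom": list(self.lengths),
                "length": [self.lengths[c] for c in self.lengths],
                "class": [self.size_classes[c] for c in self.lengths],
            }
        ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _apply_chrom_map(chrom: str, chrom_map: Mapping[str, str] | None) -> str:
    if chrom_map and chrom in chrom_map:
        return chrom_map[chrom]
    return chrom


def read_gtf(
    path: str | Path,
    chrom_map: Mapping[str, str] | None = None,
    default_source: str | None = None,
) -> Catalogue:
    """Read an Ensembl-dialect GTF into a Catalogue.

    Transcript spans are derived from exon rows; ``gene`` rows, when present,
    provide ``gene_biotype``. ``chrom_map`` harmonizes chromosome names at
    read time (e.g. ``{"chr1": "1"}``). The GTF source column (column 2) is
    kept as provenance; ``default_source`` overrides it when given.
    """
    path = Path(path)
    exons: dict[str, list[GenomicInterval]] = {}
    tx_gene: dict[str, str] = {}
    gene_biotype: dict[str, str] = {}
    gene_source: dict[str, str] = {}
    gene_order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line, dialect=None)
            except Exception as exc:
                raise ValueError(f"{path}:{lineno}: malformed GTF row ({exc})") from exc
            if feat.start is None or feat.end is None:
                raise ValueError(f"{path}:{lineno}: malformed GTF row (missing coordinates)")
            if feat.end < feat.start:
                raise ValueError(f"{path}:{lineno}: end < start")
            attrs = feat.attributes
            if "gene_id" not in attrs:
                raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
            gid = attrs["gene_id"][0]
            chrom = _apply_chrom_map(feat.seqid, chrom_map)
            if gid not in gene_source:
                gene_order.append(gid)
                gene_source[gid] = default_source or feat.source or "unknown"
            if "gene_biotype" in attrs:
                gene_biotype[gid] = normalize_biotype(attrs["gene_biotype"][0])
            if feat.featuretype != "exon":
                continue
            if "transcript_id" not in attrs:
                raise ValueError(f"{path}:{lineno}: exon without transcript_id")
            tid = attrs["transcript_id"][0]
            tx_gene[tid] = gid
            exons.setdefault(tid, []).append(
                GenomicInterval(chrom, feat.start, feat.end, feat.strand)
            )

    genes: dict[str, list[Transcript]] = {}
    for tid, ex in exons.items():
        gid = tx_gene[tid]
        genes.setdefault(gid, []).append(Transcript(tid, gid, ex))

    cat = Catalogue()
    for gid in gene_order:
        if gid not in genes:  # gene/transcript rows without exons
            continue
        cat.add_gene(
            Gene(
                gene_id=gid,
                biotype=gene_biotype.get(gid, "other"),
                source=gene_source[gid],
                transcripts=sorted(genes[gid], key=lambda t: t.transcript_id),
            )
        )
    if len(cat) == 0:
        logger.warning("no genes read from %s", path)
    return cat


def write_gtf(catalogue: Catalogue, path: str | Path) -> None:
    """Write a Catalogue as Ensembl-dialect GTF (gene/transcript/exon rows).

    Provenance goes to column 2, so a round-trip through :func:`read_gtf`
    reproduces genes, transcripts, exons, biotypes and sources.
    """
    def attr(pairs: list[tuple[str, str]]) -> str:
        return " ".join(f'{k} "{v}";' for k, v in pairs)

    with open(path, "w") as fh:
        for gene in catalogue:
            span = gene.span
            fh.write(
                "\t".join(
                    [
                        span.chrom,
                        gene.source,
                        "gene",
                        str(span.start),
                        str(span.end),
                        ".",
                        gene.strand,
                        ".",
                        attr([("gene_id", gene.gene_id), ("gene_biotype", gene.biotype)]),
                    ]
                )
                + "\n"
            )
            for tx in gene.transcripts:
                tspan = tx.span
                common = [
                    ("gene_id", gene.gene_id),
                    ("transcript_id", tx.transcript_id),
                    ("gene_biotype", gene.biotype),
                ]
                fh.write(
                    "\t".join(
                        [
                            tspan.chrom,
                            gene.source,
                            "transcript",
                            str(tspan.start),
                            str(tspan.end),
                            ".",
                            tx.strand,
                            ".",
                            attr(common),
                        ]
                    )
                    + "\n"
                )
                for ex in tx.exons:
                    fh.write(
                        "\t".join(
                            [
                                ex.chrom,
                                gene.source,
                                "exon",
                                str(ex.start),
                                str(ex.end),
                                ".",
                                ex.strand,
                                ".",
                                attr(common),
                            ]
                        )
                        + "\n"
                    )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

_BED_COLS = [
    "chrom", "start", "end", "name", "score", "strand",
    "thickStart", "thickEnd", "itemRgb", "blockCount", "blockSizes", "blockStarts",
]


def read_bed(
    path: str | Path,
    mode: str = "intervals",
    chrom_map: Mapping[str, str] | None = None,
    source: str = "bed",
    biotype: str = "lncRNA",
) -> list[GenomicInterval] | Catalogue:
    """Read a BED6/BED12 file.

    mode="intervals" returns a list of :class:`GenomicInterval` (for CAGE
    peaks; strand "." is accepted). mode="transcripts" returns a
    :class:`Catalogue` where each BED line becomes one single-transcript gene:
    BED12 blocks become exons, BED6 lines become single-exon transcripts.
    """
    if mode not in ("intervals", "transcripts"):
        raise ValueError(f"unknown mode {mode!r}")
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs >=3 columns")
    df.columns = _BED_COLS[: df.shape[1]]

    if mode == "intervals":
        out: list[GenomicInterval] = []
        for row in df.itertuples(index=False):
            chrom = _apply_chrom_map(row.chrom, chrom_map)
            strand = getattr(row, "strand", ".") or "."
            out.append(GenomicInterval(chrom, int(row.start) + 1, int(row.end), strand))
        return out

    cat = Catalogue()
    for i, row in enumerate(df.itertuples(index=False)):
        chrom = _apply_chrom_map(row.chrom, chrom_map)
        strand = getattr(row, "strand", ".") or "."
        start0, end0 = int(row.start), int(row.end)
        name = getattr(row, "name", None) or f"bed_{i}"
        if df.shape[1] >= 12:
            n_blocks = int(row.blockCount)
            sizes = [int(x) for x in str(row.blockSizes).rstrip(",").split(",")]
            starts = [int(x) for x in str(row.blockStarts).rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(f"{path}: BED12 block count mismatch for {name}")
            if starts[0] != 0 or start0 + starts[-1] + sizes[-1] != end0:
                raise ValueError(f"{path}: BED12 blocks inconsistent with span for {name}")
            exons = [
                GenomicInterval(chrom, start0 + s + 1, start0 + s + sz, strand)
                for s, sz in zip(starts, sizes)
            ]
        else:
            exons = [GenomicInterval(chrom, start0 + 1, end0, strand)]
        tx = Transcript(f"{name}.1", name, exons)
        cat.add_gene(Gene(name, biotype, source, [tx]))
    return cat


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED6 (internal 1-based inclusive -> 0-based half-open)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fh.write(
                f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\tlocus_{i}\t0\t{iv.strand}\n"
            )
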