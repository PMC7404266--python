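"""Gene annotation parsing and strand-aware promoter derivation.

Reads GENCODE-like GTF exon records into a light in-memory gene model and
derives three kinds of promoter windows around each gene's representative
transcription start site (TSS):

``proximal``
    200 bp strictly upstream of the TSS through 49 bp downstream of it
    (250 bp total, the TSS base included).
``typical``
    the 2 kb window immediately upstream of the TSS.
``expanded``
    2 kb upstream of the TSS through the end of the representative
    transcript's first intron.

All internal coordinates are 0-based half-open; GTF input is 1-based closed
and BED output is 0-based half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

__all__ = [
    "TranscriptRecord",
    "GeneRecord",
    "GeneModel",
    "PromoterRegion",
    "GtfParseError",
    "read_gene_model",
    "representative_transcript",
    "derive_promoters",
    "write_bed",
    "read_bed",
]

PROXIMAL_UP = 200   # bases strictly upstream of the TSS
PROXIMAL_DOWN = 49  # bases strictly downstream; the TSS base itself is also included
TYPICAL_UP = 2000
EXPANDED_UP = 2000

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GtfParseError(ValueError):
    """Malformed GTF input; message carries the offending line number."""


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript: its TSS and exons as 1-based closed genomic intervals."""

    transcript_id: str
    tss: int                                 # 1-based genomic position
    exons: tuple[tuple[int, int], ...]       # sorted by genomic coordinate

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    transcripts: tuple[TranscriptRecord, ...]

    @property
    def start(self) -> int:
        """1-based leftmost exon coordinate over all transcripts."""
        return min(e[0] for t in self.transcripts for e in t.exons)


@dataclass
class GeneModel:
    """Ordered collection of genes (sorted by chrom, then genomic start)."""

    genes: list[GeneRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.genes)

    def get(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass(frozen=True)
class PromoterRegion:
    """A promoter window attached to a gene, 0-based half-open."""

    gene_id: str
    kind: str           # proximal | typical | expanded
    chrom: str
    start: int          # 0-based inclusive
    end: int            # 0-based exclusive
    strand: str
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty promoter interval for {self.gene_id}: [{self.start}, {self.end})"
            )

    @property
    def span(self) -> int:
        return self.end - self.start

    def contains_1based(self, pos: int) -> bool:
        """Membership test for a 1-based genomic position."""
        return self.start < pos <= self.end


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gene_model(stream: IO[str] | Iterable[str]) -> GeneModel:
    """Parse exon features from a GTF stream into a :class:`GeneModel`.

    The TSS of each transcript is the transcription-direction 5'-most exon
    boundary: the minimum exon start on '+', the maximum exon end on '-'.
    Genes are ordered deterministically by (chrom, gene start).

    Raises
    ------
    GtfParseError
        On a malformed line (naming the line number), inconsistent strand
        within a gene, or an exon interval with end < start.
    """
    # gene_id -> (chrom, strand, {transcript_id: [exons]})
    genes: dict[str, tuple[str, str, dict[str, list[tuple[int, int]]]]] = {}

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise GtfParseError(
                f"line {lineno}: expected 9 tab-delimited fields, got {len(parts)}"
            )
        chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = parts
        if feature != "exon":
            continue
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise GtfParseError(f"line {lineno}: non-integer coordinates") from None
        if end < start:
            raise GtfParseError(f"line {lineno}: exon end {end} < start {start}")
        if strand not in "+-":
            raise GtfParseError(f"line {lineno}: strand must be '+' or '-', got {strand!r}")
        a = _parse_attributes(attrs)
        if "gene_id" not in a or "transcript_id" not in a:
            raise GtfParseError(f"line {lineno}: missing gene_id/transcript_id attribute")
        gid, tid = a["gene_id"], a["transcript_id"]
        if gid not in genes:
            genes[gid] = (chrom, strand, {})
        else:
            g_chrom, g_strand, _ = genes[gid]
            if (g_chrom, g_strand) != (chrom, strand):
                raise GtfParseError(
                    f"line {lineno}: gene {gid} has inconsistent chrom/strand"
                )
        genes[gid][2].setdefault(tid, []).append((start, end))

    records: list[GeneRecord] = []
    for gid, (chrom, strand, txs) in genes.items():
        transcripts = []
        for tid in sorted(txs):
            exons = tuple(sorted(txs[tid]))
            if not exons:
                raise GtfParseError(f"transcript {tid} of gene {gid} has no exons")
            for (s1, e1), (s2, _e2) in zip(exons, exons[1:]):
                if s2 <= e1:
                    raise GtfParseError(
                        f"transcript {tid}: overlapping exons [{s1},{e1}] and start {s2}"
                    )
            tss = exons[0][0] if strand == "+" else exons[-1][1]
            transcripts.append(TranscriptRecord(tid, tss, exons))
        records.append(GeneRecord(gid, chrom, strand, tuple(transcripts)))

    records.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return GeneModel(records)


def representative_transcript(gene: GeneRecord) -> TranscriptRecord:
    """The transcript whose TSS is transcription-direction 5'-most.

    Ties are broken by lexicographically smallest transcript_id (transcripts
    are already stored in transcript_id order, so the first winner stands).
    """
    if gene.strand == "+":
        return min(gene.transcripts, key=lambda t: (t.tss, t.transcript_id))
    return min(gene.transcripts, key=lambda t: (-t.tss, t.transcript_id))


def _first_intron_bounds(tx: TranscriptRecord, strand: str) -> tuple[int, int] | None:
    """First intron in transcription direction, 0-based half-open; None if single-exon."""
    if tx.n_exons < 2:
        return None
    if strand == "+":
        up, down = tx.exons[0], tx.exons[1]
        return up[1], down[0] - 1           # 1-based (up.end+1 .. down.start-1)
    up, down = tx.exons[-1], tx.exons[-2]
    return down[1], up[0] - 1


def derive_promoter(gene: GeneRecord, kind: str) -> PromoterRegion:
    """Promoter window of the given kind for one gene (see module docstring)."""
    tx = representative_transcript(gene)
    t = tx.tss  # 1-based
    flags: tuple[str, ...] = ()

    if kind == "proximal":
        if gene.strand == "+":
            start, end = t - 1 - PROXIMAL_UP, t + PROXIMAL_DOWN
        else:
            start, end = t - 1 - PROXIMAL_DOWN, t + PROXIMAL_UP
    elif kind == "typical":
        if gene.strand == "+":
            start, end = t - 1 - TYPICAL_UP, t - 1
        else:
            start, end = t, t + TYPICAL_UP
    elif kind == "expanded":
        intron = _first_intron_bounds(tx, gene.strand)
        if intron is None:
            # degenerate single-exon transcript: run to the transcript 3' end
            flags = ("no_first_intron",)
            if gene.strand == "+":
                start, end = t - 1 - EXPANDED_UP, tx.exons[-1][1]
            else:
                start, end = tx.exons[0][0] - 1, t + EXPANDED_UP
        else:
            if gene.strand == "+":
                start, end = t - 1 - EXPANDED_UP, intron[1]
            else:
                start, end = intron[0], t + EXPANDED_UP
    else:
        raise ValueError(f"unknown promoter kind: {kind!r}")

    if start < 0:
        flags = flags + ("clipped_at_origin",)
        start = 0
    return PromoterRegion(gene.gene_id, kind, gene.chrom, start, end, gene.strand, flags)


def derive_promoters(model: GeneModel, kind: str) -> list[PromoterRegion]:
    """Promoter regions of one kind for every gene, in gene-model order."""
    return [derive_promoter(g, kind) for g in model]


def write_bed(regions: Iterable[PromoterRegion], stream: IO[str]) -> None:
    """Write regions as BED6 with name ``gene_id|kind`` and score 0."""
    for r in regions:
        stream.write(
            f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene_id}|{r.kind}\t0\t{r.strand}\n"
        )


def read_bed(stream: IO[str] | Iterable[str]) -> list[PromoterRegion]:
    """Read BED6 regions written by :func:`write_bed`."""
    regions = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith(("track", "#")):
            continue
        parts = line.split("\t")
        if len(parts) < 6:
            raise ValueError(f"BED line {lineno}: expected 6 fields, got {len(parts)}")
        chrom, start, end, name, _score, strand = parts[:6]
        gene_id, _, kind = name.partition("|")
        regions.append(
            PromoterRegion(gene_id, kind or "region", chrom, int(start), int(end), strand)
        )
    return regions
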