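"""Transcript models: annotation parsing, canonical-isoform choice, region sequences.

A gene's mRNA is represented in *transcript coordinates* (0-based, half-open,
5'->3' in the orientation of the mature message), partitioned into 5'UTR, CDS
and 3'UTR.  All downstream seed scanning and CLIP coverage work in this
coordinate system; genomic lifting is provided for BED export and round-trip
checks.

GTF input follows the standard convention (1-based inclusive coordinates,
``gene_id``/``transcript_id`` attributes); everything is converted to 0-based
half-open on read.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

from Bio import SeqIO
from Bio.Seq import reverse_complement

FIVE_UTR = "FIVE_UTR"
CDS = "CDS"
THREE_UTR = "THREE_UTR"
REGIONS = (FIVE_UTR, CDS, THREE_UTR)


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


class MissingSequenceError(KeyError):
    """A transcript named in the GTF has no sequence in the FASTA."""


class NoRegionError(ValueError):
    """Region sequence requested from a non-coding transcript."""


@dataclass
class TranscriptModel:
    """One transcript with exon structure and UTR/CDS partition.

    ``exons`` are genomic 0-based half-open intervals sorted 5'->3' in
    transcript orientation (descending genomic order on the minus strand).
    ``cds_span`` is the genomic [start, end) envelope of the coding sequence,
    or ``None`` for non-coding transcripts.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_span: tuple[int, int] | None = None
    region_intervals: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_span is not None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.cds_span is not None and not self.region_intervals:
            self.region_intervals = self._compute_regions()

    # -- coordinate arithmetic -------------------------------------------------

    def to_transcript_coord(self, gpos: int) -> int:
        """Map a genomic position (0-based) of an exonic base to transcript coords."""
        offset = 0
        for s, e in self.exons:
            if s <= gpos < e:
                if self.strand == "+":
                    return offset + (gpos - s)
                return offset + (e - 1 - gpos)
            offset += e - s
        raise AnnotationError(
            f"{self.transcript_id}: genomic position {gpos} is not exonic"
        )

    def to_genomic_coord(self, tpos: int) -> int:
        """Map a transcript position to the genomic position of that base."""
        if not 0 <= tpos < self.length:
            raise AnnotationError(
                f"{self.transcript_id}: transcript position {tpos} out of range"
            )
        offset = 0
        for s, e in self.exons:
            n = e - s
            if tpos < offset + n:
                i = tpos - offset
                return s + i if self.strand == "+" else e - 1 - i
            offset += n
        raise AssertionError("unreachable")

    def genomic_blocks(self, t_start: int, t_end: int) -> list[tuple[int, int]]:
        """Genomic half-open intervals covering transcript span [t_start, t_end)."""
        blocks: list[tuple[int, int]] = []
        offset = 0
        for s, e in self.exons:
            n = e - s
            lo, hi = max(t_start, offset), min(t_end, offset + n)
            if lo < hi:
                if self.strand == "+":
                    blocks.append((s + (lo - offset), s + (hi - offset)))
                else:
                    blocks.append((e - (hi - offset), e - (lo - offset)))
            offset += n
        blocks.sort()
        return blocks

    def _compute_regions(self) -> dict[str, tuple[int, int]]:
        g0, g1 = self.cds_span  # genomic envelope
        # 5'-most / 3'-most coding base in transcript orientation
        if self.strand == "+":
            t_cds_start = self.to_transcript_coord(g0)
            t_cds_end = self.to_transcript_coord(g1 - 1) + 1
        else:
            t_cds_start = self.to_transcript_coord(g1 - 1)
            t_cds_end = self.to_transcript_coord(g0) + 1
        if t_cds_end <= t_cds_start:
            raise AnnotationError(f"{self.transcript_id}: empty CDS")
        return {
            FIVE_UTR: (0, t_cds_start),
            CDS: (t_cds_start, t_cds_end),
            THREE_UTR: (t_cds_end, self.length),
        }

    def region_length(self, region: str) -> int:
        if not self.is_coding:
            return 0
        s, e = self.region_intervals[region]
        return e - s


@dataclass
class TranscriptSet:
    """All transcripts plus sequences and the gene -> canonical-isoform map."""

    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)
    gene_to_canonical: dict[str, str] = field(default_factory=dict)
    sequences: dict[str, str] = field(default_factory=dict)

    def canonical_models(self) -> Iterable[TranscriptModel]:
        for gid in sorted(self.gene_to_canonical):
            yield self.transcripts[self.gene_to_canonical[gid]]

    def region_sequence(self, transcript_id: str, region: str) -> str:
        """Sequence of one UTR/CDS region, in transcript orientation."""
        tm = self.transcripts[transcript_id]
        if not tm.is_coding:
            raise NoRegionError(
                f"{transcript_id} is non-coding and has no {region} region"
            )
        s, e = tm.region_intervals[region]
        return self.sequences[transcript_id][s:e]


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def _as_lines(stream: str | TextIO) -> Iterable[str]:
    if isinstance(stream, str):
        return io.StringIO(stream)
    return stream


def load_annotation(
    gtf_stream: str | TextIO,
    fasta_stream: str | TextIO,
    mode: str = "genome",
) -> TranscriptSet:
    """Build a :class:`TranscriptSet` from GTF + FASTA.

    ``mode="genome"``: FASTA holds chromosomes; transcript sequences are
    spliced from exons and reverse-complemented into transcript orientation on
    the minus strand.  ``mode="transcript"``: FASTA holds spliced transcript
    sequences keyed by transcript_id.
    """
    if mode not in ("genome", "transcript"):
        raise ValueError(f"mode must be 'genome' or 'transcript', got {mode!r}")

    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)

    for lineno, raw in enumerate(_as_lines(gtf_stream), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise AnnotationError(
                f"GTF line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
            )
        chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
        if feature not in ("exon", "CDS"):
            continue
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise AnnotationError(
                f"GTF line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
            ) from None
        if start < 1 or end < start:
            raise AnnotationError(f"GTF line {lineno}: bad interval {start}-{end}")
        attr = _parse_attributes(attrs)
        if "gene_id" not in attr or "transcript_id" not in attr:
            raise AnnotationError(
                f"GTF line {lineno}: gene_id/transcript_id attribute missing"
            )
        tid = attr["transcript_id"]
        known = meta.setdefault(tid, (attr["gene_id"], chrom, strand))
        if known != (attr["gene_id"], chrom, strand):
            raise AnnotationError(
                f"GTF line {lineno}: transcript {tid} has inconsistent gene/chrom/strand"
            )
        iv = (start - 1, end)  # to 0-based half-open
        (exons if feature == "exon" else cds).setdefault(tid, []).append(iv)

    ts = TranscriptSet()
    for tid in sorted(meta):
        gene, chrom, strand = meta[tid]
        ex = sorted(exons.get(tid, []))
        if not ex:
            continue
        for (s0, e0), (s1, _e1) in zip(ex, ex[1:]):
            if s1 < e0:
                raise AnnotationError(f"transcript {tid}: overlapping exons")
        if strand == "-":
            ex = ex[::-1]
        span = None
        if tid in cds:
            cs = min(s for s, _ in cds[tid])
            ce = max(e for _, e in cds[tid])
            span = (cs, ce)
        ts.transcripts[tid] = TranscriptModel(
            gene_id=gene, transcript_id=tid, chrom=chrom, strand=strand,
            exons=ex, cds_span=span,
        )

    if ts.transcripts:
        _attach_sequences(ts, fasta_stream, mode)
    ts.gene_to_canonical = select_canonical(ts) if ts.transcripts else {}
    return ts


def _attach_sequences(ts: TranscriptSet, fasta_stream: str | TextIO, mode: str) -> None:
    handle = _as_lines(fasta_stream)
    seqs = {rec.id: str(rec.seq).upper().replace("U", "T")
            for rec in SeqIO.parse(handle, "fasta")}
    for tid, tm in ts.transcripts.items():
        if mode == "transcript":
            if tid not in seqs:
                raise MissingSequenceError(
                    f"transcript {tid} has no sequence in the FASTA"
                )
            seq = seqs[tid]
        else:
            if tm.chrom not in seqs:
                raise MissingSequenceError(
                    f"chromosome {tm.chrom} (transcript {tid}) missing from FASTA"
                )
            chrom_seq = seqs[tm.chrom]
            parts = []
            for s, e in sorted(tm.exons):
                if e > len(chrom_seq):
                    raise AnnotationError(
                        f"transcript {tid}: exon [{s},{e}) beyond {tm.chrom} length"
                    )
                parts.append(chrom_seq[s:e])
            seq = "".join(parts)
            if tm.strand == "-":
                seq = reverse_complement(seq)
        if len(seq) != tm.length:
            raise AnnotationError(
                f"transcript {tid}: sequence length {len(seq)} != exon total {tm.length}"
            )
        ts.sequences[tid] = seq


def select_canonical(ts: TranscriptSet) -> dict[str, str]:
    """One coding transcript per gene: longest 3'UTR, then longest transcript,
    then lexicographically smallest id.  Genes without a coding isoform are
    dropped."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tm in ts.transcripts.values():
        if tm.is_coding:
            by_gene.setdefault(tm.gene_id, []).append(tm)
    return {
        gene: min(
            models,
            key=lambda tm: (-tm.region_length(THREE_UTR), -tm.length, tm.transcript_id),
        ).transcript_id
        for gene, models in by_gene.items()
    }


def region_sequence(ts: TranscriptSet, transcript_id: str, region: str) -> str:
    return ts.region_sequence(transcript_id, region)


def write_region_bed(ts: TranscriptSet, out: TextIO) -> None:
    """BED6 of canonical UTR/CDS regions in genomic coordinates, one line per
    exon-split block."""
    for tm in ts.canonical_models():
        for region in REGIONS:
            t0, t1 = tm.region_intervals[region]
            for gs, ge in tm.genomic_blocks(t0, t1):
                name = f"{tm.gene_id}|{tm.transcript_id}|{region}"
                out.write(f"{tm.chrom}\t{gs}\t{ge}\t{name}\t0\t{tm.strand}\n")
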