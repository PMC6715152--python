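"""AGO2 CLIP alignment processing: dedup, read partition, coverage, depths.

Single-end CLIP alignments (SAM) are collapsed on (reference, start, strand,
UMI), split into miRNA-derived vs target reads by overlap with mature miRNA
loci, and turned into per-position depth profiles from which seed-site
occupancy is read off.  The 2-nt UMI comes from the randomized dinucleotide
ligated with the 3' linker and is parsed from a ``_NN`` read-name suffix.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pysam
from scipy import stats

from .seedscan import SeedSite
from .transcriptome import CDS, FIVE_UTR, REGIONS, THREE_UTR, TranscriptSet

log = logging.getLogger(__name__)

_UMI_RE = re.compile(r"_([ACGT]{2})$")


class CoverageError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    reference: str
    start: int  # 0-based half-open
    end: int
    strand: str
    umi: str | None = None
    mapq: int = 255
    primary: bool = True

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass
class CoverageProfile:
    reference: str
    depth: np.ndarray  # per-position read depth

    @property
    def total(self) -> int:
        return int(self.depth.sum())


@dataclass(frozen=True)
class BedInterval:
    chrom: str
    start: int
    end: int
    name: str
    strand: str


@dataclass
class MirnaAbundanceTable:
    """Per-family AGO2-bound read counts with fractions and dense ranks."""

    counts: dict[str, int]
    fractions: dict[str, float]
    ranks: dict[str, int]
    mirna_read_fraction: float

    def rank_of(self, family: str) -> int:
        return self.ranks[family]


def parse_umi(read_id: str) -> str | None:
    m = _UMI_RE.search(read_id)
    return m.group(1) if m else None


def read_sam(path_or_handle, min_mapq: int = 10, primary_only: bool = True
             ) -> list[AlignmentRecord]:
    """Load single-end SAM alignments as :class:`AlignmentRecord`.

    Secondary/supplementary alignments and records below ``min_mapq`` are
    discarded (multimapper policy: primary, mapq >= 10).
    """
    tmp = None
    if hasattr(path_or_handle, "read"):
        # pysam needs a real file; spool handle contents through a temp file
        import tempfile
        tmp = tempfile.NamedTemporaryFile("w", suffix=".sam", delete=False)
        tmp.write(path_or_handle.read())
        tmp.close()
        path = tmp.name
    else:
        path = str(path_or_handle)
    fh = pysam.AlignmentFile(path, "r", check_sq=False)
    records: list[AlignmentRecord] = []
    with fh:
        for aln in fh.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            primary = not (aln.is_secondary or aln.is_supplementary)
            if primary_only and not primary:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            records.append(AlignmentRecord(
                read_id=aln.query_name,
                reference=aln.reference_name,
                start=aln.reference_start,
                end=aln.reference_end,
                strand="-" if aln.is_reverse else "+",
                umi=parse_umi(aln.query_name),
                mapq=aln.mapping_quality,
                primary=primary,
            ))
    if tmp is not None:
        import os
        os.unlink(tmp.name)
    if records and all(r.umi is None for r in records):
        log.warning("no UMIs found in read names; duplicate collapse is positional only")
    return records


def collapse_duplicates(records: Sequence[AlignmentRecord]) -> list[AlignmentRecord]:
    """Keep the first record per (reference, start, strand, UMI); stable order.

    Reads without a UMI collapse on position alone (the key's UMI slot is
    ``None`` for all of them).
    """
    seen: set[tuple] = set()
    out: list[AlignmentRecord] = []
    for r in records:
        key = (r.reference, r.start, r.strand, r.umi)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def read_bed(stream: str | TextIO) -> list[BedInterval]:
    handle = io.StringIO(stream) if isinstance(stream, str) else stream
    out = []
    for raw in handle:
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 6:
            raise CoverageError(f"BED line needs 6 fields: {line!r}")
        out.append(BedInterval(f[0], int(f[1]), int(f[2]), f[3], f[5]))
    return out


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def partition_reads(records: Sequence[AlignmentRecord],
                    mirna_intervals: Sequence[BedInterval]
                    ) -> tuple[list[AlignmentRecord], list[AlignmentRecord]]:
    """Split deduplicated reads into (miRNA-derived, target) reads.

    A read is miRNA-derived iff >= 50% of its aligned span overlaps a
    same-strand mature miRNA interval.  The partition is exhaustive/disjoint.
    """
    by_ref: dict[tuple[str, str], list[BedInterval]] = {}
    for iv in mirna_intervals:
        by_ref.setdefault((iv.chrom, iv.strand), []).append(iv)
    mirna, target = [], []
    for r in records:
        ivs = by_ref.get((r.reference, r.strand), ())
        best = max((_overlap(r.start, r.end, iv.start, iv.end) for iv in ivs),
                   default=0)
        (mirna if best * 2 >= r.length else target).append(r)
    return mirna, target


def assign_mirna_reads(mirna_records: Sequence[AlignmentRecord],
                       mirna_intervals: Sequence[BedInterval]) -> dict[str, str]:
    """read_id -> mature miRNA name, by largest same-strand overlap."""
    by_ref: dict[tuple[str, str], list[BedInterval]] = {}
    for iv in mirna_intervals:
        by_ref.setdefault((iv.chrom, iv.strand), []).append(iv)
    assignment = {}
    for r in mirna_records:
        ivs = by_ref.get((r.reference, r.strand), ())
        best = max(ivs, key=lambda iv: _overlap(r.start, r.end, iv.start, iv.end),
                   default=None)
        if best is not None:
            assignment[r.read_id] = best.name
    return assignment


def family_abundance(mirna_records: Sequence[AlignmentRecord],
                     mirna_intervals: Sequence[BedInterval],
                     mature_to_family: Mapping[str, str],
                     n_total_records: int) -> MirnaAbundanceTable:
    """Per-family read counts, fractions of miRNA-assigned reads, dense ranks.

    Families listed in ``mature_to_family`` but receiving zero reads are kept
    at count 0.  ``n_total_records`` is the deduplicated library size, used
    for the global miRNA read fraction.
    """
    assignment = assign_mirna_reads(mirna_records, mirna_intervals)
    counts = {fam: 0 for fam in sorted(set(mature_to_family.values()))}
    for read_id, mature in assignment.items():
        fam = mature_to_family.get(mature)
        if fam is not None:
            counts[fam] += 1
    total = sum(counts.values())
    fractions = {f: (c / total if total else 0.0) for f, c in counts.items()}
    # dense ranks, descending count, ties share the smaller rank
    distinct = sorted(set(counts.values()), reverse=True)
    rank_of_count = {c: i + 1 for i, c in enumerate(distinct)}
    ranks = {f: rank_of_count[c] for f, c in counts.items()}
    frac = total / n_total_records if n_total_records else 0.0
    return MirnaAbundanceTable(counts=counts, fractions=fractions, ranks=ranks,
                               mirna_read_fraction=frac)


def coverage(target_records: Sequence[AlignmentRecord],
             reference_lengths: Mapping[str, int]) -> dict[str, CoverageProfile]:
    """Per-position depth per reference; a read beyond its reference is an error."""
    profiles = {ref: CoverageProfile(ref, np.zeros(n, dtype=np.int64))
                for ref, n in reference_lengths.items()}
    for r in target_records:
        if r.reference not in profiles:
            raise CoverageError(f"read {r.read_id}: unknown reference {r.reference}")
        prof = profiles[r.reference]
        if r.end > len(prof.depth) or r.start < 0:
            raise CoverageError(
                f"read {r.read_id}: span [{r.start},{r.end}) exceeds "
                f"{r.reference} length {len(prof.depth)}"
            )
        prof.depth[r.start:r.end] += 1
    return profiles


def site_depth(profile: CoverageProfile, site: SeedSite) -> int:
    """Maximum per-base depth within the site span."""
    window = profile.depth[site.t_start:site.t_end]
    return int(window.max()) if window.size else 0


@dataclass
class GeneDepth:
    depth_3utr: int | None = None
    depth_5cds: int | None = None


def gene_site_depth(sites: Sequence[SeedSite],
                    profiles: Mapping[str, CoverageProfile]) -> dict[str, GeneDepth]:
    """Per gene, the maximum site depth over 3'UTR sites and over 5'UTR+CDS sites."""
    out: dict[str, GeneDepth] = {}
    for s in sites:
        prof = profiles.get(s.transcript_id)
        if prof is None:
            continue
        d = site_depth(prof, s)
        gd = out.setdefault(s.gene_id, GeneDepth())
        if s.region == THREE_UTR:
            gd.depth_3utr = d if gd.depth_3utr is None else max(gd.depth_3utr, d)
        else:
            gd.depth_5cds = d if gd.depth_5cds is None else max(gd.depth_5cds, d)
    return out


def write_gene_depth_tsv(gene_depths: Mapping[str, GeneDepth], out: TextIO) -> None:
    out.write("gene_id\tdepth_3utr\tdepth_5cds\n")
    for gid in sorted(gene_depths):
        gd = gene_depths[gid]
        d3 = "" if gd.depth_3utr is None else gd.depth_3utr
        d5 = "" if gd.depth_5cds is None else gd.depth_5cds
        out.write(f"{gid}\t{d3}\t{d5}\n")


def read_gene_depth_tsv(stream: str | TextIO) -> dict[str, GeneDepth]:
    handle = io.StringIO(stream) if isinstance(stream, str) else stream
    header = handle.readline().rstrip("\n").split("\t")
    if header != ["gene_id", "depth_3utr", "depth_5cds"]:
        raise CoverageError(f"gene-depth header mismatch: {header}")
    out = {}
    for line in handle:
        gid, d3, d5 = line.rstrip("\n").split("\t")
        out[gid] = GeneDepth(
            depth_3utr=int(float(d3)) if d3 not in ("", "None") else None,
            depth_5cds=int(float(d5)) if d5 not in ("", "None") else None)
    return out


OTHER = "OTHER"


def region_relative_coverage(target_records: Sequence[AlignmentRecord],
                             ts: TranscriptSet) -> dict[str, float]:
    """Reads per kilobase of region, per region class (plus non-mRNA remainder).

    A read is assigned to the region containing its midpoint; a midpoint
    sitting exactly on a boundary falls into the downstream (3') region by the
    half-open interval convention.  Reads on references that are not coding
    canonical transcripts count as OTHER, as does their length.
    """
    canonical = {tid: ts.transcripts[tid] for tid in ts.gene_to_canonical.values()}
    reads = {r: 0 for r in REGIONS} | {OTHER: 0}
    length = {r: 0 for r in REGIONS} | {OTHER: 0}
    for tid, tm in canonical.items():
        for region in REGIONS:
            length[region] += tm.region_length(region)
    for tid, seq in ts.sequences.items():
        if tid not in canonical:
            length[OTHER] += len(seq)
    for r in target_records:
        tm = canonical.get(r.reference)
        if tm is None:
            reads[OTHER] += 1
            continue
        m = r.midpoint
        for region in REGIONS:
            a, b = tm.region_intervals[region]
            if a <= m < b:
                reads[region] += 1
                break
        else:
            reads[OTHER] += 1
    return {cls: (reads[cls] / (length[cls] / 1000) if length[cls] else 0.0)
            for cls in reads}


def mirna_seed_correlation(ab: MirnaAbundanceTable,
                           mirna_intervals: Sequence[BedInterval],
                           mature_to_family: Mapping[str, str],
                           sites: Sequence[SeedSite],
                           profiles: Mapping[str, CoverageProfile]
                           ) -> tuple[float, float]:
    """Spearman correlation of per-family miRNA read density vs seed-site
    coverage density.

    miRNA density = family read count / total mature-locus length (per kb);
    site density = summed per-base depth within the family's sites / total
    site length.  Needs >= 3 families with defined site density.
    """
    locus_len: dict[str, int] = {}
    for iv in mirna_intervals:
        fam = mature_to_family.get(iv.name)
        if fam is not None:
            locus_len[fam] = locus_len.get(fam, 0) + (iv.end - iv.start)

    site_mass: dict[str, int] = {}
    site_len: dict[str, int] = {}
    for s in sites:
        prof = profiles.get(s.transcript_id)
        if prof is None:
            continue
        site_mass[s.family] = site_mass.get(s.family, 0) + int(
            prof.depth[s.t_start:s.t_end].sum())
        site_len[s.family] = site_len.get(s.family, 0) + s.length

    fams = sorted(f for f in ab.counts
                  if site_len.get(f) and locus_len.get(f))
    if len(fams) < 3:
        raise InsufficientDataError(
            f"need >= 3 families with seed-site coverage density, have {len(fams)}"
        )
    x = [ab.counts[f] / (locus_len[f] / 1000) for f in fams]
    y = [site_mass[f] / site_len[f] for f in fams]
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant input handled below
        rho, p = stats.spearmanr(x, y)
    if not np.isfinite(rho):
        raise InsufficientDataError("correlation undefined (constant density)")
    return float(rho), float(p)


def write_bedgraph(profiles: Mapping[str, CoverageProfile], out: TextIO) -> None:
    for ref in sorted(profiles):
        depth = profiles[ref].depth
        if depth.size == 0:
            continue
        change = np.flatnonzero(np.diff(depth)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [depth.size]))
        for s, e in zip(starts, ends):
            if depth[s]:
                out.write(f"{ref}\t{s}\t{e}\t{depth[s]}\n")
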