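"""Seed-match scanning.

A miRNA represses messages through Watson–Crick pairing of its *seed*
(nucleotides 2–8) to a complementary stretch in the target.  On the target
strand (written 5'->3' in DNA alphabet) the canonical site classes are:

* ``7mer-m8``  — reverse complement of miRNA positions 2–8;
* ``8mer``     — the 7mer-m8 followed by an adenosine opposite position 1;
* ``7mer-A1``  — reverse complement of positions 2–7 followed by that A.

Scanning is hierarchical: a locus matching the 8mer is reported once, as an
8mer, and never again as either contained 7mer.  6mer sites are deliberately
out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

from Bio.Seq import reverse_complement

from .transcriptome import REGIONS, THREE_UTR, TranscriptSet

EIGHTMER = "EIGHTMER"
SEVENMER_M8 = "SEVENMER_M8"
SEVENMER_A1 = "SEVENMER_A1"
SITE_TYPES = (EIGHTMER, SEVENMER_M8, SEVENMER_A1)

_SITE_LEN = {EIGHTMER: 8, SEVENMER_M8: 7, SEVENMER_A1: 7}


class SeedError(ValueError):
    pass


@dataclass
class SeedDescriptor:
    """Target-strand match patterns for one miRNA seed family."""

    family: str
    members: list[str]
    seed7: str  # miRNA nucleotides 2-8, DNA alphabet
    patterns: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.seed7) != 7:
            raise SeedError(f"{self.family}: seed must be 7 nt, got {self.seed7!r}")


@dataclass(frozen=True)
class SeedSite:
    gene_id: str
    transcript_id: str
    region: str
    t_start: int  # transcript coordinates, 0-based half-open
    t_end: int
    site_type: str
    family: str

    @property
    def length(self) -> int:
        return self.t_end - self.t_start


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def seed_from_mature(family: str, mature_seq: str,
                     members: Sequence[str] = ()) -> SeedDescriptor:
    """Derive the target-strand site patterns from a mature miRNA sequence.

    U and T are interchangeable on input; patterns are emitted in DNA.
    """
    seq = _normalize(mature_seq)
    if len(seq) < 8:
        raise SeedError(
            f"{family}: mature sequence must be >= 8 nt, got {len(seq)}"
        )
    seed7 = seq[1:8]                     # positions 2-8
    m8 = reverse_complement(seed7)       # 7mer-m8 on the target strand
    patterns = {
        SEVENMER_M8: m8,
        EIGHTMER: m8 + "A",
        SEVENMER_A1: reverse_complement(seq[1:7]) + "A",
    }
    return SeedDescriptor(family=family, members=list(members), seed7=seed7,
                          patterns=patterns)


def _find_all(seq: str, pattern: str) -> list[int]:
    hits, i = [], seq.find(pattern)
    while i != -1:
        hits.append(i)
        i = seq.find(pattern, i + 1)
    return hits


def scan_region(seq: str, sd: SeedDescriptor) -> list[tuple[int, str]]:
    """All seed-match loci in ``seq``, hierarchically typed, sorted by offset.

    An 8mer at offset *i* suppresses the 7mer-m8 at *i* and the 7mer-A1 at
    *i*+1 that it contains.  If the two 7mer patterns happen to be the same
    string, a match is reported once as 7mer-m8 (the stronger class).
    """
    seq = _normalize(seq)
    eight = set(_find_all(seq, sd.patterns[EIGHTMER]))
    m8 = sd.patterns[SEVENMER_M8]
    a1 = sd.patterns[SEVENMER_A1]
    hits = [(i, EIGHTMER) for i in eight]
    hits += [(i, SEVENMER_M8) for i in _find_all(seq, m8) if i not in eight]
    if a1 != m8:
        hits += [(i, SEVENMER_A1) for i in _find_all(seq, a1) if i - 1 not in eight]
    hits.sort()
    return hits


def build_site_table(ts: TranscriptSet, descriptors: Iterable[SeedDescriptor],
                     regions: Sequence[str] = REGIONS) -> list[SeedSite]:
    """Scan every canonical transcript's requested regions for every family.

    Offsets are lifted to transcript coordinates.  A match can never straddle
    a region boundary because each region sequence is scanned separately.
    Output order: (gene, region order 5'UTR/CDS/3'UTR, start, family).
    """
    region_order = {r: k for k, r in enumerate(REGIONS)}
    sites: list[SeedSite] = []
    for tm in ts.canonical_models():
        for region in regions:
            r0, _r1 = tm.region_intervals[region]
            seq = ts.region_sequence(tm.transcript_id, region)
            for sd in descriptors:
                for off, stype in scan_region(seq, sd):
                    sites.append(SeedSite(
                        gene_id=tm.gene_id, transcript_id=tm.transcript_id,
                        region=region, t_start=r0 + off,
                        t_end=r0 + off + _SITE_LEN[stype],
                        site_type=stype, family=sd.family,
                    ))
    sites.sort(key=lambda s: (s.gene_id, region_order[s.region], s.t_start, s.family))
    return sites


def read_mirna_table(stream: str | TextIO) -> tuple[list[SeedDescriptor], dict[str, str]]:
    """Read the miRNA TSV (columns: name, family, mature_sequence).

    Members sharing a family collapse onto one descriptor; a family whose
    members disagree on the seed is an error.  Returns the descriptors plus
    the mature-name -> family map.
    """
    import io as _io
    handle = _io.StringIO(stream) if isinstance(stream, str) else stream
    fam_members: dict[str, list[tuple[str, str]]] = {}
    for lineno, raw in enumerate(handle, start=1):
        line = raw.strip()
        if not line or line.startswith("#") or line.lower().startswith("name\t"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise SeedError(f"miRNA table line {lineno}: need name/family/sequence")
        name, family, seq = parts[0], parts[1], parts[2]
        fam_members.setdefault(family, []).append((name, seq))

    descriptors, mature_to_family = [], {}
    for family in sorted(fam_members):
        members = fam_members[family]
        sds = [seed_from_mature(family, seq, members=[name]) for name, seq in members]
        seeds = {sd.seed7 for sd in sds}
        if len(seeds) > 1:
            raise SeedError(f"family {family}: members carry different seeds {sorted(seeds)}")
        descriptors.append(SeedDescriptor(
            family=family, members=[n for n, _ in members],
            seed7=sds[0].seed7, patterns=sds[0].patterns,
        ))
        for name, _ in members:
            mature_to_family[name] = family
    return descriptors, mature_to_family


def write_site_tsv(sites: Sequence[SeedSite], out: TextIO) -> None:
    out.write("gene_id\ttranscript_id\tregion\tt_start\tt_end\tsite_type\tfamily\n")
    for s in sites:
        out.write(f"{s.gene_id}\t{s.transcript_id}\t{s.region}\t{s.t_start}\t"
                  f"{s.t_end}\t{s.site_type}\t{s.family}\n")


def read_site_tsv(stream: str | TextIO) -> list[SeedSite]:
    import io as _io
    handle = _io.StringIO(stream) if isinstance(stream, str) else stream
    header = handle.readline().rstrip("\n").split("\t")
    expected = ["gene_id", "transcript_id", "region", "t_start", "t_end",
                "site_type", "family"]
    if header != expected:
        raise SeedError(f"site table header mismatch: {header}")
    sites = []
    for line in handle:
        f = line.rstrip("\n").split("\t")
        sites.append(SeedSite(gene_id=f[0], transcript_id=f[1], region=f[2],
                              t_start=int(f[3]), t_end=int(f[4]),
                              site_type=f[5], family=f[6]))
    return sites


def write_site_bed(sites: Sequence[SeedSite], ts: TranscriptSet, out: TextIO) -> None:
    """Genomic BED6 of sites (name = family|site_type|region), exon-split."""
    for s in sites:
        tm = ts.transcripts[s.transcript_id]
        for gs, ge in tm.genomic_blocks(s.t_start, s.t_end):
            out.write(f"{tm.chrom}\t{gs}\t{ge}\t{s.family}|{s.site_type}|{s.region}"
                      f"\t0\t{tm.strand}\n")


def three_utr_site_genes(sites: Iterable[SeedSite]) -> set[str]:
    return {s.gene_id for s in sites if s.region == THREE_UTR}
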