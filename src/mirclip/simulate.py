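"""Synthetic transcriptome / CLIP / DE generator with exact ground truth.

Emulates the statistical structure of an AGO2 CLIP + knockout RNA-seq study:
a toy transcriptome of coding transcripts (5'UTR/CDS/3'UTR) on both strands,
seed-match sites planted into the 3'UTRs of a target subset, CLIP reads piled
on the bound sites over a uniform background plus a miRNA-derived read pool
with skewed family abundances, and a DE table in which bound seed-match genes
are up-shifted in the knockout.

Ground truth is defined by re-scanning the *emitted* sequences, not by the
planting intent, so seed matches arising by chance are recorded and cannot
corrupt downstream evaluation.  Every generator is a pure function of
(config, seed): identical inputs give byte-identical text outputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import seedscan
from .seedscan import EIGHTMER, SeedDescriptor, SeedSite
from .transcriptome import THREE_UTR, TranscriptModel, TranscriptSet, load_annotation

log = logging.getLogger(__name__)

# mature sequences for the default simulated miRNA pool (mouse); the target
# family miR-15/16 shares the AGCAGCA seed across its three members
DEFAULT_MIRNAS: list[tuple[str, str, str]] = [
    ("miR-142-3p", "miR-142", "UGUAGUGUUUCCUACUUUAUGGA"),
    ("miR-150-5p", "miR-150", "UCUCCCAACCCUUGUACCAGUG"),
    ("miR-16-5p", "miR-15/16", "UAGCAGCACGUAAAUAUUGGCG"),
    ("miR-15a-5p", "miR-15/16", "UAGCAGCACAUAAUGGUUUGUG"),
    ("miR-15b-5p", "miR-15/16", "UAGCAGCACAUCAUGGUUUACA"),
    ("miR-21a-5p", "miR-21", "UAGCUUAUCAGACUGAUGUUGA"),
    ("let-7g-5p", "let-7", "UGAGGUAGUAGUUUGUACAGUU"),
    ("miR-103-3p", "miR-103", "AGCAGCAUUGUACAGGGCUAUGA"),
]
# family abundance weights: miR-15/16 third-most abundant, mirroring the
# skewed repertoire of AGO2-loaded miRNAs in T cells
DEFAULT_FAMILY_WEIGHTS: dict[str, float] = {
    "miR-142": 0.30,
    "miR-150": 0.24,
    "miR-15/16": 0.17,
    "miR-21": 0.13,
    "let-7": 0.09,
    "miR-103": 0.07,
}
TARGET_FAMILY = "miR-15/16"


@dataclass
class SimConfig:
    """Study-structured simulation parameters.

    Lengths are nt ranges (inclusive); ``gc`` is the G+C base fraction;
    ``peak_reads`` the mean CLIP reads per bound site; ``bg_rate`` background
    reads per kb of transcript; ``mirna_read_share`` the fraction of all
    deduplicated reads that are miRNA-derived; ``de_effect`` the mean log2FC
    added to bound 3'UTR-site genes in the knockout; ``de_sigma`` the
    fold-change noise scale (per-replicate sd ``de_sigma/2``, so the observed
    log2FC noise sd is de_sigma/sqrt(total samples)); ``replicates`` per group.
    """

    n_genes: int = 500
    utr5_range: tuple[int, int] = (100, 300)
    cds_range: tuple[int, int] = (300, 1500)
    utr3_range: tuple[int, int] = (300, 1500)
    gc: float = 0.42
    n_target_genes: int = 50
    bound_fraction: float = 1.0
    peak_reads: float = 20.0
    bg_rate: float = 0.5
    mirnas: list[tuple[str, str, str]] = field(
        default_factory=lambda: list(DEFAULT_MIRNAS))
    family_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_WEIGHTS))
    target_family: str = TARGET_FAMILY
    mirna_read_share: float = 0.37
    # bound-site count for each non-target family; None scales the target
    # family's count by relative abundance weight, coupling occupancy to
    # abundance across the repertoire
    secondary_sites_per_family: int | None = None
    duplication_factor: int = 1
    de_effect: float = 1.0
    de_sigma: float = 0.5
    replicates: int = 4
    rpm_log_mean: float = math.log(50.0)
    rpm_log_sigma: float = 1.2
    rpm_floor: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.utr5_range, self.cds_range, self.utr3_range):
            if lo <= 0 or hi < lo:
                raise ValueError("length ranges must be positive and ordered")
        if not 0 <= self.bound_fraction <= 1:
            raise ValueError("bound_fraction must be in [0,1]")
        if self.de_sigma <= 0:
            raise ValueError("de_sigma must be > 0")
        if not 0 <= self.mirna_read_share < 1:
            raise ValueError("mirna_read_share must be in [0,1)")


@dataclass
class TruthTable:
    """Exact ground truth for one simulated dataset.

    ``genes`` has one row per gene: planted / bound flags, the planted site's
    transcript interval (-1 when absent), true_log2fc, and is_true_target
    (bound AND a 3'UTR seed site AND true_log2fc > 0).  ``sites`` is the
    post-hoc scan of the emitted sequences for the target family — the
    authoritative site set including chance matches.
    """

    genes: pd.DataFrame
    sites: list[SeedSite]
    descriptor: SeedDescriptor

    def true_targets(self) -> set[str]:
        g = self.genes
        return set(g.loc[g["is_true_target"], "gene_id"])


@dataclass(frozen=True)
class PlantedSite:
    family: str
    gene_id: str
    t_start: int
    t_end: int
    bound: bool


@dataclass
class SimulatedTranscriptome:
    fasta: str
    gtf: str
    ts: TranscriptSet
    truth: TruthTable
    # bound sites of the non-target families, for abundance-proportional
    # CLIP signal (no DE effect: only the target family is knocked out)
    secondary_sites: list[PlantedSite] = field(default_factory=list)


_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _descriptors(cfg: SimConfig) -> tuple[list[SeedDescriptor], dict[str, str]]:
    tsv = "\n".join(f"{name}\t{fam}\t{seq}" for name, fam, seq in cfg.mirnas)
    return seedscan.read_mirna_table(tsv)


def mirna_table_text(cfg: SimConfig) -> str:
    lines = ["name\tfamily\tmature_sequence"]
    lines += [f"{name}\t{fam}\t{seq}" for name, fam, seq in cfg.mirnas]
    return "\n".join(lines) + "\n"


def simulate_transcriptome(cfg: SimConfig) -> SimulatedTranscriptome:
    """Emit FASTA/GTF for a toy genome and the exact truth table.

    Each gene gets its own contig with 1–3 exons and a random strand; the
    target family's 8mer is planted at a random 3'UTR offset in
    ``n_target_genes`` randomly chosen genes.  Truth sites come from
    re-scanning the emitted region sequences.
    """
    rng = _rng(cfg, 1)
    descriptors, _ = _descriptors(cfg)
    target_sd = next(d for d in descriptors if d.family == cfg.target_family)
    pattern = target_sd.patterns[EIGHTMER]

    order = rng.permutation(cfg.n_genes)
    target_idx = set(order[: cfg.n_target_genes].tolist())

    # assign non-target-family bound sites to non-target genes so CLIP signal
    # scales with the whole miRNA repertoire, not just the knocked-out family
    sec_patterns: dict[int, list[str]] = {}
    non_target = [i for i in range(cfg.n_genes) if i not in target_idx]
    w_target = cfg.family_weights.get(cfg.target_family, 1.0)
    for sd in descriptors:
        if sd.family == cfg.target_family or not non_target:
            continue
        if cfg.secondary_sites_per_family is None:
            w = cfg.family_weights.get(sd.family, 0.0)
            k = int(round(cfg.n_target_genes * w / w_target))
        else:
            k = cfg.secondary_sites_per_family
        k = min(k, len(non_target))
        for i in rng.choice(non_target, size=k, replace=False):
            sec_patterns.setdefault(int(i), []).append(sd.family)

    fasta_parts: list[str] = []
    gtf_lines: list[str] = []
    planted: dict[str, tuple[int, int]] = {}  # gene -> transcript-coord site
    sec_planted: list[tuple[str, str, int, int]] = []  # (family, gene, t0, t1)
    flank = 20

    for i in range(cfg.n_genes):
        gene = f"G{i:04d}"
        tid = f"T{i:04d}"
        chrom = f"chr_{gene}"
        u5 = int(rng.integers(cfg.utr5_range[0], cfg.utr5_range[1] + 1))
        cds = int(rng.integers(cfg.cds_range[0], cfg.cds_range[1] + 1)) // 3 * 3
        u3 = int(rng.integers(cfg.utr3_range[0], cfg.utr3_range[1] + 1))
        tlen = u5 + cds + u3
        tseq = _random_seq(rng, tlen, cfg.gc)
        if i in target_idx:
            if u3 < len(pattern):
                raise ValueError(f"{gene}: 3'UTR too short for a planted site")
            off = int(rng.integers(0, u3 - len(pattern) + 1))
            t0 = u5 + cds + off
            tseq = tseq[:t0] + pattern + tseq[t0 + len(pattern):]
            planted[gene] = (t0, t0 + len(pattern))
        for fam in sec_patterns.get(i, ()):
            pat = next(d for d in descriptors if d.family == fam).patterns[EIGHTMER]
            if u3 < len(pat):
                continue
            for _attempt in range(20):
                off = int(rng.integers(0, u3 - len(pat) + 1))
                t0 = u5 + cds + off
                taken = [(a, b) for _f, g, a, b in sec_planted if g == gene]
                if all(t0 + len(pat) <= a or t0 >= b for a, b in taken):
                    tseq = tseq[:t0] + pat + tseq[t0 + len(pat):]
                    sec_planted.append((fam, gene, t0, t0 + len(pat)))
                    break

        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(1, 4))
        cuts = sorted(rng.choice(np.arange(1, tlen), size=n_ex - 1,
                                 replace=False).tolist()) if n_ex > 1 else []
        bounds = [0, *cuts, tlen]
        piece_lens = [b - a for a, b in zip(bounds, bounds[1:])]

        # lay exons on the contig in genomic order (transcript order reversed
        # for minus strand), separated by random introns
        genomic_pieces = piece_lens if strand == "+" else piece_lens[::-1]
        pos = flank
        g_exons: list[tuple[int, int]] = []
        for n in genomic_pieces:
            g_exons.append((pos, pos + n))
            pos += n + int(rng.integers(50, 201))
        chrom_len = g_exons[-1][1] + flank

        # contig sequence: random background, exon slots overwritten
        contig = list(_random_seq(rng, chrom_len, cfg.gc))
        exons_tx_order = g_exons if strand == "+" else g_exons[::-1]
        off_t = 0
        for gs, ge in exons_tx_order:
            piece = tseq[off_t: off_t + (ge - gs)]
            if strand == "-":
                piece = piece[::-1].translate(str.maketrans("ACGT", "TGCA"))
            contig[gs:ge] = list(piece)
            off_t += ge - gs
        fasta_parts.append(f">{chrom}\n{''.join(contig)}\n")

        # CDS genomic blocks via a throwaway model (no cds_span -> no regions)
        helper = TranscriptModel(gene_id=gene, transcript_id=tid, chrom=chrom,
                                 strand=strand, exons=exons_tx_order)
        attrs = f'gene_id "{gene}"; transcript_id "{tid}";'
        for gs, ge in sorted(g_exons):
            gtf_lines.append(f"{chrom}\tsim\texon\t{gs + 1}\t{ge}\t.\t{strand}\t.\t{attrs}")
        for gs, ge in helper.genomic_blocks(u5, u5 + cds):
            gtf_lines.append(f"{chrom}\tsim\tCDS\t{gs + 1}\t{ge}\t.\t{strand}\t.\t{attrs}")

    fasta = "".join(fasta_parts)
    gtf = "\n".join(gtf_lines) + "\n"
    ts = load_annotation(gtf, fasta, mode="genome")

    # truth from the emitted sequences, never from intent
    sites = seedscan.build_site_table(ts, [target_sd])
    genes_with_3utr = {s.gene_id for s in sites if s.region == THREE_UTR}
    bound_draw = _rng(cfg, 2)
    rows = []
    for i in range(cfg.n_genes):
        gene = f"G{i:04d}"
        is_planted = gene in planted
        bound = bool(is_planted and bound_draw.random() < cfg.bound_fraction)
        true_fc = cfg.de_effect if (bound and gene in genes_with_3utr) else 0.0
        t0, t1 = planted.get(gene, (-1, -1))
        rows.append({
            "gene_id": gene, "planted": is_planted, "bound": bound,
            "site_t_start": t0, "site_t_end": t1,
            "true_log2fc": true_fc,
            "is_true_target": bound and gene in genes_with_3utr and true_fc > 0,
        })
    truth = TruthTable(genes=pd.DataFrame(rows), sites=sites, descriptor=target_sd)
    secondary = [PlantedSite(family=f, gene_id=g, t_start=a, t_end=b,
                             bound=bool(bound_draw.random() < cfg.bound_fraction))
                 for f, g, a, b in sec_planted]
    return SimulatedTranscriptome(fasta=fasta, gtf=gtf, ts=ts, truth=truth,
                                  secondary_sites=secondary)


_UMI_BASES = list("ACGT")


def _umi(rng: np.random.Generator) -> str:
    return "".join(_UMI_BASES[k] for k in rng.integers(0, 4, size=2))


_PRE_PAD5 = 12   # precursor padding upstream of the mature locus
_PRE_PAD3 = 14
_PRE_COPIES = 4  # precursor loci per mature miRNA (multi-copy families)


def simulate_ahc(cfg: SimConfig, sim: SimulatedTranscriptome
                 ) -> tuple[str, str, str]:
    """Emit (SAM text, mature-miRNA BED text, miRNA table TSV).

    Bound target-family sites receive Poisson(peak_reads) reads of length
    U[18,40] covering the site; secondary-family sites receive reads at a rate
    proportional to family abundance weight; background reads are
    Poisson(bg_rate * length/1000) per transcript.  miRNA-derived reads map to
    two precursor loci per mature miRNA (as for genuine multi-copy families)
    with heterogeneous 5' ends; their number is chosen so that after collapse
    on (reference, start, strand, UMI) they make up ``mirna_read_share`` of
    the deduplicated pool in expectation.  Every read name carries a random
    dinucleotide UMI suffix; ``duplication_factor`` emits PCR copies sharing
    position and UMI.
    """
    rng = _rng(cfg, 3)
    ts = sim.ts
    truth = sim.truth

    refs: list[tuple[str, int]] = [(tid, len(seq))
                                   for tid, seq in sorted(ts.sequences.items())]
    reads: list[tuple[str, str, int, int, str]] = []  # (name, ref, start, L, seq)
    n_read = 0

    def _emit(ref: str, start: int, length: int, seq: str) -> None:
        nonlocal n_read
        name = f"r{n_read:07d}_{_umi(rng)}"
        n_read += 1
        reads.append((name, ref, start, length, seq))

    def _site_reads(gene_id: str, t0: int, t1: int, lam: float) -> None:
        tid = ts.gene_to_canonical.get(gene_id)
        if tid is None:
            return
        tseq = ts.sequences[tid]
        tlen = len(tseq)
        for _ in range(rng.poisson(lam)):
            length = int(rng.integers(18, 41))
            lo = max(0, t1 - length)
            hi = min(t0, tlen - length)
            if hi < lo:
                lo = hi = max(0, min(t0, tlen - length))
            start = int(rng.integers(lo, hi + 1))
            _emit(tid, start, length, tseq[start:start + length])

    # CLIP signal at bound target-family sites
    for row in truth.genes[truth.genes["bound"]].itertuples(index=False):
        if row.site_t_start >= 0:
            _site_reads(row.gene_id, row.site_t_start, row.site_t_end,
                        cfg.peak_reads)

    # secondary families: signal scaled by abundance weight
    w_target = cfg.family_weights.get(cfg.target_family, 1.0)
    for site in sim.secondary_sites:
        if site.bound:
            lam = cfg.peak_reads * cfg.family_weights[site.family] / w_target
            _site_reads(site.gene_id, site.t_start, site.t_end, lam)

    # uniform background
    for tid, seq in sorted(ts.sequences.items()):
        tlen = len(seq)
        if tlen < 18:
            continue
        for _ in range(rng.poisson(cfg.bg_rate * tlen / 1000)):
            length = int(rng.integers(18, min(41, tlen + 1)))
            start = int(rng.integers(0, tlen - length + 1))
            _emit(tid, start, length, seq[start:start + length])

    # deduplicated size of the target pool, for the miRNA share calculation
    n_target_dedup = len({(ref, start, name.rsplit("_", 1)[1])
                          for name, ref, start, _l, _s in reads})

    # miRNA-derived reads: several precursor loci per mature, 5'-end jitter of
    # +/-11 nt keeps every read >= 50% within the mature locus; the draw count
    # inverts the expected UMI/position saturation (coupon collector) so the
    # deduplicated share approximates mirna_read_share
    fams = sorted(cfg.family_weights)
    w = np.array([cfg.family_weights[f] for f in fams], float)
    w = w / w.sum()
    members = {f: [(n, s) for n, fam, s in cfg.mirnas if fam == f] for f in fams}
    share = cfg.mirna_read_share
    needed = share / (1 - share) * n_target_dedup if share else 0.0

    mir_refs: list[tuple[str, int]] = []
    pre_seq: dict[str, str] = {}
    bed_lines: list[str] = []
    for name, _fam, mseq in cfg.mirnas:
        dna = mseq.upper().replace("U", "T")
        for copy in range(1, _PRE_COPIES + 1):
            ref = f"pre_{name}_{copy}"
            seq = (_random_seq(rng, _PRE_PAD5, cfg.gc) + dna
                   + _random_seq(rng, _PRE_PAD3, cfg.gc))
            mir_refs.append((ref, len(seq)))
            pre_seq[ref] = seq
            bed_lines.append(
                f"{ref}\t{_PRE_PAD5}\t{_PRE_PAD5 + len(dna)}\t{name}\t0\t+")
    refs += mir_refs

    n_starts = 23  # m0-11 .. m0+11
    keys_per_copy = n_starts * 16
    for fi, fam in enumerate(fams):
        mem = members[fam]
        if not mem:
            continue
        for name, mseq in mem:
            dna = mseq.upper().replace("U", "T")
            for copy in range(1, _PRE_COPIES + 1):
                ref = f"pre_{name}_{copy}"
                want = needed * w[fi] / (len(mem) * _PRE_COPIES)
                want = min(want, 0.95 * keys_per_copy)
                if want <= 0:
                    continue
                n_draw = int(math.ceil(-keys_per_copy
                                       * math.log(1 - want / keys_per_copy)))
                for _ in range(n_draw):
                    start = _PRE_PAD5 + int(rng.integers(-11, 12))
                    length = int(rng.integers(22, 25))
                    seq = pre_seq[ref][start:start + length]
                    _emit(ref, start, len(seq), seq)

    # SAM text (single-end, plus strand, mapq 42)
    lines = ["@HD\tVN:1.6\tSO:unknown"]
    lines += [f"@SQ\tSN:{sn}\tLN:{ln}" for sn, ln in refs]
    for name, ref, start, length, seq in reads:
        for k in range(max(1, cfg.duplication_factor)):
            qname = name if k == 0 else f"{name.split('_')[0]}d{k}_{name.split('_')[1]}"
            lines.append(f"{qname}\t0\t{ref}\t{start + 1}\t42\t{length}M\t*\t0\t0\t{seq}\t*")
    sam = "\n".join(lines) + "\n"
    bed = "\n".join(bed_lines) + "\n"
    return sam, bed, mirna_table_text(cfg)


def simulate_de(cfg: SimConfig, truth: TruthTable) -> pd.DataFrame:
    """Knockout-vs-control DE table with planted de-repression.

    Per gene, per-replicate log2 expression offsets are Normal(true_fc, s) in
    the knockout and Normal(0, s) in control with s = de_sigma/2; log2FC is
    the group-mean difference and p comes from Welch-free two-sample t-tests.
    padj is Benjamini-Hochberg.  mean_rpm is log-normal with a floor so the
    expressed-gene filter has something to remove.
    """
    rng = _rng(cfg, 4)
    s = cfg.de_sigma / 2
    r = cfg.replicates
    genes = truth.genes["gene_id"].tolist()
    true_fc = truth.genes["true_log2fc"].to_numpy(float)

    ctrl = rng.normal(0.0, s, size=(len(genes), r))
    ko = rng.normal(0.0, s, size=(len(genes), r)) + true_fc[:, None]
    log2fc = ko.mean(axis=1) - ctrl.mean(axis=1)
    p = sps.ttest_ind(ko, ctrl, axis=1).pvalue
    p = np.nan_to_num(p, nan=1.0)
    padj = sps.false_discovery_control(p, method="bh")
    mean_rpm = np.maximum(cfg.rpm_floor,
                          rng.lognormal(cfg.rpm_log_mean, cfg.rpm_log_sigma,
                                        size=len(genes)))
    return pd.DataFrame({
        "gene_id": genes,
        "mean_rpm": np.round(mean_rpm, 4),
        "log2fc": np.round(log2fc, 6),
        "p": p,
        "padj": padj,
    })


def de_to_tsv(de: pd.DataFrame) -> str:
    return de.to_csv(sep="\t", index=False, float_format="%.6g")


def truth_to_tsv(truth: TruthTable) -> str:
    return truth.genes.to_csv(sep="\t", index=False)


@dataclass
class RecoveryResult:
    sensitivity: float | None
    precision: float | None
    fdr: float | None
    n_true: int
    n_called: int
    n_correct: int


def evaluate_recovery(calls, truth: TruthTable) -> RecoveryResult:
    """Sensitivity/precision of HIGH_CONFIDENCE_DIRECT calls against truth.

    With zero true targets sensitivity is flagged undefined (None); with zero
    calls precision is undefined.
    """
    from .stats import TIER_HIGH
    called = {c.gene_id for c in calls if c.tier == TIER_HIGH}
    true = truth.true_targets()
    n_correct = len(called & true)
    sens = n_correct / len(true) if true else None
    prec = n_correct / len(called) if called else None
    fdr = (1 - prec) if prec is not None else None
    return RecoveryResult(sensitivity=sens, precision=prec, fdr=fdr,
                          n_true=len(true), n_called=len(called),
                          n_correct=n_correct)
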