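"""End-to-end composition of the analysis stages.

``analyze`` is the pure library entry point: it takes parsed inputs
(transcripts, seed descriptors, alignments, DE table) and returns every
downstream result — site table, depth profiles, abundance, gene classes, the
de-repression statistics and tiered target calls.  ``run_simulation`` wires
the synthetic generator into it for a no-downloads full run with truth-based
recovery metrics.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import seedscan, simulate, stats
from .coverage import (AlignmentRecord, BedInterval, CoverageProfile,
                       GeneDepth, InsufficientDataError, MirnaAbundanceTable,
                       collapse_duplicates, partition_reads, family_abundance,
                       coverage as compute_coverage, gene_site_depth,
                       region_relative_coverage, mirna_seed_correlation,
                       read_sam, read_bed)
from .seedscan import SeedDescriptor, SeedSite
from .simulate import RecoveryResult, SimConfig, SimulatedTranscriptome
from .stats import Config, TargetCall
from .transcriptome import THREE_UTR, TranscriptSet

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    sites: list[SeedSite]
    profiles: dict[str, CoverageProfile]
    gene_depths: dict[str, GeneDepth]
    abundance: MirnaAbundanceTable
    region_coverage: dict[str, float]
    n_reads_raw: int
    n_reads_dedup: int
    de: pd.DataFrame
    classes: pd.DataFrame
    cdf: dict = field(default_factory=dict)
    depth_direction: dict = field(default_factory=dict)
    correlation: tuple[float, float] | None = None
    calls: list[TargetCall] = field(default_factory=list)
    recovery: RecoveryResult | None = None
    enrichment: stats.EnrichmentResult | None = None
    signature: stats.SignatureResult | None = None

    def call_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.calls:
            out[c.tier] = out.get(c.tier, 0) + 1
        return out


def analyze(ts: TranscriptSet,
            descriptors: Sequence[SeedDescriptor],
            mature_to_family: Mapping[str, str],
            records: Sequence[AlignmentRecord],
            mirna_intervals: Sequence[BedInterval],
            de: pd.DataFrame,
            config: Config | None = None,
            target_family: str | None = None,
            targetscan: Sequence[str] | None = None,
            signature: Sequence[str] | None = None,
            enrichment_set: Sequence[str] | None = None,
            dedup: bool = True) -> PipelineResult:
    """Run seed scan -> CLIP coverage -> DE integration on parsed inputs.

    ``target_family`` restricts site-based gene classing and target calls to
    one seed family (defaults to the sole descriptor, otherwise required).
    ``dedup`` can be switched off to quantify without UMI collapsing.
    """
    config = config or Config()
    if target_family is None:
        if len(descriptors) == 1:
            target_family = descriptors[0].family
        else:
            raise ValueError("target_family required with several descriptors")

    # CLIP side
    n_raw = len(records)
    deduped = collapse_duplicates(records) if dedup else list(records)
    mirna_reads, target_reads = partition_reads(deduped, mirna_intervals)
    abundance = family_abundance(mirna_reads, mirna_intervals,
                                     mature_to_family, len(deduped))
    ref_lengths = {tid: len(seq) for tid, seq in ts.sequences.items()}
    for r in deduped:  # non-transcript references (miRNA precursors etc.)
        if r.reference not in ref_lengths or (
                r.reference not in ts.sequences
                and r.end > ref_lengths[r.reference]):
            ref_lengths[r.reference] = max(r.end,
                                           ref_lengths.get(r.reference, 0))
    for iv in mirna_intervals:
        ref_lengths[iv.chrom] = max(ref_lengths.get(iv.chrom, 0), iv.end)
    profiles = compute_coverage(target_reads, ref_lengths)
    region_cov = region_relative_coverage(target_reads, ts)

    # seed side: all families scanned (for the abundance/site correlation),
    # target-family sites drive classing and calls
    all_sites = seedscan.build_site_table(ts, descriptors)
    sites = [s for s in all_sites if s.family == target_family]
    gene_depths = gene_site_depth(sites, profiles)

    try:
        correlation = mirna_seed_correlation(
            abundance, mirna_intervals, mature_to_family, all_sites, profiles)
    except InsufficientDataError as exc:
        log.info("miRNA/seed correlation skipped: %s", exc)
        correlation = None

    # DE integration
    classes = stats.classify_genes(de, sites, gene_depths,
                                   targetscan=targetscan, config=config)
    pairs = [(stats.SEED_3UTR, stats.NO_SEED),
             (stats.SEED_3UTR_AHC5, stats.NO_SEED)]
    if targetscan:
        pairs.append((stats.TARGETSCAN, stats.NO_SEED))
    cdf = {}
    try:
        cdf = stats.cdf_shift(de, classes, pairs)
    except InsufficientDataError as exc:
        log.info("CDF shift skipped: %s", exc)

    depth_dir = {}
    for scope in (THREE_UTR, "FIVE_CDS"):
        try:
            depth_dir[scope] = stats.depth_by_direction(de, classes, scope,
                                                        config=config)
        except InsufficientDataError as exc:
            log.info("depth-by-direction %s skipped: %s", scope, exc)

    calls = stats.call_targets(de, classes, config)

    enrichment = None
    if enrichment_set:
        ranked = de.sort_values("log2fc", ascending=False)
        try:
            enrichment = stats.enrichment_score(
                list(zip(ranked["gene_id"], ranked["log2fc"])), enrichment_set)
        except ValueError as exc:
            log.info("enrichment skipped: %s", exc)

    sig_result = None
    if signature:
        sig_result = stats.intersect_signature(de, classes, signature,
                                               config=config)

    return PipelineResult(
        sites=sites, profiles=profiles, gene_depths=gene_depths,
        abundance=abundance, region_coverage=region_cov,
        n_reads_raw=n_raw, n_reads_dedup=len(deduped),
        de=de, classes=classes, cdf=cdf, depth_direction=depth_dir,
        correlation=correlation, calls=calls, enrichment=enrichment,
        signature=sig_result,
    )


def run_simulation(cfg: SimConfig, config: Config | None = None,
                   enrichment_on_truth: bool = True
                   ) -> tuple[PipelineResult, SimulatedTranscriptome, pd.DataFrame]:
    """Simulate a dataset and push it through the full pipeline.

    The emitted text artifacts (SAM, BED, TSV) are parsed back through the
    same readers real data would use, so the simulation exercises the whole
    I/O surface.  Recovery metrics against the truth table are attached.
    """
    config = config or Config()
    sim = simulate.simulate_transcriptome(cfg)
    sam, bed, mirna_tsv = simulate.simulate_ahc(cfg, sim)
    de_full = simulate.simulate_de(cfg, sim.truth)

    descriptors, mature_to_family = seedscan.read_mirna_table(mirna_tsv)
    records = read_sam(io.StringIO(sam))
    intervals = read_bed(bed)
    de = stats.load_de_table(io.StringIO(simulate.de_to_tsv(de_full)), config)

    enrichment_set = sorted(sim.truth.true_targets()) if enrichment_on_truth else None
    result = analyze(sim.ts, descriptors, mature_to_family, records, intervals,
                     de, config=config, target_family=cfg.target_family,
                     enrichment_set=enrichment_set)
    result.recovery = simulate.evaluate_recovery(result.calls, sim.truth)
    return result, sim, de_full
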