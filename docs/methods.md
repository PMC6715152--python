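# Methods

## Model and procedure

miRNAs repress messages mainly through Watson–Crick pairing of their seed
(nucleotides 2–8) to sites in the 3′UTR. Loss of a miRNA family therefore
*de-represses* its direct targets: their knockout/control log₂ fold-change
distribution shifts right relative to genes without a seed match. CLIP of
AGO2 adds physical evidence: reads pile up where AGO2–miRNA complexes were
crosslinked, so seed matches under CLIP peaks are occupied sites rather
than incidental sequence. The pipeline formalizes this as a per-gene
evidence lattice:

    NONE  ⊃  SEED_ONLY (3′UTR 7mer/8mer)  ⊃  AHC_BOUND (site depth ≥ depth_min)
          ⊃  HIGH_CONFIDENCE_DIRECT (additionally p ≤ p_de and log₂FC > 0)

### Canonical transcript

Analyses are gene-level; one coding isoform represents each gene. The rule
is: longest annotated 3′UTR, then longest transcript, then lexicographically
smallest transcript id. The analysis is 3′UTR-centric, so maximizing the
scanned 3′UTR is the conservative choice for site discovery; it is a
declared convention, not an inference about any particular dataset.
Coordinates are 0-based half-open internally; GTF (1-based inclusive) is
converted on input, BED is written natively. Transcripts with a CDS but a
zero-length 3′UTR are kept (they contribute no 3′UTR sites); non-coding
transcripts are excluded from region analyses.

### Seed sites

From a mature sequence (U/T equivalent), the target-strand patterns are:
7mer-m8 = reverse complement of nucleotides 2–8; 8mer = 7mer-m8 + A;
7mer-A1 = reverse complement of nucleotides 2–7 + A. The A1 adenosine is
defined on the target strand in every region, including CDS/5′UTR scans.
Scanning is hierarchical with longest-match suppression: a locus matching
the 8mer is reported once as an 8mer, never additionally as either contained
7mer. 6mer and offset-6mer sites are excluded — weaker site classes would
dilute the depth-gated target calls. Families whose members share the seed
collapse to one descriptor (miR-15a/15b/16 are one family). Regions are
scanned independently, so a match straddling a region boundary is reported
in neither region; ambiguity codes (N) can never match.

### CLIP processing

Only primary alignments with MAPQ ≥ 10 enter the analysis (multimapper
policy). Duplicates collapse on (reference, start, strand, UMI), keeping the
first record; the 2-nt UMI is the randomized dinucleotide on the 3′ linker,
parsed from a `_NN` read-name suffix. Missing UMIs degrade to positional
collapse with a logged warning; a switch allows quantifying without
deduplication. A read is miRNA-derived iff ≥ 50% of its aligned span
overlaps a same-strand mature miRNA locus; the partition is exhaustive and
disjoint. Family abundances are read counts with dense descending ranks
(ties share the smaller rank) plus the global miRNA read fraction of the
deduplicated pool.

Site depth is the **maximum** per-base depth within the site span; a gene's
depth is the maximum over its sites, kept separately for 3′UTR and
5′UTR∪CDS. The depth gate (`depth_min = 5`) applies if any 3′UTR site
reaches it. Region-normalized coverage assigns each read to the region
containing its midpoint (boundary ties go 3′, the natural consequence of
half-open intervals) and divides by region length in kb; references that
are not coding canonical transcripts count as "other". The
abundance–occupancy correlation is Spearman's rank between per-family miRNA
read density (reads per kb of mature loci) and seed-site coverage density
(summed per-base depth within the family's sites over total site length);
it requires ≥ 3 families with defined densities.

### DE integration

The DE table (gene, mean RPM, log₂FC knockout/control, p, padj) is filtered
to expressed genes, mean RPM ≥ `rpm_min` (5, inclusive). Raw p drives the
significance gates (`p_de = 0.05` for direction and depth comparisons,
`p_sig = 0.1` for signature intersections), matching how such gates are
typically quoted; a flag switches every gate to adjusted p. A zero log₂FC
is "not significant" regardless of p.

The de-repression shift compares ECDFs of log₂FC per gene class against the
no-seed background. The two-sample Kolmogorov–Smirnov statistic (scipy,
exact/asymptotic automatic) and the median shift are reported alongside the
curves; the statistic is descriptive, and no multiple-testing correction is
applied across the (few, nested) class pairs. Depth-by-direction uses a
two-sided Mann–Whitney U on per-gene **maximum** depth (the summed
alternative was rejected to keep one depth definition throughout): exact
p by complete relabelling enumeration when both groups are ≤ 8, otherwise
the normal approximation with tie correction.

The enrichment score is the classic weighted running sum on a pre-ranked
list: hits step up by |score|^w (w = 1) normalized over hit scores, misses
step down by 1/(N − n_hits); ES is the signed largest absolute excursion
and the curve starts and ends at zero (within 1e-9). If every hit score is
zero, hits fall back to equal weights. An optional uniform permutation of
hit positions gives a p-value; permutation-based FDR is out of scope.

## Synthetic data

The generator emulates the statistical structure of an AGO2 CLIP + knockout
RNA-seq study with exact ground truth:

* **Transcriptome** — `n_genes` coding genes, one contig each, 1–3 exons,
  random strand; 5′UTR/CDS/3′UTR lengths uniform on (100–300, 300–1500,
  300–1500) nt at GC 0.42. The target family's 8mer is planted at a random
  3′UTR offset in `n_target_genes` genes (default 50/500). Non-target
  families receive bound 3′UTR sites in other genes, with counts and
  per-site read intensity both scaled by abundance weight, so CLIP occupancy
  tracks the repertoire as it does in real libraries. **Truth is the post
  hoc re-scan of the emitted sequences**, never the planting intent: chance
  seed matches are recorded and cannot corrupt evaluation.
* **CLIP** — bound sites receive Poisson(`peak_reads` = 20) reads of length
  U[18,40] covering the site; background is Poisson(0.5/kb) uniform per
  transcript. The default miRNA pool is six families (miRBase mouse mature
  sequences) with weights 0.30/0.24/0.17/0.13/0.09/0.07 placing miR-15/16
  third — the skewed AGO2 repertoire of T cells. miRNA reads map to four
  precursor loci per mature sequence with ±11 nt 5′-end jitter (every read
  keeps ≥ 50% overlap with the mature locus); because a 2-nt UMI saturates
  at point sources, the number of draws inverts the expected coupon-collector
  saturation so the *deduplicated* miRNA share approximates the nominal 37%.
  A duplication factor emits PCR copies that UMI collapse exactly undoes.
* **DE** — per-replicate log₂ expression offsets are Normal(true_fc, s) in
  knockout and Normal(0, s) in control with s = `de_sigma`/2, so observed
  log₂FC noise scales as de_sigma/√(total samples); p comes from two-sample
  t-tests on the per-replicate values (4 vs 4 by default), padj is
  Benjamini–Hochberg. Mean RPM is log-normal (median 50, σ_log 1.2, floor
  0.1), leaving a realistic minority of genes under the expressed-gene
  filter. With `de_effect` = 0 the p-values are uniform.

Every generator is a pure function of (config, seed): identical inputs give
byte-identical FASTA/GTF/SAM/TSV text.

**What the simulation does not model:** crosslink-induced truncations and
mutations, sequencing errors, isoform mixtures, batch effects, 3′-
supplementary pairing or thermodynamic site context, and DE count noise
beyond the Gaussian log-scale model. Passing tests therefore demonstrate
the correctness of the computation and its calibration under these
idealized conditions, not performance on real libraries, where peak calling
against structured background and context-dependent site efficacy matter.

## Numerical and design notes

* Exact Mann–Whitney enumerates C(n₁+n₂, n₁) relabellings (≤ 12870 at the
  8/8 cutoff); U uses midranks so U₁ + U₂ = n₁n₂ under ties.
* The KS statistic is invariant under common monotone transforms; the
  shift analysis is insensitive to the log base.
* Degenerate inputs fail loudly: classes with < 2 genes, empty direction
  groups, < 3 correlatable families, constant densities, empty gene-set
  intersections and malformed annotation lines all raise typed errors
  (the CLI maps them to exit code 1).
* Problem sizes in the test suite (500-gene recovery run, 200 replicate
  null draws, 100-seed false-call scan, 1000 scanner-oracle sequences) were
  chosen as the smallest sizes at which the binomial noise of the measured
  rates is well inside the asserted bands.
* Recovery metrics: sensitivity = |called ∩ true|/|true| over *all* true
  targets, so targets lost to the expressed-gene filter count against
  sensitivity; with zero true targets sensitivity is flagged undefined
  rather than reported as a number.

## Known limitations

* One canonical isoform per gene; isoform-aware quantification and UTR
  re-annotation are out of scope.
* No peak calling or crosslink-site inference — site occupancy is raw
  depth at seed matches, which is conservative for closely spaced sites.
* External prediction lists (e.g. TargetScan) and signatures are consumed
  as plain gene-ID lists and intersected with expressed genes; predictions
  are not recomputed, and list version bookkeeping is the caller's
  responsibility.
* Single-end alignments only.
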