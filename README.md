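# mirclip

Mapping a microRNA family's **direct target network** by combining three
orthogonal lines of evidence per gene:

1. **Seed-match scanning** — canonical 8mer / 7mer-m8 / 7mer-A1 sites
   (complementary to miRNA nucleotides 2–8) in the 5′UTR, CDS and 3′UTR of
   one canonical transcript per gene;
2. **AGO2 CLIP occupancy** — UMI-deduplicated AGO2 HITS-CLIP read depth at
   each seed-match site, with miRNA-derived reads partitioned out and the
   AGO2-loaded miRNA repertoire quantified per family;
3. **De-repression** — upregulation of the gene after knockout of the miRNA
   family, taken from a knockout-vs-control differential expression table.

A gene with a 3′UTR seed match, site depth ≥ 5 deduplicated reads, and
significant upregulation (p ≤ 0.05, log₂FC > 0) in the knockout is called a
**high-confidence direct target**. The package was built around the
miR-15/16 family in T cells (where such networks regulate cell cycle,
survival and memory differentiation) but works for any seed family.

## What it computes

Given annotation (GTF), sequence (FASTA), CLIP alignments (SAM), mature
miRNA definitions (TSV + BED loci) and a DE table (TSV), the pipeline
produces:

* the seed-match **site table** (hierarchically typed: an 8mer is never
  double-counted as its contained 7mers) and per-gene maximum site depth,
  split 3′UTR vs 5′UTR/CDS;
* per-family **AGO2-bound miRNA abundances** (fractions, dense ranks, global
  miRNA read share) and region-normalized CLIP coverage (reads/kb of 5′UTR,
  CDS, 3′UTR, other);
* the **de-repression shift**: empirical CDFs of log₂FC per gene class
  (no-seed background, 3′UTR seed, CLIP-supported subset, optional external
  prediction list), with two-sample Kolmogorov–Smirnov D/p and median shift;
* **depth by direction**: Mann–Whitney comparison of CLIP depth between up-
  and downregulated seed-match genes (exact enumeration for small groups);
* a pre-ranked, weighted running-sum **enrichment score** for any gene set
  against the log₂FC ranking;
* tiered **target calls** and gene-signature intersections;
* with simulated input, **recovery metrics** (sensitivity/precision) against
  exact planted truth.

A synthetic-data module generates a full study-structured dataset — toy
transcriptome, planted seed sites, CLIP reads with UMI duplicates and a
skewed miRNA repertoire, knockout DE table — so the entire pipeline is
testable without downloads.

## Worked example

```python
from mirclip.pipeline import run_simulation
from mirclip.simulate import SimConfig

cfg = SimConfig(seed=1)           # 500 genes, 50 planted miR-15/16 targets
result, sim, de = run_simulation(cfg)

ab = result.abundance
print(f"miRNA-derived read share : {ab.mirna_read_fraction:.2f}")
print(f"miR-15/16 abundance rank : {ab.rank_of('miR-15/16')}")
r = result.cdf[("SEED_3UTR", "NO_SEED")]
print(f"de-repression KS D       : {r.ks_d:.3f}  (p = {r.ks_p:.2e})")
print(f"median log2FC shift      : {r.median_shift:.3f}")
dd = result.depth_direction["THREE_UTR"]
print(f"up/down seed genes p<=.05: {dd.n_up}/{dd.n_down}  (Mann-Whitney p = {dd.p:.3g})")
rec = result.recovery
print(f"recovery                 : sensitivity {rec.sensitivity:.2f}, precision {rec.precision:.2f}")
```

prints

```
miRNA-derived read share : 0.36
miR-15/16 abundance rank : 3
de-repression KS D       : 0.613  (p = 2.75e-24)
median log2FC shift      : 0.916
up/down seed genes p<=.05: 50/2  (Mann-Whitney p = 0.0215)
recovery                 : sensitivity 0.98, precision 1.00
```

Reading: ~36% of deduplicated CLIP reads are miRNA-derived and miR-15/16 is
the third most abundant AGO2-loaded family; genes carrying a 3′UTR seed
match are strongly right-shifted in knockout log₂ fold change relative to
the no-seed background (KS D = 0.61); among significantly changed seed-match
genes, upregulated ones dominate (50 vs 2) and carry more CLIP depth; 49 of
the 50 planted targets are recovered as high-confidence direct targets with
no false calls.

The same run is available from the shell:

```bash
printf 'simulate:\n  seed: 1\n' > run.yaml
mirclip run --config run.yaml --out results/
```

which writes the site table, coverage bedGraph, abundance table, gene
classes, ECDF curves, target calls, truth table and a `summary.json` plus a
run manifest. `mirclip simulate` / `mirclip scan` expose the individual
stages for file-based inputs.

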