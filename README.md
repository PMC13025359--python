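# lcrqc

Low-coverage-region (LCR) detection and batch-effect QC for clinical
exome (ES) and genome (GS) sequencing depth profiles.

## The problem

A negative ES/GS result is only as trustworthy as the coverage behind
it. Even experiments with excellent *global* mean depth leave individual
coding intervals underpowered for variant detection, and those gaps can
silently hide pathogenic variants. `lcrqc` is for diagnostic and
research labs that want coverage gaps treated as a first-class QC
object: where they are, whether they are systematic to a sequencing
batch or platform, which genes they burden, and which known pathogenic
variants they could mask.

The pipeline consumes per-interval mean depth-of-coverage tables (one
mosdepth-style `regions` BED per sample, computed over a shared CDS
target design), never raw alignments.

## The model

For sample *s* and target interval *i* with mean depth of coverage
DoC(*s*, *i*):

* **LCR call** — interval *i* is an LCR in sample *s* iff
  DoC(*s*, *i*) < *t*, with *t* = 20x by default (strict inequality;
  10x and 30x are built-in sensitivity settings).
* **Assay concordance** — for a donor sequenced by both assays, with
  LCR sets *E* (ES) and *G* (GS), the Jaccard coefficient
  *J* = |*E* ∩ *G*| / |*E* ∪ *G*| measures whether the two approaches
  fail in the same places. Cohort-level structure is examined by PCA of
  the binary interval × sample LCR matrix, plus a one-sample Wilcoxon
  signed-rank test of per-donor *J* against 1.
* **Systematic LCRs (sLCRs)** — within a batch, depths are capped at
  *t* (so over-coverage carries no signal), averaged across the batch's
  samples per interval, and the per-interval batch means *m_i* are
  standardized across intervals: *z_i* = (*m_i* − mean(*m*)) / SD(*m*).
  Intervals with *z_i* < −1.96 (default; −1.64 and −2.58 as sensitivity
  settings) are flagged as systematically undercovered in that batch.
* **Gene burden** — LCRs are assigned to genes via a gene model
  (canonical transcript = longest CDS), counted per category (ES-only /
  GS-only / shared), normalized per kb of CDS, stratified by first
  coding exon vs other coding exons, and summarized as the fraction of
  CDS bases overlapped.
* **Clinical overlay** — recurrent LCRs (present in every sample of a
  cohort) are intersected with disease-gene lists (OMIM-morbid-like,
  SysNDD-like with evidence tiers) and with pathogenic-variant catalogs
  (VCF with a clinical-significance field).

A seeded simulator generates multi-batch, multi-assay cohorts with
planted systematic dropout, GC-dependent coverage depression, and
lognormal sample noise — plus a matching synthetic annotation bundle —
so every stage is testable against known ground truth.

## Worked example

`examples/02_assay_concordance.py` simulates 14 donors sequenced by
both ES (225x) and GS (64.4x) with disjoint planted assay-specific
dropout, and prints:

```
paired donors: 14
median Jaccard: 0.047  (1 = assays fail in identical intervals, 0 = disjoint failures)
one-sample Wilcoxon vs J=1: p = 6.10e-05
pooled unique intervals: 324 ES-only, 162 GS-only, 37 shared
PCA: PC1 explains 97.6% of variance; between-assay centroid distance / within-assay spread = 18.6
-> samples cluster by sequencing approach, not by donor: coverage failures are platform signatures.
```

The low median Jaccard says the two assays almost never fail on the
same intervals; the Wilcoxon p-value (the exact one-sided signed-rank
tail at n = 14) rejects concordance; and the PCA ratio shows samples
clustering by platform, not by donor. The other examples cover LCR
calling (`01`), batch z-score QC with Venn decomposition (`03`) and
gene burden / clinical annotation (`04`); each prints what the numbers
mean as it goes.

A thin CLI wraps the same library calls:

```bash
lcrqc simulate --scenario paired --seed 1 --out demo/
lcrqc call          --manifest demo/manifest.tsv --targets demo/targets.bed --out demo/call
lcrqc compare-assays --manifest demo/manifest.tsv --targets demo/targets.bed --out demo/cc
lcrqc batch-qc       --manifest demo/manifest.tsv --targets demo/targets.bed --out demo/bqc
```

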