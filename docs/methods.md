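# Methods

This note documents the statistical procedures, the defaults and the
design choices in `lcrqc`, in the order the pipeline applies them.

## Data model and coordinates

All analyses run on per-interval *mean* depth of coverage (DoC) over a
shared CDS target design — the output dialect of `mosdepth --by
regions.bed`. The package never touches alignments; per-base depth is
out of scope. Internally every coordinate is 0-based half-open (BED
convention). GTF input (1-based inclusive) is shifted on read; VCF
positions are shifted where compared against intervals. The join key
across samples is the literal string `chrom:start-end`, which is valid
because a cohort is by construction evaluated on one exact target set —
for the same reason, an interval missing from one sample's profile is a
hard error, never imputed as depth 0 (zero-fill would manufacture
LCRs).

## LCR calling

An interval is an LCR when its mean DoC is **strictly below** the
threshold; exactly 20.0x is adequate coverage. 20x is the conventional
minimum for confident germline heterozygous/homozygous calls; 10x and
30x are exposed for sensitivity analysis, and call sets are provably
nested across thresholds. No merging of adjacent low intervals is
performed: the interval grid is the unit of analysis throughout.

## Assay concordance

* **Jaccard** of two per-donor LCR sets; the two-empty-sets case is
  defined as 1.0 (no discordance exists). This case never arises in
  realistic data but must be fixed for the statistic to be total.
* **One-sample Wilcoxon signed-rank vs J = 1**, one-sided
  (alternative: concordance below 1). The exact null distribution is
  used for n ≤ 25 with no zero differences; otherwise the normal
  approximation with continuity correction. With n = 14 donors all
  below 1 the exact one-sided p is 2⁻¹⁴ ≈ 6.1 × 10⁻⁵, which is the
  test's resolution limit at that sample size.
* **Paired Wilcoxon** of per-donor ES-only vs GS-only counts
  (two-sided), **Spearman** correlation between those counts, and
  **Levene's test** in the median-centered Brown–Forsythe variant
  (robust to non-normal counts) for variance equality between assays.
* **PCA** of the binary interval × sample matrix with samples as
  observations: column-centered, unscaled. Centering without scaling is
  the standard treatment for presence/absence profiles; scaling would
  inflate near-constant intervals. Components are deterministic up to
  sign.

## Batch-systematic LCRs

Depths are capped at the LCR threshold *before* any averaging, so the
statistic responds only to undercoverage — an interval at 200x and one
at 21x are equally "fine". Capping applies to the per-interval mean
depths, because those are the data the pipeline carries; a per-base cap
followed by averaging would bound the capped mean from below and can
differ slightly for intervals straddling the threshold. This is the one
place where summarising at interval granularity is visible, and it is
deliberate: the detector's input and the caller's input stay identical.

Per interval, capped depths are averaged over the batch's samples, and
the resulting batch means are standardized **across intervals** (sample
SD, n−1). The alternative reading — standardizing each interval across
samples — cannot flag an interval that is uniformly low in every
sample, which is precisely what a systematic LCR is, so it would be
self-defeating; it remains available as `mode="pooled"` (standardize
against all capped sample×interval values) for comparison. z-scores
therefore have mean 0 and SD 1 over intervals by construction, and sLCR
sets are nested across cutoffs (−2.58 ⊆ −1.96 ⊆ −1.64).

Because z is standardized within batch, batches that differ only in
dropout *severity* at equal affected-interval counts produce nearly
identical z distributions; what separates batches in the rank-based
contrasts (Kruskal–Wallis, pairwise rank-sum with Benjamini–Hochberg
adjustment over each batch's sLCR z-scores) is the *number* and
structure of affected intervals.

Intra-batch consistency classifies an interval as consistent when its
binary LCR status agrees across every sample of the batch; the percent
is reported raw and rounded to the nearest 0.5 point (the granularity
of typical QC reports). Inter-batch structure is an exact Venn
decomposition of the batches' sLCR sets: region counts are disjoint and
sum to the union.

## Gene-level burden and GC

The ES ∪ GS LCR union is partitioned into ES-only / GS-only / shared.
Genes are represented by a **canonical transcript** (longest total CDS;
lexicographically smallest `transcript_id` on ties) — gene-level
aggregation needs one deterministic transcript, and longest-CDS is the
conventional choice. "Exon 1" means the first *coding* exon in
transcript orientation (strand-aware), not the genomic leftmost
segment. Intervals overlapping several genes count toward each, without
fractional splitting; base-level burden (fraction of CDS bases
overlapped) counts each base once regardless of how many LCR intervals
cover it. Per-kb rates are count × 1000 / CDS length.

Top-gene concentration ranks genes by total LCR count (ties: per-kb
rate, then gene id) and compares the observed share of LCRs in the top
k genes with the uniform expectation 100·k/G, where G is the number of
genes with ≥ 1 LCR.

GC content per interval is computed directly from FASTA with an
all-uppercase G+C count over the non-N length (all-N intervals are
flagged missing, not 0). Category GC distributions are compared by
Kruskal–Wallis followed by **Dunn's post hoc test** implemented from
pooled rank sums with the standard tie correction and two-sided normal
p-values, BH-adjusted across the three contrasts; with two groups it
reduces exactly to the uncorrected normal approximation of the Wilcoxon
rank-sum test, which is the cross-check used in the tests.

## Clinical annotation

"Recurrent" means present in 100% of the (assay-filtered) samples; a
lower recurrence fraction is exposed for exploration but defaults to
1.0. Gene-list joins are case-insensitive exact symbol matches — alias
resolution would need an external resource and is intentionally out of
scope; a cohort whose LCR genes match *no* list triggers a
symbol-mismatch warning instead of a silent zero. Variant overlap tests
the VCF POS base (converted to 0-based) against the half-open interval;
multi-base deletions are anchored at POS. Clinical-significance
matching is token-based and case-insensitive on `/ , |`-split labels,
so compound ClinVar labels like `Pathogenic/Likely_pathogenic` match
either component.

## The simulator

`synthetic_data` emulates the structure such a study observes, with all
randomness from one seeded generator (identical config ⇒ byte-identical
files):

* **Design**: 10,000 intervals by default, lognormal lengths (median
  ≈ 140 bp, clipped to [50, 2000]) laid across 22 chromosomes — CDS
  exon-like geometry.
* **Batches**: four ES batches at 229/117/117/126x with 10 samples
  each; the paired scenario uses 14 donors at ES 225x / GS 64.4x.
* **Planted systematic dropout**: 200 intervals per batch (250 ES /
  160 GS / 20 shared in the paired scenario), drawn disjointly, with
  expected depth multiplied by 0.05. This is the recoverable ground
  truth.
* **GC effect**: per-interval GC ~ Beta(8.1, 9.9) (mean 0.45); a
  piecewise-linear factor depresses depth outside GC ∈ [0.3, 0.6],
  with stronger slopes for ES-like capture (8 low-side / 5 high-side)
  than GS-like libraries (3 / 3), floored at 0.02. The slopes are
  chosen so that the GC tails, not the bulk, fall below threshold —
  reproducing the qualitative pattern that capture assays lose the
  GC extremes.
* **Noise**: multiplicative lognormal with sigma 0.2 on each sample's
  interval depth — depth is positive and right-skewed, and a
  multiplicative model keeps planted/GC structure intact in
  expectation.

What the simulator does **not** model: capture-probe geometry, mapping
ambiguity and segmental duplications, correlated noise along the
genome, per-base depth variation inside an interval, and indel/SNV
genotypes beyond planted annotation records. Tests passing on this
generator therefore certify the *statistical machinery* — thresholding,
standardization, set algebra, test plumbing — under a controlled data
model; they do not certify performance on the failure modes real
capture chemistry produces.

The annotation generator groups consecutive intervals into genes of 2–6
CDS exons (10% of genes get a second, shorter transcript to exercise
canonical selection), assigns 30% of genes to an OMIM-like list and 15%
to a SysNDD-like list with evidence tiers (definitive/moderate/limited
at 0.5/0.3/0.2), writes a FASTA whose per-interval GC matches the
ground truth, and plants pathogenic-labelled variants at the midpoints
of dropout intervals (benign/uncertain labels in unplanted intervals,
to exercise significance filtering).

## Numerical choices and degenerate inputs

* SDs use the n−1 denominator throughout.
* A batch whose capped batch means have zero variance is a "degenerate
  batch" error (nothing to standardize); a batch with < 2 samples is an
  error for both z-scores and consistency.
* Kruskal–Wallis on identical groups can return a tiny negative
  statistic with NaN p in floating point; this is clamped to (0, p=1).
* Wilcoxon with all-zero differences is reported as not applicable
  (`None`) rather than p = 1.
* Categories/batches contributing < 2 values to a rank test are
  excluded with a warning, not an error.
* Matrix row order is sorted `interval_id`; column order follows the
  manifest. When a donor appears in both assays, columns are keyed
  `sample_id.assay`.

## Problem sizes

The default test and reproduction runs use 10,000-interval universes
with 40-sample (batch) and 28-sample (paired) cohorts, 1,000 random
profiles for threshold-nesting checks, and 500 random instances per
brute-force oracle comparison. These sizes are large enough that the
planted-recovery and concordance statistics are stable to the third
decimal across seeds, while the whole suite runs in seconds.

## Known limitations

* Gene-level results depend on the canonical-transcript choice;
  exon-1 statistics in particular can shift under a different
  transcript selection policy.
* GC is computed from the reference FASTA, not from the reads.
* The interval-mean cap (vs per-base capping) slightly smooths
  intervals that straddle the threshold, as discussed above.
* Recurrent-LCR gene counts are computed gene-wise from the hosting
  intervals' genes; interval-wise counting would differ for genes
  sharing intervals.
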