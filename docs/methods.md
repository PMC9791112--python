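# Methods

## Setting and scope

The package models a targeted cfDNA methylation-sequencing study with very
small groups (3 cases vs 6 controls by default). It deliberately starts
*after* alignment: inputs are fragment tables, per-fragment methylation
summaries, beta-value matrices and electropherogram peak tables, all plain
text. Read processing (trimming, bisulfite/EM alignment, deduplication) is
out of scope; the only read-level filter retained is the mapping-quality
field check (MAPQ ≥ 20 generally, ≥ 30 for motif counting).

## Fragmentation index

Electropherogram peaks are sorted by size and swept left to right; a peak
merges with its predecessor when their relative difference
(larger − smaller)/smaller is below the sizing resolution of the band the
smaller peak lies in — 10% under 600 bp, 20% from 600 bp up. This is
single-linkage clustering: a chain of peaks each within resolution of its
neighbour counts once. Intensities are ignored; the index is the number of
clusters. Merging is monotone in the resolution: coarser resolution can
only reduce the index (property-tested). Sizes below 50 bp use the 10%
band; the rule is undefined by the instrument above 7000 bp and we keep 20%
there.

## End-motif frequency

The motif score of a 4-mer m is the fraction of quality-passing fragments
(MAPQ ≥ 30) whose 5'-end 4-mer equals m. Motifs containing N are excluded
from both numerator and denominator, which keeps the 256 canonical-motif
frequencies summing to exactly 1 and makes the single-motif query equal the
corresponding entry of the full frequency table. An input with no
quality-passing fragments yields NaN (undefined), never 0.

## DELFI score

Per region: short = fragments 100–150 bp, long = 151–220 bp, raw ratio =
short/long. Fragments are assigned to regions by midpoint containment
(unambiguous for fragments straddling region edges). Region GC is the mean
of fragment GC within the region — fragment-derived because the synthetic
regions have no reference sequence; with real data a reference-based region
GC can be supplied in the same column. The raw ratio is regressed on region
GC by LOESS (statsmodels lowess, span 0.75) and corrected as
residual + grand mean, each sample fitted independently. Regions with zero
long-fragment coverage are excluded; with fewer than five usable regions,
or a constant GC covariate, the correction is a no-op (raw ratios used,
logged). The sample score is the mean corrected ratio over usable regions;
a pooled-count mode (total short / total long) is available behind a flag.
The mean-over-regions default was chosen because it weighs targeted regions
equally and is the aggregation under which the GC correction acts.

## Panel design

**Moderated t.** Per CpG, a two-group comparison on beta values with
empirical-Bayes variance shrinkage: the gene-wise sample variances s² (df
d) are moment-matched on the log scale to a scaled-F prior, yielding prior
variance s₀² and prior df d₀ (d₀ = ∞ with the plain mean of s² as the
pooled variance when the observed spread is no wider than sampling alone);
the moderated variance is (d₀·s₀² + d·s²)/(d₀ + d) and the statistic is
referred to a t distribution with d₀ + d df, capped at the pooled residual
df. The implementation is cross-checked against R limma's `eBayes` to
1e-6 relative tolerance in the test suite. Setting the prior df to 0
recovers the ordinary two-sample t exactly.

**Selection.** Benjamini–Hochberg FDR (the limma default) on the moderated
p-values. Two DMP modes: *threshold* (|Δβ| > 0.3 and FDR < 0.05, both
strict, matching the stated inequalities) and *topN* (among FDR-passing
CpGs the 5000 largest |Δβ|; boundary ties broken by larger |Δβ|, then
smaller p, then CpG id, so output is deterministic).

**DMR merging.** Consecutive DMPs on one chromosome chain into a DMR when
their (probe-coordinate) distance is strictly less than 250 bp —
single-linkage, so a run with every consecutive gap < 250 bp is one DMR
regardless of total span. Output intervals are 0-based half-open; a
singleton DMP at 1-based position p becomes [p−1, p). Equivalence with a
transitive-closure oracle is property-tested.

**MCBs.** Scanning CpGs in genomic order, a block extends while the next
site is ≤ 100 bp away (inclusive) and its beta values correlate ≥ 0.95
(Pearson, inclusive) with the previous site across samples; blocks with
≥ 3 sites are emitted. A zero-variance site has no defined correlation and
breaks the chain. Equivalence with a maximal-qualifying-run oracle is
property-tested.

## Methylation scoring

Fragments qualify for the methylated fragment ratio when they cover ≥ 3
CpGs in the region and have conversion rate ≥ 95% (both inclusive). For a
region and sample, c is the number of qualifying fragments and MFR the
fraction of them fully methylated (n_meth = n_cpg); MFR is undefined (NaN)
at c = 0. The fragment-level mean beta reported in the metrics table is the
pooled ratio Σ n_meth / Σ n_cpg over qualifying fragments — the estimate of
the region's CpG-mean methylation available from fragment summaries.

Feature selection runs the moderated t per region on the chosen metric
(MFR by default; mean beta supported) between groups, keeping regions with
unadjusted p below α (0.05 or 0.01); regions with an undefined metric in
any sample are excluded.

Scoring standardises each sample's MFR against the baseline built from the
control group: Z_i = (x_i − μ_i)/σ_i. The control-sample Z uses an
inclusive baseline (its own value contributes to μ_i, σ_i) by default —
the simplest reading of "controls as baseline" — with a leave-one-out
option for the stricter variant. Z is converted to an upper-tail normal
p-value by default, because the panel targets hypermethylated regions and
disease is expected to raise MFR; a two-sided option exists. Features with
baseline σ below 1e-9 (numerically zero) are dropped for all samples;
features without qualifying fragments in a sample are dropped for that
sample. The weighted Fisher combination Σ −2 cᵢ ln pᵢ / Σ cᵢ uses the
sample's own fragment counts as weights; p-values are floored at 1e-300 so
the logarithm stays finite. The score is invariant to rescaling all weights
and monotone decreasing in every pᵢ (property-tested).

Feature selection and scoring use the same nine samples — the small-cohort
design being emulated has this circularity, and the pipeline reproduces it
rather than hiding it; the LOOCV stage is the guard against over-reading
the resulting separation.

## Exact group statistics

For combined samples of ≤ 12 tie-free values the two-sided rank-sum p is
exact: U = #{(x,y): x > y}, and p = 2·min(P(U ≤ u), P(U ≥ u)) capped at 1,
with the U distribution obtained by enumerating all C(n₁+n₂, n₁) rank
assignments. Tail doubling (rather than summing deviations) is the
convention chosen; for 3 vs 6 the attainable minimum is 2/84 ≈ 0.0238.
Ties or larger samples fall back to the normal approximation with tie and
continuity correction (cross-checked against scipy's asymptotic
Mann–Whitney U). Spearman correlation and the uncorrected 2×2 Pearson
chi-square wrap scipy.

## Classification

Leave-one-out CV over the sample-by-feature MFR matrix with four
deliberately untuned models: logistic regression (sklearn defaults),
decision tree (entropy criterion), random forest (30 trees), SVC with
probability output. Held-out probabilities are thresholded strictly
(score > t): 0.63 logistic, 0 decision tree (degenerate by construction —
any positive probability calls a case), 0.23 random forest, 0.2 SVC (0.24
for MFR-derived features, stored as a preset). Fold models are retained so
tests can verify the held-out sample never influences its own fold.

## Synthetic data generator

The generator emulates the study conditions, not a particular dataset:

* **Cohort shape** — 3 cases vs 6 controls, 100 regions of 1 kb on one
  synthetic chromosome, 10 000 fragments per sample.
* **Fragment lengths** — a two-component truncated-normal mixture: short
  N(135, 10²) on [100, 150], long N(166, 15²) on [151, 220] (166 bp being
  the mononucleosomal mode of plasma cfDNA). Default short-fragment weights
  0.47 (case) and 0.43 (control) are back-derived from representative mean
  short:long coverage ratios of 0.897 and 0.763 via p = r/(1+r).
* **GC** — fragment GC ~ N(0.5 + 0.2·(160 − L)/60, 0.03²), i.e. GC drifts
  with fragment length, so regions that happen to be short-rich also drift
  in mean GC — exactly the confounding the LOESS step must remove.
* **Methylation** — control region methylation probabilities ~ U(0.1, 0.5);
  cases add meth_shift = 0.2 (clipped to [0, 1]), a realistic regional
  hypermethylation difference. Per fragment the covered-CpG count is
  truncated Poisson(4) ≥ 1, methylated counts are binomial, and conversion
  rate ~ Beta with mean 0.99 (concentration 100), so the ≥ 3-CpG and ≥ 95%
  filters both bite occasionally.
* **End motifs** — a fixed distribution over the 256 4-mers, uniform with
  CCCA enriched to ≈ 0.019, the magnitude typical of plasma cfDNA.
* **Electropherograms** — peaks at 166 and 332 bp plus a Poisson(3) number
  of log-uniform extra peaks within the 35–10380 bp marker range, sizes
  jittered by ≤ 2%.
* **Beta matrices** — CpGs in clusters of five sharing a latent factor
  (adjacent correlation ≈ 0.96), inter-site gaps drawn from
  {30, 60, 90, 150, 300, 600} bp so both the 100 bp MCB and 250 bp DMR
  thresholds are exercised; planted DMPs occupy whole clusters and add the
  requested tumor-minus-blood Δβ.

What the generator does **not** emulate: sequence-specific fragmentation
(end motifs are independent of position), copy-number or coverage
variation, per-CpG methylation heterogeneity within a region, batch
effects, and array-specific artefacts. Passing tests therefore demonstrate
that the statistical machinery recovers planted effects under the model's
own assumptions — not that the pipeline is robust to every artefact of real
plasma sequencing.

## Numerical choices and problem sizes

Determinism: every generator consumes a single numpy `default_rng(seed)`;
identical seeds give byte-identical output files (fixed float formatting:
GC and conversion to 4 decimals, betas to 6). Simulation-based tests use
100 regions × 10 000 fragments × 9 samples and 20–50 seeds, sizes at which
the planted effects are comfortably detectable and the whole suite runs in
about a minute; the moderated-t null calibration uses 2000 features ×
12 samples. Degenerate inputs are signalled rather than silently zeroed:
undefined ratios return NaN, invalid configurations raise, and each
pipeline stage re-raises failures labelled with the stage name.

## Known limitations

* The exact rank-sum path handles ties by falling back to the
  approximation; an exact tie-permutation distribution is not implemented.
* The moderated t assumes (approximate) normality of beta values; for
  betas near 0 or 1 an M-value transform would be preferable and is not
  provided.
* MCB chaining uses adjacent-pair correlation only, the stated definition;
  blocks are not re-validated for all-pairs coherence.
* SVC probabilities come from libsvm's internal Platt scaling, which is
  noisy at n = 8 training samples; thresholds are presets, not calibrated.
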