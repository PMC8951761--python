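# Methods

## Problem and model

X-chromosome inactivation (XCI) silences one X per female cell; the
population-level split between the two parental X chromosomes is the XCI
pattern, written as a ratio such as [75:25]. The package determines this
pattern from methylation-sensitive fragment analysis at a polymorphic repeat
locus: genomic DNA is split into a mock (undigested) and a
methylation-sensitive-endonuclease-treated (digested) reaction, both are
PCR-amplified across the repeat, and the products are sized on capillary
electrophoresis. Unmethylated (active-X) templates are cut and drop out of
the digested channel, so for a heterozygous sample the digested/undigested
signal ratio of each allele measures the fraction of cells in which that
allele's X is inactive.

Two assay flavours are supported: the HUMARA design on the *AR* exon-1 CAG
repeat ("Assay A", quantified on peak areas, digested and undigested run as
separate single-dye reactions) and a methylation-PCR design on the *FMR1*
promoter CGG repeat ("Assay B", FAM/HEX duplex, quantified on peak heights).
Both reduce at parse time to the same two-channel representation; dye
identity is discarded because the downstream mathematics only needs
digested vs undigested.

For alleles i = 1, 2 with per-allele signals u_i (undigested) and d_i
(digested) on the configured quantity:

    r_i       = d_i / u_i
    percent_i = 100 · r_i / (r_1 + r_2)
    skew      = max(percent_1, percent_2)  ∈ [50, 100]

The per-allele division cancels each allele's amplification efficiency, so
the estimator is exact under pure length-dependent amplification bias; the
sum normalisation makes the two percentages complementary. Both assay
flavours use the same cross-allele normalisation so that results are always
x:y pairs summing to 100. Display ratios are integers (largest-remainder
rounding, allele order ascending by repeat count); all logic uses unrounded
values.

## Classification and the stepwise QC decision

Skew is classified against three boundaries (b1, b2, b3), upper endpoints
closed:

| category            | range            | Assay B default | Assay A default |
|---------------------|------------------|-----------------|-----------------|
| random              | 50 ≤ s ≤ b1      | b1 = 75         | b1 = 80         |
| moderately skewed   | b1 < s ≤ b2      | b2 = 89         | b2 = 90         |
| highly skewed       | b2 < s ≤ b3      | b3 = 99         | b3 = 99         |
| completely skewed   | b3 < s ≤ 100     |                 |                 |

The Assay A boundaries are a documented assumption (the HUMARA cut-offs in
routine use are laboratory-specific); they are overridable in the YAML
config, as are all thresholds below. A result within ±2 percentage points
(`borderline_margin`) of any boundary is borderline: still categorised, but
not accurately defined. Note that with b3 = 99 every completely skewed
result is by construction within the borderline margin of b3; borderline
accounting therefore reports per-boundary proximity, not a judgement that
such results are wrong.

`stepwise_call` applies the decision sequence per sample × assay, in order:

1. one allele → `UNINFORMATIVE_HOMOZYGOUS` (no category);
2. allele repeat difference ≤ 2 → `UNRELIABLE_STUTTER`: the larger allele's
   minus-one-repeat stutter band overlaps the smaller allele's primary band
   and corrupts its quantification. The category is still computed (for
   concordance tables) but marked unusable; the caller flags rather than
   attempts a stutter correction, since the overlapped band cannot be
   decomposed from peak-table data;
3. repeat difference ≥ 7 with fewer than 3 replicates →
   `TRIPLICATE_REQUIRED`: preferential amplification of the shorter allele
   makes a single replicate untrustworthy; the mean of triplicates is used
   whenever replicates are available;
4. undigested imbalance max(u1,u2)/min(u1,u2) > 1.3 on the replicate-mean
   signals → `BIASED` (the 1.3-fold limit is inclusive);
5. borderline skew → `BORDERLINE`;
6. otherwise `OK`.

Replicates must agree on the called genotype; their percentages are
averaged (arithmetic mean of percent_1) before classification.

## Allele calling

Peak sizes are converted to repeat counts by nearest-integer rounding of
(size − offset)/unit, ties away from zero; the offset (fragment length at
zero repeats) is a kit calibration constant that cancels from every
downstream rule, with defaults of 170 bp (CAG, unit 3 bp) and 230 bp (CGG).
In the undigested channel, a peak is absorbed as stutter when it sits
exactly one repeat below a taller peak and is smaller than
`stutter_fraction_max` (default 0.15) of it; the tallest peak and the
tallest remaining non-stutter peak become the alleles, and more than two
non-stutter peaks raises an ambiguous-genotype error for manual review.
Equal-height candidates are ordered by stutter support then smaller size,
for determinism. Digested peaks are paired by repeat equality (sub-half-
repeat sizing discrepancies are absorbed by the shared rounding); an
unmatched allele has digested signal 0, i.e. is called fully unmethylated.

## Concordance statistics

* **Chi-square homogeneity** on per-category counts of two assays, with the
  expected count per category taken as the two-assay mean. This is the
  decomposition under which the per-category partials each carry 1 df and
  sum to the total; the overall test is reported with df = k − 1, and the
  report notes the df convention. Zero-total categories contribute 0 and
  are excluded from df, with a warning.
* **Two-sample Kolmogorov–Smirnov** on per-category values. D is the exact
  ECDF supremum distance; the p-value uses the asymptotic Kolmogorov series
  2·Σ (−1)^(j−1) exp(−2 j² λ²) at Stephens' corrected argument
  λ = (√ne + 0.12 + 0.11/√ne)·D with ne = nm/(n+m), clamped to [0, 1].
  Counts and percentages give the same D (the statistic is invariant to
  strictly increasing transforms); per-sample values would not, and the
  report says which convention was used. An exact-enumeration p-value is
  available for tie-free samples with n·m ≤ 100.
* **Brown–Forsythe** replicate-variance homogeneity: one-way ANOVA on
  absolute deviations from group medians (scipy's median-centred Levene
  test), with a degenerate-data error when every deviation is zero. With 8
  samples in triplicate, df_between = 7.
* **Shapiro–Wilk** normality for 3 ≤ n ≤ 5000 (scipy implementation).
* **Concordance summary**: 4×4 category confusion matrix over samples
  categorised by both assays, concordant fraction = trace/total, and
  per-assay accounting of uninformative (homozygous), borderline and
  combined "not accurately defined" fractions.

## Synthetic data generator

The simulator emulates the statistical structure the analysis assumes, with
every constant configurable:

* **True skew**: a fraction of samples (default 0.75) is "random", with the
  allele-1 inactivation fraction p drawn from Beta(20, 20) (SD ≈ 0.078
  around 0.5, spanning roughly the [50:50]–[70:30] range); the rest draw a
  skew uniformly from 0.76–0.99 with the favoured allele randomised. The
  two alleles' methylation levels are exactly complementary (m1 + m2 = 1):
  escape from XCI is not modelled.
* **Amplification efficiency** decays geometrically at
  `efficiency_decay_per_repeat` = 0.038 per repeat, calibrated so a
  7-repeat gap produces an undigested imbalance of (1/0.962)^7 ≈ 1.31 —
  just past the 1.3 QC limit, reproducing the large-gap failure mode.
* **Stutter**: each allele peak casts a minus-one-repeat band at
  `stutter_ratio` (default 0.10) of its parent, in both channels, summed
  onto any coincident allele peak. Minus-two stutter is available but off
  by default. With a one-repeat gap the leak makes the small allele's ratio
  a convex mixture of the two methylation levels — contracting the observed
  skew toward 50, strongly when the larger allele is the methylated one and
  only mildly in the mirror case, where the two channels' leaks nearly
  cancel. This is the algebraic oracle the stutter tests assert.
* **Replicate noise**: every per-allele, per-channel signal carries a
  lognormal factor with mean 1 and CV `noise_cv` (default 0.10, a typical
  capillary-electrophoresis replicate variation consistent with low
  internal reproducibility between replicates). Assay A's separate digested
  reaction gets extra per-allele lognormal jitter (default CV 0.05); a
  tube-level factor shared by both alleles would cancel exactly in the
  sum-normalised percentages, so only allele-level reaction noise is
  observable downstream.
* Peak areas are a fixed multiple of heights, so area- and height-based
  quantification see identical ratios; repeat ranges default to 15–35 (CAG)
  and 20–45 (CGG), uniform without population structure.

`make_paper_like_cohort` produces (a) a 48-sample study-like cohort with a
36/6/6/0 category mix, four small-gap (≤2) genotypes placed on
random-pattern samples and five large-gap (≥7) genotypes, with true skews
drawn inside category bands and away from borderline zones so the mix is
exactly recoverable when noise is off; and (b) a 74-sample
retrospective-like cohort with ~11% homozygotes and the retrospective
category mix over full bands, so borderline results arise naturally.

What the simulator does **not** model: raw electropherogram traces,
instrument saturation, allele dropout, size-standard miscalibration,
expanded (>55 CGG) alleles, AGG interruptions, mosaicism, and XCI escape.
Passing tests therefore demonstrate correctness of the decision logic and
estimators under the stated generative assumptions, not performance on
every artefact of real capillary data.

## Numerical and design choices

* Rounding of repeat counts: half away from zero; of display ratios:
  largest remainder (ties to allele 1).
* Monte-Carlo designs: the replicate-averaging experiment uses 1000 trials
  of 20-sample cohorts (gaps 3–6, noise CV 0.1) and compares cohort-level
  mean absolute skew error of triplicate means vs single replicates; the
  cohort-level comparison is the quantity of interest because a
  single-sample comparison of |mean error| vs one replicate's error is
  dominated by folded-noise fluctuations. Noiseless recovery is checked to
  1e-9 (measured ~1e-14, pure float roundoff).
* Stutter-heavy simulations (stutter ratio 0.3) are analysed with
  `stutter_fraction_max` = 0.4, matching the filter to the simulated
  stutter intensity; with the default 0.15 threshold such cohorts are
  rejected as ambiguous genotypes rather than called, which is itself the
  correct behaviour for a filter calibrated to ~10% stutter.
* Supplied peak areas are treated as final (no baseline correction).
* QC failures are data, not errors: the CLI writes them as rows with a
  status, and exits non-zero only for unusable inputs.

## Known limitations

* The stutter model is minus-one-repeat only; the caller flags overlapped
  genotypes instead of deconvolving them.
* The chi-square df convention (partials each df = 1, total reported at
  df = k − 1) is a reporting convention of the validation design, not a
  textbook contingency test; both are printed in the report.
* Assay A category boundaries ship as assumptions and should be replaced by
  the laboratory's validated HUMARA cut-offs.
* With b3 = 99 and margin 2, completely skewed results are always
  borderline-adjacent; interpret the borderline flag per boundary.
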