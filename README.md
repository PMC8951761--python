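# xciskew

Determination of the X-chromosome inactivation (XCI) pattern from
methylation-sensitive fragment-analysis peak data.

## Who this is for

Clinical and research molecular-genetics laboratories that assess XCI
skewing — e.g. for X-linked disease carrier studies — using either the
classical HUMARA design on the *AR* CAG repeat ("Assay A") or a
methylation-PCR design on the *FMR1* promoter CGG repeat ("Assay B"). The
package takes GeneMapper-style peak tables (sample, assay, replicate,
digested/undigested channel, fragment size, peak height and area), calls
alleles, quantifies per-allele methylation, classifies the XCI pattern, and
applies a stepwise quality-control decision so that unreliable results are
flagged instead of silently reported.

## The estimator

For a heterozygous sample, each allele's digested/undigested signal ratio
estimates the fraction of cells in which that allele's X is inactive
(methylated templates survive methylation-sensitive digestion):

    r_i = d_i / u_i,      percent_i = 100 · r_i / (r_1 + r_2)
    skew = max(percent_1, percent_2)  ∈ [50, 100]

Skew is classified as **random** (≤ 75 for Assay B), **moderately skewed**
(≤ 89), **highly skewed** (≤ 99) or **completely skewed** (> 99), with
results within ±2 points of a boundary flagged *borderline*. The stepwise QC
reports a result as `OK` only when the alleles differ by more than two
repeats (no stutter-band overlap) and fewer than seven (no strong
preferential amplification — otherwise triplicates are required and
averaged), the undigested allele signals are balanced within 1.3-fold, and
the skew is outside borderline limits.

A synthetic peak-data generator with known ground truth (true skew,
repeat-length-dependent amplification efficiency, minus-one-repeat stutter,
digestion proportional to methylation, lognormal replicate noise) makes the
whole pipeline testable without instrument data. See `docs/methods.md` for
the model, parameters and limitations.

## Worked example

Given `peaks.tsv` for one sample (Assay B, one replicate; sizes 302/320 bp
are 24 and 30 CGG repeats at the default calibration):

```text
sample_id	assay	replicate	channel	size_bp	height	area
P1	B	1	undigested	302	1520	4864
P1	B	1	undigested	320	1410	4512
P1	B	1	digested	302	1216	3891
P1	B	1	digested	320	282	902
```

```sh
xci call --peaks peaks.tsv --out calls
```

produces `calls/calls.tsv`:

```text
sample_id  assay  n_replicates  repeats  repeat_difference  bias_ratio  percent_allele1  percent_allele2  ratio    skew  category           borderline  status  error
P1         B      1             24/30    6                  1.078014    80.0             20.0             [80:20]  80.0  MODERATELY_SKEWED  False       OK
```

Reading the row: allele ratios are r₁ = 1216/1520 = 0.80 and
r₂ = 282/1410 = 0.20, so 80% of cells inactivate the X carrying the
24-repeat allele — a [80:20], moderately skewed pattern. The repeat gap (6)
is in the safe 3–6 window, the undigested signals are balanced
(1.08 ≤ 1.3), and 80 is more than 2 points from every boundary, so the
result is usable (`OK`).

The other entry points are `xci simulate --preset study --seed 7 --out sim`
(synthetic cohort with ground truth) and
`xci compare --a callsA.tsv --b callsB.tsv --out cmp`, which writes the
between-assay category counts, per-category and total chi-square,
Kolmogorov–Smirnov D and p, the category confusion matrix and the
concordance/accounting percentages as TSV + JSON. The same functionality is
available as a library (`xciskew.stepwise_call`, `xciskew.chi2_homogeneity`,
`xciskew.simulate_cohort`, ...).

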