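# Methods

This note documents the statistical model behind `snpqc`, the defaults and
numerical conventions it commits to, and what its synthetic-data generator
does and does not emulate.

## Individual-level allele frequencies

The within-individual relative abundance of allele A at a SNP is estimated
from the allele-specific hybridization intensities `(I_A, I_B)`. Because the
two allele probes rarely hybridize with equal efficiency, the raw fraction
`I_A / (I_A + I_B)` is biased for heterozygotes. The per-SNP coefficient of
preferential amplification/hybridization (CPA), `kappa_m`, is the
arithmetic mean of `I_A / I_B` over samples called heterozygous at SNP m
(with `I_B > 0`); the adjusted AF

    lambda = I_A / (I_A + kappa_m * I_B)

then equals 0.5 exactly when `I_A = kappa_m * I_B`, i.e. heterozygotes are
calibrated onto the middle band, and the estimate is invariant to joint
rescaling of both channels. Defaults and edge rules:

* `min_het = 3`: below three usable heterozygotes the ratio mean is too
  unstable, so `kappa` falls back to 1 (no adjustment) and the SNP is
  flagged; the flag travels with the persisted CPA table.
* `lambda` is clipped to [0, 1] rather than rejected: background noise can
  push intensities slightly past the pure-allele bounds, and clipping
  preserves the cell while bounding the distance it can contribute.
* Cells with `I_A + kappa * I_B = 0` are missing.

CPA tables may be computed from the study samples themselves or loaded from
a reference file, so a fixed per-platform calibration is equally supported.

## AF references

An AF reference stores, per SNP and genotype class (AA/AB/BB), the mean
`mu_G` and sample SD `sigma_G` (n − 1 denominator) of individual-level AFs
over reference samples with that called genotype and a non-missing AF. A
cell is *eligible* for index computation only if it rests on at least
`min_count = 3` samples and `sigma_G > sd_floor = 1e-4`. Ineligible cells
are excluded rather than floored: flooring a near-zero SD would silently
deflate standardized distances, whereas exclusion merely loses one
SNP-genotype cell. References can come from the study cohort or from an
independent reference cohort; both paths share the same estimator.

## Quality indices

SNP-level distances:

* genotype-based (Q1): `q = |lambda − mu_G| / sigma_G` with G the called
  genotype; missing when the call is NC, lambda is missing, or the
  reference cell is ineligible.
* nearest-mean (Q2): `G* = argmin_G |lambda − mu_G|` over eligible cells,
  `q = |lambda − mu_G*| / sigma_G*`. When two classes are exactly
  equidistant in mean, the class yielding the smaller q (the larger sigma)
  is chosen — deterministic and conservative, since the ambiguous cell then
  contributes the least possible distance. Q2 needs no genotype calls,
  which keeps it meaningful where calling is unreliable (copy-number
  change, aberrant samples).

Distances use the absolute value: the indices are distances with positive
support, which is also what the lognormal reference model assumes.

Array-level summary `Q_x(rho)`: the winsorized mean replaces every distance
strictly above the array's rho-quantile with that quantile and averages;
`rho = 0.95` by default (so the top 5% of SNPs cannot dominate the index),
with the median and the upper-trimmed mean as alternatives. Summaries are
computed per chromosome and genome-wide; a scope with fewer than
`min_snps = 30` usable distances is skipped (quantiles of fewer points are
not meaningful) and recorded as a warning. Companion arrays are merged by
pooling SNP-level distances and summarizing the pooled vector — not by
averaging the per-array indices, which would weight the parts equally
regardless of SNP count.

All quantiles anywhere in the package — winsorization caps, empirical
confidence limits, simulation null thresholds — use linear interpolation of
order statistics (numpy's default, the "type 7" convention), recorded in
output metadata. Using one rule everywhere keeps winsorized indices and the
limits they are compared against self-consistent.

## Reference distributions and detection

Across a cohort of clean arrays the indices are well described by a
lognormal. `fit_lognormal` fits by the sample mean and SD (ddof = 1) of the
log values and attaches a one-sample Kolmogorov–Smirnov test of the log
values against the fitted normal. The KS test plugs the fitted parameters
in ("plain" KS, asymptotic p-value); with estimated parameters this is
conservative (it under-rejects), which is documented here rather than
corrected, because the detector consumes empirical quantiles, not KS
p-values.

A QI reference stores, per stratum (population, array label, scope, index,
summary, rho), the upper confidence limits at the 95/97.5/99% levels —
empirical quantiles of the reference indices by default, or lognormal
quantiles `exp(meanlog + z_level * sdlog)` as an alternative — plus the
reference mean and SD of the QI used by the heatmap's `mu + k*sigma` color
scale. Empirical limits require at least 20 reference arrays per stratum.
An array is flagged when its index *strictly* exceeds the selected limit;
by construction roughly `1 − level` of arrays drawn from the reference
distribution itself are flagged.

Group comparisons (populations, laboratories) test log-scale means with a
two-sample Z test using unpooled variances (robust when cohort sizes and
variances differ), log-scale variances with an F test, and whole
distributions with a two-sample KS test; all two-sided, with no
multiple-testing adjustment across strata (raw p-values are reported).

## Generative model and detection-rate experiment

The generator emulates one chromosome of a genotyping experiment:

1. Per SNP, allele-A frequency `p ~ Uniform(0.05, 0.5)` and genotype
   probabilities `(p^2, 2p(1−p), (1−p)^2)` (Hardy–Weinberg).
2. Per SNP, genotype counts over the N arrays are
   `Multinomial(N, probs)`, assigned to arrays by a uniformly random
   permutation (equivalent to any exchangeable assignment).
3. Per cell, `lambda ~ Beta(alpha_G, beta_G)` with moment-matched shapes:
   mean `mu_G` and total variance `V_T = V_S / (1 − r)`.

The relation `V_T = V_S / (1 − r)` is forced by the definition of the
relative extra error `r = V_E / V_T` together with `V_T = V_S + V_E` and a
fixed systematic variance `V_S`; r = 0 is a clean experiment, and larger r
broadens the AF bands. When `V_T` would exceed the Beta bound
`mu(1 − mu)` (possible only for extreme mu at large r), the variance is
clamped to 0.99 of the bound and a warning is emitted with the count of
affected cells.

Band defaults are `mu = 0.93 / 0.50 / 0.07` for AA/AB/BB with
`V_S = 0.0015` (SD ≈ 0.039): CPA-adjusted homozygote bands in real
intensity data sit visibly off 0 and 1 because of background
cross-hybridization, and an SD of ~0.04 gives the three cleanly separated
bands seen on good arrays. Each SNP receives small jitter — additive
Gaussian (sd 0.01) on the means, multiplicative lognormal (sdlog 0.1) on
the variances — so SNPs are heterogeneous, as in real data.

The detection-rate experiment mirrors field use of the detector. Stage 1
derives null thresholds as level-quantiles of array indices pooled over all
clean (r = 0) replications — one global threshold per level, mimicking a
fixed reference database and stabilizing the threshold (a per-replication
mode is available). Standardization uses the generating `(mu_G, sqrt(V_S))`
as the AF reference, isolating the index's behavior from
reference-estimation noise. Stage 2 walks the r grid (default 0 to 0.6 in
steps of 0.025): per replication, N = 100 arrays are simulated, summarized,
and the proportion with QI strictly above the threshold recorded; the curve
reports the mean and SD of that proportion over replications. Means follow
an S-shaped curve in r; the SD is near zero at both extremes (uniform
non-detection / saturation) with an interior peak where detection is
uncertain.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run the experiment at 100–300
replications (instead of the 1,000 used for production curves) on 690-SNP
and 6,396-SNP chromosomes with 100 arrays per replication. At these sizes
the Monte-Carlo standard errors are already far smaller than the effects
being checked (saturated detection at r = 0.4 and r = 0.175 sits many
standard errors above any sub-100% alternative), so the reduced replication
count changes nothing but runtime; tolerances in the tests are expressed as
multiples of the Monte-Carlo SE wherever the quantity is stochastic.

## What the generator does not emulate

* Linkage disequilibrium: SNPs are independent; real chromosomes are
  correlated, which mildly widens the null QI distribution relative to
  independence. Thresholds are derived from the same generator as the test
  data, so the power curves are internally consistent, but absolute power
  at a given r on real data will differ with the platform's band
  parameters.
* Genotype-calling error: simulated calls are the true generating
  genotypes; Q1 on real data additionally absorbs miscalls.
* No-calls, batch effects, GC waves, or copy-number structure.
* The published per-platform reference limits (e.g. for the Nsp/Sty 500K
  arrays) depend on cohorts this package does not ship; tests use such
  printed limits only as fixture constants for the detection rule.

Passing tests therefore demonstrate the correctness and calibration of the
machinery under the stated model, not platform-specific reference values.

## Known limitations

* The lognormal fit uses ddof = 1 on the log scale; for the cohort sizes
  involved (n ≥ 20) the difference from the MLE (ddof = 0) is negligible,
  but exact reproduction of another implementation's `sdlog` may differ in
  the third decimal at small n.
* The nearest-mean index is computed per cell over at most three reference
  classes; SNPs whose reference has no eligible class are dropped from
  every scope, which slightly changes `n_snps_used` between samples when
  AF missingness differs.
* Plots are static (PNG/PDF); there is no interactive viewer.
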