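# snpqc

Quality control of genome-wide SNP arrays from individual-level allele
frequencies.

## The problem

Downstream analyses of SNP-array data — association scans, loss-of-
heterozygosity and copy-number analyses — are only as good as the arrays
they run on. The customary screen, the genotype call rate (GCR), depends on
the calling algorithm's settings and can be driven to 100% by lenient
"forced calls", so it misses real hybridization failures. `snpqc`
implements a caller-independent alternative: it measures how far each
array's estimated *individual-level allele frequencies* (AFs) stray from
the three-band profile expected of clean data, and flags arrays whose
departure is statistically extreme relative to a reference cohort.

## The method

For SNP *m* on array *n*, the individual-level AF is estimated from
allele-specific hybridization intensities with a per-SNP correction for
preferential amplification/hybridization (CPA):

```
kappa_m  = mean over heterozygotes of I_A / I_B
lambda_nm = I_A / (I_A + kappa_m * I_B)
```

so heterozygotes sit at 0.5 and homozygotes near 1 and 0. An *AF
reference* stores the genotype-specific mean and SD (mu_G, sigma_G) of
these AFs in reference samples. Two SNP-level standardized distances
quantify the departure of an observed lambda:

* **Q1 (genotype-based):** q = |lambda − mu_G| / sigma_G with G the called
  genotype;
* **Q2 (nearest-mean):** the same distance against the genotype class whose
  reference mean is closest to lambda — no genotype calls needed.

Per array, the distances are summarized by the **winsorized mean at
rho** (values above the rho-quantile are capped at it; median and trimmed
mean are alternatives), per chromosome and genome-wide, and companion
arrays (e.g. Nsp + Sty) pool their SNPs into a "Merge" index. Array-level
indices follow a lognormal distribution across a clean cohort, so the
95/97.5/99% quantiles of a reference cohort's indices serve as upper
confidence limits: an array whose index strictly exceeds the chosen limit
is flagged as questionable.

A simulation suite characterizes the detector: genotypes are multinomial
under Hardy–Weinberg, AFs are Beta-distributed with genotype means mu_G and
total variance `V_T = V_S / (1 − r)`, where `r = V_E / V_T` is the fraction
of AF variance contributed by poor array/DNA quality. Detection rate as a
function of r forms an S-shaped power curve.

## Worked example

```python
import numpy as np
from snpqc import (
    synth_population, simulate_arrays, snp_qi_nearest, array_qi,
    build_qi_reference, detect_poor_arrays,
)

# a clean 690-SNP chromosome with 100 reference arrays
params = synth_population(690, seed=7)
ref = params.to_af_reference()
_, af_ref = simulate_arrays(params, 100, r=0.0, seed=8)
qi_ref_table = array_qi(snp_qi_nearest(af_ref, ref), rho=0.95, scopes="genome")
limits = build_qi_reference(qi_ref_table, levels=(0.95,))

# 20 test arrays with 30% of their AF variance due to poor quality
_, af_test = simulate_arrays(params, 20, r=0.3, seed=9)
qi_test = array_qi(snp_qi_nearest(af_test, ref), rho=0.95, scopes="genome")
report = detect_poor_arrays(qi_test, limits, level=0.95)
print(limits.table[["level", "limit"]].to_string(index=False))
print(f"flagged {report['flag'].sum()} of {len(report)} arrays; "
      f"QI range {report['qi'].min():.3f}-{report['qi'].max():.3f}")
```

prints

```
 level    limit
  0.95 0.800434
flagged 20 of 20 arrays; QI range 0.874-0.950
```

i.e. the 95% upper confidence limit of the clean cohort's winsorized-mean
Q2 is 0.800, and every degraded array exceeds it — at r = 0.3 the
per-array index has moved far outside the reference distribution.

The same pipeline is scriptable from the shell via the `snpqc` command
(`cpa`, `af`, `build-ref`, `qi`, `detect`, `simulate`, `plot`); run
`snpqc --help` for the utilities and `docs/methods.md` for the statistical
details.

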