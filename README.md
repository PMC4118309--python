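# cnpscan

Copy-number polymorphism (CNP) genotyping and quantitative-trait association
from SNP-array intensities.

## The problem

Common deletions and duplications — copy-number polymorphisms — are poorly
captured by SNP genotyping, yet they can modulate heritable traits such as
serum uric acid. Detecting and testing them from SNP-array data requires a
chain of steps, each with its own failure modes:

1. **Genomic-wave correction** — slow, GC-correlated spatial trends in the
   log R ratio (LRR) must be removed before any copy-number inference.
2. **Segmentation** — a 6-state hidden Markov model (copy numbers 0–4 plus a
   copy-neutral run-of-homozygosity state) integrates LRR and B allele
   frequency (BAF) to call per-subject copy-number segments; calls supported
   by fewer than 10 markers are discarded.
3. **Sample QC** — subjects with residual waves are excluded when the lag-10
   autocorrelation of their genome-ordered LRR exceeds 0.03, their
   normal-consistent MAD exceeds 0.32, or they carry more than 100 CNV calls.
4. **Region construction** — cutting the cohort's CNV territory at every
   observed breakpoint yields disjoint intervals on which each subject's copy
   number is unambiguous; intervals where at least 1% of subjects carry a
   deletion or duplication constitute the CNPs.
5. **Bayesian genotyping** — at a CNP locus, the per-subject average LRR is a
   3-component normal mixture indexed by the latent copy number (0/1/2). A
   conjugate Gibbs sampler approximates the posterior and each subject gets
   the maximum-a-posteriori component as an integer copy number.
6. **Association** — a linear mixed model for the seasonally adjusted log
   trait with fixed effects for study center, age, log BMI, sex and
   age/log-BMI-by-sex interactions, a chemistry-plate random intercept, and
   copy number (0–4) as a continuous covariate, optionally interacting with
   sex (2-df likelihood-ratio test). Because the trait is log transformed,
   slopes β are reported as the percentage change per copy,
   100·(e^β − 1), as a (2.5, 50, 97.5) percentile triple.

Real cohort intensity data of this kind is access-restricted, so the package
ships a first-class synthetic-cohort generator with known ground truth —
latent genotypes at (optionally negatively linked) deletion loci under
Hardy–Weinberg equilibrium, GC waves, plate batch effects, seasonal trait
trends and sex-specific multiplicative copy-number effects — against which
every stage is tested.

## Worked example

Simulate a cohort with a deletion polymorphism (deletion allele frequency
0.24) whose trait effect per deleted copy is +4.93% in women and +1.36% in
men, genotype the locus, and fit the interaction model:

```python
import numpy as np
from cnpscan import (SimConfig, CNPSpec, TraitSpec, simulate_marker_map,
                     simulate_cohort, region_mean_lrr, CopyNumberMixture,
                     CNPAssociationModel, seasonal_adjust)

cfg = SimConfig(
    n_subjects=4000,
    chrom_lengths={"chr4": 500_000},
    marker_spacing=1700,
    cnp_loci=[CNPSpec("chr4", 200_000, 219_368, deletion_allele_freq=0.24)],
    n_plates=40,
    trait_model=TraitSpec(
        cn_effect_female=-np.log(1.0493),   # +4.93% per deleted copy in women
        cn_effect_male=-np.log(1.0136),     # +1.36% per deleted copy in men
        residual_sd=0.2,
    ),
    seed=7,
)
mmap = simulate_marker_map(cfg)
data, pheno, genotypes, truth = simulate_cohort(mmap, cfg)

lrr_bar = region_mean_lrr(data, ("chr4", 200_000, 219_368))
fit = CopyNumberMixture(lrr_bar).fit(n_iter=4000, burn_in=1000, seed=1)
print(fit.summary())

cn = fit.map_cn.astype(float)
res = CNPAssociationModel(seasonal_adjust(pheno), cn=cn,
                          sex_interaction=True).fit(per_deleted_copy=True)
print(res.summary())
```

Output:

```
3-component normal mixture (Gibbs), 4000 sweeps, burn-in 1000, seed 1
 CN      mean  sd(mean)  variance   weight   n_MAP
  0   -2.0019    0.0040    0.0039   0.0595     237
  1   -0.5507    0.0015    0.0033   0.3752    1501
  2    0.0004    0.0012    0.0035   0.5653    2262

CNP association (plate random-intercept LMM, ML): LRT=43.32 df=2 p=3.93e-10
  women per deleted copy: _3.02_4.48_5.96_ (p=1.04e-09)
  men   per deleted copy: _0.41_1.91_3.43_ (p=0.0122)
```

The mixture recovers the three copy-number clusters (means near −2.0, −0.55
and 0.0 LRR, mixture weights near the Hardy–Weinberg frequencies 0.058 /
0.365 / 0.578 for q = 0.24), every subject is assigned its true copy number,
and the interaction model recovers the generating sex-specific effects within
sampling error — the `_2.5_50_97.5_` triples are percentage change per
deleted copy.

At this cohort size the point estimates carry Monte-Carlo noise of roughly
half a percentage point; averaging over seeds at n = 8411 (see below)
tightens them to the generating values.

## Command-line pipeline

Every stage is also a `cnpscan` subcommand operating on TSV files:

```
cnpscan simulate    --config cohort.yaml --out raw/ --seed 1
cnpscan wavecorrect --in raw/ --windows 10kb,50kb,250kb,1Mb --out corr/
cnpscan callcnv     --in corr/ --min-markers 10 --out segments.tsv
cnpscan qc          --in corr/ --segments segments.tsv --out qc.tsv
cnpscan genotype    --in raw/ --region chr4:200000-219368 --seed 1 --out cn.tsv
cnpscan associate   --cn cn.tsv --pheno raw/phenotypes.tsv --interaction
cnpscan surrogate   --calls calls.tsv --truth truth.tsv
```

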