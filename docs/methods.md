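# Methods

This note records the models implemented in `cnpscan`, the defaults and the
reasoning behind choices the design left open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic cohort generator

The generator (`cnpscan.simulate`) is the ground-truth oracle for the whole
pipeline. Its observation model for subject *i*, marker *j* is

    LRR_ij = mu(CN_ij) + a_i * w_j + plate_i + e_ij,   e_ij ~ N(0, lrr_sd)

with `mu = (-2.0, -0.55, 0.0, 0.35, 0.65)` for copy numbers 0–4. These
emission levels are deliberately compressed relative to the naive
log2(c/2): arrays saturate at high copy number, and homozygous deletions
retain background signal rather than reaching −∞. The spatial wave shape
`w_j` mixes a standardized local-GC term and a 2 Mb-period sinusoid in
genome position (waves in real arrays are GC-correlated but not perfectly so;
the sinusoid is the part GC regression cannot remove). Per-subject wave
amplitudes `a_i` are log-normal (σ = 0.5) around the configured
`wave_amplitude`; `n_wave_outliers` subjects get a fixed 8× amplitude and are
recorded in the truth tables as intended QC failures.

BAF at a SNP with copy number c and b B-alleles is a normal truncated to
[0, 1] centred at b/c with sd 0.03; copy number 0 yields Uniform(0, 1) noise.
Nonpolymorphic markers have missing BAF. Genotype calls at SNPs inside CNP
loci collapse the allele count to A/AB/B, with a null (missing) call at
copy number 0 — hemizygous subjects therefore appear as homozygous calls,
which is what makes missing-call surrogates and concordance checks
meaningful.

CNP genotypes are generated at the haplotype level: each haplotype carries 0
or 1 copies per locus, drawn at the configured deletion allele frequency
under Hardy–Weinberg equilibrium. A linked locus pair is drawn jointly with
P(deletion at both on one haplotype) = q1·q2·(1 + r), r ∈ [−1, 0]; r = −1
forbids double-deletion haplotypes, which reproduces the empirical regime of
two common deletions in strong repulsion — strongly negative copy-number
correlation and no double homozygous deletions — without any per-subject
coupling.

The trait is log-normal: the log-trait linear predictor has intercept, sex,
age, log BMI, age×sex, log-BMI×sex, categorical center effects, a 365-day
sinusoid over a uniform 2-year draw-date window, a plate random intercept,
and a per-copy effect at one designated causal locus (`causal_locus`),
sex-specific. A per-deleted-copy multiplicative effect of (1 + p/100) is
encoded as `cn_effect = −log(1 + p/100)` per copy. An optional binary
outcome is drawn from a logistic model whose linear predictor passes through
the log trait (mediation) with the intercept solved numerically to match a
target prevalence.

What the generator does **not** emulate: population structure and admixture,
family relatedness, marker-specific noise heterogeneity, allele-specific
hybridization bias in BAF, mosaic (fractional) copy number, and batch
effects that correlate with phenotype. Tests passing on this generator
demonstrate the pipeline's correctness under its stated model, not
robustness to those real-data pathologies.

## Wave correction

A single-window linear residualization: each subject's LRR is regressed on
the windowed mean GC (window chosen from {10, 50, 250, 1000} kb by maximal
median squared correlation across subjects, ties to the smallest window) and
replaced by the residual recentred to the subject's original mean. The
multi-resolution search of dedicated wave-correction tools is deliberately
not reproduced: correction is preprocessing here, and the single-window
linear model already removes the GC-correlated component that drives QC
failures. The correction is idempotent, preserves each subject's mean LRR
exactly (so genome-wide dosage is untouched), and degrades to a flagged
no-op when the GC covariate is constant.

## Segmentation HMM

Six states: CN0, CN1, CN2, CN2-ROH, CN3, CN4 — five copy-number levels; the
ROH state shares the diploid LRR mean but permits only homozygous BAF
clusters, so long runs of homozygosity are absorbed as copy-neutral instead
of being miscalled as deletions. Emissions: Gaussian LRR terms with
per-state sds (0.50, 0.25, 0.20, 0.20, 0.25, 0.30) — CN0 is widest because
deleted DNA leaves only background noise — plus, at SNPs with observed BAF,
an equal-weight mixture of [0,1]-truncated normals (sd 0.03) over the
state's permitted cluster centers; CN0 uses a uniform BAF density. Missing
LRR or BAF contributes nothing, which handles nonpolymorphic markers
naturally.

Transitions depend on inter-marker distance d: stay probability
1 − ε·(1 − e^(−d/D)) with ε = 0.01 and D = 100 kb; the leave mass is split
over other states proportionally to the stationary distribution
(0.005, 0.03, 0.90, 0.01, 0.04, 0.015). The limits are the identity matrix
at d → 0 and a fixed ε-leave matrix at d → ∞. Decoding is exact Viterbi per
chromosome (verified against exhaustive path enumeration on short
instances); scaled forward–backward supplies marginal posteriors. Runs of
non-diploid states become CNV segments (1-based closed coordinates at marker
positions; BED export converts to 0-based half-open); segments with fewer
than 10 markers are dropped. Autosomes only; chromosome X/Y dosage is out of
scope.

## Sample QC

Three exclusion metrics, all strict inequalities so boundary values pass:
lag-10 autocorrelation of the genome-ordered LRR (biased 1/n normalization,
chromosomes concatenated) > 0.03; normal-consistent MAD
(1.4826 × median |x − median|) > 0.32; CNV call count > 100. Whether the
0.32 cutoff was historically applied to raw or normal-consistent MAD is not
documented anywhere we could find; this implementation adopts the
normal-consistent convention (the common default in robust statistics) and
makes the cutoff configurable. A genotype-cluster signal-to-noise ratio
(between-cluster variance of the allelic contrast over mean within-cluster
variance, capped at 1e6) is reported as an array-quality diagnostic but
never used for exclusion.

## Interval construction

Per chromosome, the union of all segment start/end coordinates cuts the
CNV-covered territory into maximal disjoint pieces such that every segment
is an exact union of pieces; pieces containing no marker are dropped. By
construction each subject's copy number is constant on each interval, so the
interval × subject matrix (default 2) is well defined; a partial overlap or
two same-subject segments of different copy number on one interval is an
input-contract violation and raises. Carriers are subjects with copy number
≠ 2; intervals with carrier frequency ≥ 1% are retained. Retained intervals
merge into loci when no marker lies strictly between them — adjacency is
marker-relative, not bp-relative, because a bp gap that no marker
interrogates carries no evidence of separation. Implementation matches a
per-basepair brute-force scan on randomized instances (property test).

## Mixture genotyping

At a CNP locus the per-subject mean LRR over the locus's markers is fitted
with a k = 3 normal mixture by conjugate Gibbs sampling: component labels
(Gumbel-max categorical draws), means (normal posterior), variances
(inverse-gamma), weights (Dirichlet). Priors: means N(empirical tertile
centers, 1), variances InvGamma(2, 0.05), weights Dirichlet(1, 1, 1) —
weakly informative; the data at cohort scale dominate. Label switching is
resolved by relabeling components in ascending mean order every sweep, so
component index equals copy number (lower LRR ⇒ fewer copies). Defaults:
4000 sweeps, 1000 burn-in; per-subject membership probabilities are
Rao-Blackwellized (posterior responsibilities averaged over kept sweeps)
rather than label frequencies. MAP assignment takes the highest-probability
component, ties toward the lower copy number. A component empty in more
than half the sweeps flags the fit as degenerate (returned, not raised).
k is fixed at 3 — the loci of interest are deletion polymorphisms;
duplication-bearing loci would need k > 3 and are out of scope.

## Association models

The trait is log transformed and seasonally adjusted before modelling:
within each sex, a lowess smoother of log trait on draw date removes the
seasonal trend and the residual is recentred at the stratum mean. The
smoother span of "110" is interpreted as a 110-day bandwidth converted to
the lowess fraction over the stratum's date range; this is configurable
since the historical parameterization is ambiguous (it could also be a
neighbor count). Strata under 10 subjects pass through unadjusted with a
warning.

The baseline mixed model has fixed effects for center, age, log BMI, sex,
age×sex and log-BMI×sex, and a chemistry-plate random intercept, fitted by
maximum likelihood (not REML) so that likelihood-ratio tests between nested
fixed-effect models are valid. CNP models add copy number (continuous 0–4)
and optionally copy-number×sex; the LRT against baseline has 1 or 2 df. With
a single plate the random effect is unidentifiable and the fit falls back to
OLS, which is the exact ML solution at the zero-variance boundary. Singular
designs raise with the collinear columns named. Sex-specific slopes come
from the one interaction model (female slope = CN main effect, male = main +
interaction, with the delta-method se); stratified fits remain available as
a diagnostic through the model class.

Percentage-change reporting: for slope β with standard error s, the triple
is 100·(e^(β ± 1.959964·s) − 1) with the point estimate at β — a Wald
interval transformed to the percentage scale; the per-deleted-copy framing
applies the same transform to −β. The historical percentile notation does
not document its construction; the Wald construction is used because it is
exactly invertible (β = ln(1 + p50/100)) and matches the mixed-model output.

The genome scan fits the CNP model per disjoint interval (the null model is
fitted once — it does not depend on the interval), reports −log10 p,
expected quantiles for QQ plots, and flags intervals under the Bonferroni
threshold 0.05/m. Bonferroni is conservative here because adjacent
intervals carry correlated copy number, but no permutation scheme is
implemented. SNP-conditional models put B-allele dosages (0/1/2,
continuous) in both null and extended models. Haplotype association takes
phased input (phasing itself is upstream): within each stratum of identical
unordered SNP-haplotype pairs showing variation in the CNP-haplotype pair,
the adjusted log trait is regressed on the CNP-pair category (reference =
most common; LRT df = categories − 1), sexes separately and combined, by
OLS with age and log BMI. Binary outcomes use logistic regression with the
same fixed covariates plus plate as a fixed effect (a random-effect logistic
model is not attempted) and report the odds ratio per copy, optionally
adjusting for the trait to assess mediation.

## Surrogate genotypes and attenuation

A missing biallelic call at a SNP inside a deletion locus flags probable
homozygous deletion. Sensitivity is the flagged fraction of true CN0
subjects; specificity the unflagged fraction of true CN2 subjects; CN1
subjects are tabulated but enter neither rate, since the surrogate targets
homozygous deletion and specificity is assessed against canonical diploid
genotypes. The attenuation experiment simulates a cohort with a known
per-copy effect and compares the mixed-model slope on true copy number with
the slope on a surrogate indicator (flagging CN0 subjects with the given
sensitivity; specificity 1). The indicator contrasts CN0 against everyone
else — a two-copy contrast — so its coefficient is halved to the per-copy
scale before comparison; hemizygous subjects hidden in the reference class
and missed homozygotes then bias the surrogate slope toward zero. A
`binary_cn` option reassigns hemizygotes (adjusting their trait exactly on
the log scale) to create the contamination-free reference case in which the
two estimates agree up to coding scale.

## Problem sizes and numerical choices

- Injection–recovery experiments run at the cohort scale they emulate
  (n = 8411, 100 plates, residual sd 0.2 on the log trait), averaging point
  estimates over 10 generation seeds; the synthetic chromosome is 500 kb at
  ~1.7 kb marker spacing with a ~19.4 kb locus — region-mean genotyping
  needs only the locus plus flanks, not a whole genome.
- Type-I-error calibration uses 500 null cohorts of 600 subjects on 15
  plates; the attenuation comparison uses 200 replicates of 8000 subjects
  (per-replicate contrasts must be sharper than the attenuation gap for the
  paired comparison to be informative).
- Viterbi is validated against exhaustive 6^m enumeration for m ≤ 8;
  forward–backward marginals are checked to sum to 1 within 1e-10.
- All stochastic components accept explicit seeds; equal seeds give
  byte-identical cohorts, maps and Gibbs chains. Derived seeds use an
  FNV-style hash of (seed, stream label) reduced below 2^31.
- MixedLM optimization tries the default optimizer, then Powell and
  conjugate-gradient; if none yields a finite likelihood (plate variance
  pinned at the zero boundary), the OLS solution is used, which is the ML
  fit in that boundary case.

## Known limitations

- The HMM's emission parameters are fixed, not re-estimated per sample
  (no Baum–Welch); samples whose noise deviates grossly from the assumed
  sds rely on QC for protection.
- k = 3 genotyping cannot represent duplication alleles at the same locus.
- Bonferroni correction ignores inter-interval correlation.
- The logistic outcome model treats plate as fixed, which is unstable for
  many small plates.
- The generator's BAF model ignores allelic cross-hybridization, so
  BAF-based evidence is cleaner than on real arrays; segmentation accuracy
  on real data will be lower at equal LRR noise.
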