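"""Synthetic cohort generator with known copy-number ground truth.

Emulates the statistical structure of a large SNP-array cohort study of a
log-normal serum trait: latent copy-number polymorphism (CNP) genotypes at
deletion loci (optionally negatively linked at the haplotype level),
Hardy-Weinberg allele frequencies, GC-correlated genomic waves, chemistry-plate
batch effects on both intensities and trait, seasonal trait trends, and
sex-specific multiplicative copy-number effects.

The generator is the ground-truth oracle for every downstream stage: the
hidden Markov segmentation, sample QC, interval construction, mixture
genotyping and the mixed-model association all have a known answer on its
output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "LRR_MEAN_BY_CN",
    "CNPSpec",
    "TraitSpec",
    "SimConfig",
    "IntensityData",
    "TruthTables",
    "simulate_marker_map",
    "simulate_cohort",
]

# Expected log R ratio per integer copy number 0..4.  Compressed relative to
# the naive log2(c/2) because array saturation attenuates the response at
# high copy number and homozygous deletions rarely reach the theoretical -inf.
LRR_MEAN_BY_CN = np.array([-2.0, -0.55, 0.0, 0.35, 0.65])

BAF_CLUSTER_SD = 0.03


@dataclass
class CNPSpec:
    """A common deletion polymorphism segregating at Hardy-Weinberg
    equilibrium; copy number per subject is in {0, 1, 2}.

    ``linked_to`` names the index of another locus in ``SimConfig.cnp_loci``;
    ``repulsion`` in [-1, 0] scales the probability that a single haplotype
    carries the deletion at both loci: P(both) = q1*q2*(1 + repulsion), so -1
    forbids double-deletion haplotypes entirely.
    """

    chrom: str
    start: int
    end: int
    deletion_allele_freq: float
    linked_to: Optional[int] = None
    repulsion: float = 0.0

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("CNPSpec requires start < end")
        if not 0.0 <= self.deletion_allele_freq <= 1.0:
            raise ValueError("deletion_allele_freq must be in [0, 1]")
        if not -1.0 <= self.repulsion <= 0.0:
            raise ValueError("repulsion must be in [-1, 0]")


@dataclass
class TraitSpec:
    """Generative model for the log-scale quantitative trait.

    All effects are on the natural-log scale of the trait.  ``cn_effect_*``
    is the additive log-trait change per copy at the causal CNP locus
    (``causal_locus`` indexes ``SimConfig.cnp_loci``): a multiplicative
    trait ratio of r between CN=k+1 and CN=k corresponds to
    ``cn_effect = log(r)``.
    """

    intercept: float = 1.45
    sex_effect: float = 0.18          # male minus female
    age_slope: float = 0.004          # per year
    logbmi_slope: float = 0.10        # per log(kg/m^2)
    age_sex_interaction: float = -0.002
    logbmi_sex_interaction: float = -0.03
    center_effects: tuple = (0.0, 0.02, -0.02, 0.01)
    plate_sd: float = 0.03
    seasonal_amplitude: float = 0.03
    cn_effect_female: float = 0.0
    cn_effect_male: float = 0.0
    causal_locus: int = 0
    residual_sd: float = 0.2
    gout_prevalence: float = 0.0      # 0 disables the binary outcome
    gout_logor_per_log_trait: float = 3.0
    gout_logor_per_copy: float = 0.0  # direct CN->outcome path, usually 0

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")


@dataclass
class SimConfig:
    n_subjects: int = 1000
    chrom_lengths: dict = field(default_factory=lambda: {"chr4": 2_000_000})
    marker_spacing: int = 1700
    snp_fraction: float = 0.5
    cnp_loci: list = field(default_factory=list)
    rare_cnv_rate: float = 0.0        # expected rare CNVs per subject
    wave_amplitude: float = 0.0       # typical per-subject wave scale, LRR units
    n_wave_outliers: int = 0          # subjects with grossly amplified waves
    plate_sd: float = 0.0             # plate-level LRR shift
    lrr_sd: float = 0.2               # marker-level LRR noise
    n_plates: int = 10
    trait_model: TraitSpec = field(default_factory=TraitSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        for name in ("rare_cnv_rate", "wave_amplitude", "plate_sd", "lrr_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class IntensityData:
    """Subjects x markers intensity matrices plus the marker map.

    ``lrr``/``baf`` are (n_subjects, n_markers) float arrays; BAF is NaN at
    nonpolymorphic markers.  ``map`` is a DataFrame with columns
    marker_id, chrom, pos, is_snp, gc (positions 1-based, sorted within
    chromosome).
    """

    lrr: np.ndarray
    baf: np.ndarray
    map: pd.DataFrame
    subject_ids: list

    def __post_init__(self) -> None:
        n, m = self.lrr.shape
        if self.baf.shape != (n, m) or len(self.map) != m:
            raise ValueError("intensity matrices and marker map disagree in size")
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length mismatch")

    @property
    def n_subjects(self) -> int:
        return self.lrr.shape[0]

    @property
    def n_markers(self) -> int:
        return self.lrr.shape[1]


@dataclass
class TruthTables:
    """Ground truth recorded by the generator.

    hap_copies: (n_subjects, 2, n_loci) int array, copies (0 or 1) carried by
        each haplotype at each CNP locus.
    cn_by_locus: (n_subjects, n_loci) integer copy number; always the sum of
        the two haplotype copies.
    cn_by_marker: (n_subjects, n_markers) integer copy number at every marker.
    rare_cnvs: DataFrame (subject_id, chrom, start, end, cn, n_markers).
    plate_lrr_effects / plate_trait_effects: per-plate random intercepts.
    qc_violators: subject ids whose waves were deliberately amplified so that
        they fail intensity QC.
    """

    hap_copies: np.ndarray
    cn_by_locus: np.ndarray
    cn_by_marker: np.ndarray
    rare_cnvs: pd.DataFrame
    plate_lrr_effects: np.ndarray
    plate_trait_effects: np.ndarray
    qc_violators: list


def simulate_marker_map(config: SimConfig) -> pd.DataFrame:
    """Lay out jittered, approximately evenly spaced markers per chromosome
    with a smooth autocorrelated local-GC track.

    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(_derive_seed(config.seed, "marker_map"))
    rows = []
    for chrom, length in config.chrom_lengths.items():
        if config.marker_spacing <= 0:
            raise ValueError("marker_spacing must be positive")
        if config.marker_spacing > length:
            raise ValueError(
                f"marker_spacing {config.marker_spacing} exceeds length of {chrom}"
            )
        grid = np.arange(config.marker_spacing // 2, length, config.marker_spacing)
        jitter = rng.uniform(-0.3, 0.3, size=grid.size) * config.marker_spacing
        pos = np.clip(np.sort(grid + jitter).astype(np.int64), 1, length)
        pos = np.unique(pos)
        # smooth GC: heavily filtered white noise around a 0.41 genome average
        raw = rng.standard_normal(pos.size)
        smooth = gaussian_filter1d(raw, sigma=10.0, mode="nearest")
        sd = smooth.std()
        gc = np.clip(0.41 + 0.12 * smooth / (sd if sd > 0 else 1.0), 0.0, 1.0)
        is_snp = rng.random(pos.size) < config.snp_fraction
        for i in range(pos.size):
            rows.append((f"{chrom}_m{i:06d}", chrom, int(pos[i]), bool(is_snp[i]), float(gc[i])))
    out = pd.DataFrame(rows, columns=["marker_id", "chrom", "pos", "is_snp", "gc"])
    return out


def _derive_seed(seed: int, label: str) -> int:
    """Stable stream seed below 2**31 derived from the master seed."""
    h = 2166136261
    for b in f"{seed}:{label}".encode():
        h = ((h ^ b) * 16777619) % (2**32)
    return h % (2**31 - 1)


def _sample_haplotypes(rng: np.random.Generator, loci: Sequence[CNPSpec], n: int) -> np.ndarray:
    """Draw per-subject haplotype deletion indicators, (n, 2, n_loci).

    Entry 1 means the haplotype carries the deletion (zero copies) at that
    locus.  Linked pairs are drawn jointly with the configured repulsion;
    unlinked loci independently.
    """
    k = len(loci)
    d = np.zeros((n, 2, k), dtype=np.int8)
    done = set()
    for j, spec in enumerate(loci):
        if j in done:
            continue
        if spec.linked_to is not None:
            i2 = spec.linked_to
            q1, q2 = spec.deletion_allele_freq, loci[i2].deletion_allele_freq
            p11 = q1 * q2 * (1.0 + spec.repulsion)
            probs = np.array([1 - q1 - q2 + p11, q2 - p11, q1 - p11, p11])
            if (probs < -1e-12).any():
                raise ValueError("incompatible linked-locus frequencies/repulsion")
            probs = np.clip(probs, 0, None)
            probs /= probs.sum()
            draw = rng.choice(4, size=(n, 2), p=probs)
            d[:, :, j] = draw // 2       # deletion at this locus
            d[:, :, i2] = draw % 2       # deletion at the partner
            done.update((j, i2))
        else:
            q = spec.deletion_allele_freq
            d[:, :, j] = rng.random((n, 2)) < q
            done.add(j)
    return d


def _rare_cnvs(
    rng: np.random.Generator,
    config: SimConfig,
    mmap: pd.DataFrame,
    subject_ids: Sequence[str],
) -> pd.DataFrame:
    """Sprinkle private CNVs (CN in {0,1,3,4}) outside the CNP loci."""
    rows = []
    cn_choices = np.array([0, 1, 3, 4])
    cn_probs = np.array([0.10, 0.45, 0.33, 0.12])
    by_chrom = {c: g for c, g in mmap.groupby("chrom", sort=False)}
    chroms = list(by_chrom)
    for sid in subject_ids:
        for _ in range(rng.poisson(config.rare_cnv_rate)):
            chrom = chroms[rng.integers(len(chroms))]
            g = by_chrom[chrom]
            n_mark = int(rng.integers(5, 80))
            if n_mark >= len(g):
                continue
            i0 = int(rng.integers(0, len(g) - n_mark))
            start = int(g["pos"].iloc[i0])
            end = int(g["pos"].iloc[i0 + n_mark - 1])
            if any(
                spec.chrom == chrom and start <= spec.end and end >= spec.start
                for spec in config.cnp_loci
            ):
                continue  # keep CNP loci clean
            cn = int(rng.choice(cn_choices, p=cn_probs))
            rows.append((sid, chrom, start, end, cn, n_mark))
    return pd.DataFrame(
        rows, columns=["subject_id", "chrom", "start", "end", "cn", "n_markers"]
    )


def simulate_cohort(mmap: pd.DataFrame, config: SimConfig):
    """Generate intensities, phenotypes, genotype calls and ground truth.

    Returns ``(IntensityData, phenotypes: DataFrame, genotypes: DataFrame,
    TruthTables)``.  The observation model is

        LRR_ij = mu(CN_ij) + wave_i(gc_j, pos_j) + plate_lrr + N(0, lrr_sd)

    with per-subject wave amplitudes drawn log-normal around
    ``wave_amplitude`` (plus ``n_wave_outliers`` subjects amplified 8x —
    deliberate QC fixtures).  BAF at SNPs is drawn from genotype-conditional
    truncated-normal clusters at b/c (sd 0.03); CN 0 gives Uniform(0,1);
    nonpolymorphic markers have NaN BAF.  The log trait follows the
    TraitSpec linear predictor plus a 365-day seasonal sinusoid over a
    2-year draw-date window, a plate random intercept and the sex-specific
    per-copy effect at the causal locus.
    """
    rng = np.random.default_rng(_derive_seed(config.seed, "cohort"))
    n = config.n_subjects
    m = len(mmap)
    subject_ids = [f"S{i:05d}" for i in range(n)]
    pos = mmap["pos"].to_numpy()
    gc = mmap["gc"].to_numpy()
    is_snp = mmap["is_snp"].to_numpy()
    chrom = mmap["chrom"].to_numpy()

    for spec in config.cnp_loci:
        if spec.chrom not in config.chrom_lengths:
            raise ValueError(f"CNP locus on unknown chromosome {spec.chrom}")
        if spec.end > config.chrom_lengths[spec.chrom]:
            raise ValueError("CNP locus outside chromosome bounds")

    # --- latent copy number -------------------------------------------------
    k_loci = len(config.cnp_loci)
    hap_del = _sample_haplotypes(rng, config.cnp_loci, n)
    hap_copies = 1 - hap_del                      # copies carried per haplotype
    cn_by_locus = hap_copies.sum(axis=1).astype(np.int8)  # (n, k_loci)

    cn = np.full((n, m), 2, dtype=np.int8)
    for j, spec in enumerate(config.cnp_loci):
        in_locus = (chrom == spec.chrom) & (pos >= spec.start) & (pos <= spec.end)
        cn[:, in_locus] = cn_by_locus[:, [j]]

    rare = _rare_cnvs(rng, config, mmap, subject_ids)
    sid_index = {s: i for i, s in enumerate(subject_ids)}
    for row in rare.itertuples(index=False):
        sel = (chrom == row.chrom) & (pos >= row.start) & (pos <= row.end)
        cn[sid_index[row.subject_id], sel] = row.cn

    # --- intensities --------------------------------------------------------
    plates = np.repeat(np.arange(config.n_plates), int(np.ceil(n / config.n_plates)))[:n]
    plate_lrr = rng.normal(0.0, config.plate_sd, size=config.n_plates)

    amp = rng.lognormal(
        mean=np.log(config.wave_amplitude) if config.wave_amplitude > 0 else -np.inf,
        sigma=0.5,
        size=n,
    )
    if config.wave_amplitude == 0:
        amp = np.zeros(n)
    qc_violators: list = []
    if config.n_wave_outliers > 0:
        bad = rng.choice(n, size=min(config.n_wave_outliers, n), replace=False)
        amp[bad] = 8.0 * max(config.wave_amplitude, 1e-3)
        qc_violators = [subject_ids[i] for i in sorted(bad)]

    gc_term = (gc - gc.mean()) / (gc.std() if gc.std() > 0 else 1.0)
    sin_term = np.sin(2 * np.pi * pos / 2_000_000.0)
    wave_shape = 0.7 * gc_term + 0.7 * sin_term   # unit-scale spatial pattern

    lrr = (
        LRR_MEAN_BY_CN[cn]
        + amp[:, None] * wave_shape[None, :]
        + plate_lrr[plates][:, None]
        + rng.normal(0.0, config.lrr_sd, size=(n, m))
    )

    # BAF: genotype-conditional clusters at b/c
    pop_baf = rng.uniform(0.05, 0.95, size=m)     # per-SNP B allele frequency
    b_alleles = rng.binomial(cn.clip(min=0).astype(np.int64), pop_baf[None, :])
    baf = np.full((n, m), np.nan)
    snp_cols = np.flatnonzero(is_snp)
    for j in snp_cols:
        c = cn[:, j].astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            center = np.where(c > 0, b_alleles[:, j] / np.maximum(c, 1), np.nan)
        vals = np.clip(rng.normal(center, BAF_CLUSTER_SD), 0.0, 1.0)
        vals[c == 0] = rng.uniform(0.0, 1.0, size=int((c == 0).sum()))
        baf[:, j] = vals

    data = IntensityData(lrr=lrr, baf=baf, map=mmap.reset_index(drop=True),
                         subject_ids=subject_ids)

    # --- genotype calls at SNPs inside CNP loci -----------------------------
    geno_cols = {}
    for spec in config.cnp_loci:
        sel = np.flatnonzero(
            (chrom == spec.chrom) & (pos >= spec.start) & (pos <= spec.end) & is_snp
        )
        for j in sel:
            c = cn[:, j]
            b = b_alleles[:, j]
            calls = np.where(b == 0, "A", np.where(b == c, "B", "AB"))
            calls = calls.astype(object)
            calls[c == 0] = None                  # null genotype: no signal
            geno_cols[mmap["marker_id"].iloc[j]] = calls
    genotypes = pd.DataFrame(geno_cols, index=subject_ids)
    genotypes.index.name = "subject_id"

    # --- phenotype ----------------------------------------------------------
    ts = config.trait_model
    male = (rng.random(n) < 0.47).astype(int)
    age = rng.normal(54.0, 5.7, size=n)
    log_bmi = np.log(np.clip(rng.normal(27.0, 4.8, size=n), 15.0, None))
    center = rng.integers(0, len(ts.center_effects), size=n)
    draw_day = rng.integers(0, 730, size=n)       # days since study start
    dates = pd.Timestamp("2005-01-01") + pd.to_timedelta(draw_day, unit="D")
    plate_trait = rng.normal(0.0, ts.plate_sd, size=config.n_plates)

    cn_causal = (
        cn_by_locus[:, ts.causal_locus].astype(float) if k_loci else np.zeros(n)
    )
    cn_effect = np.where(male == 1, ts.cn_effect_male, ts.cn_effect_female)
    log_trait = (
        ts.intercept
        + ts.sex_effect * male
        + ts.age_slope * age
        + ts.logbmi_slope * log_bmi
        + ts.age_sex_interaction * age * male
        + ts.logbmi_sex_interaction * log_bmi * male
        + np.asarray(ts.center_effects)[center]
        + ts.seasonal_amplitude * np.sin(2 * np.pi * draw_day / 365.0)
        + plate_trait[plates]
        + cn_effect * cn_causal
        + rng.normal(0.0, ts.residual_sd, size=n)
    )
    pheno = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "trait": np.exp(log_trait),
            "draw_date": dates,
            "sex": np.where(male == 1, "M", "F"),
            "age": age,
            "log_bmi": log_bmi,
            "center": [f"C{c}" for c in center],
            "plate": [f"P{p:03d}" for p in plates],
        }
    )
    if ts.gout_prevalence > 0:
        lt_c = log_trait - log_trait.mean()
        eta = (
            ts.gout_logor_per_log_trait * lt_c
            + ts.gout_logor_per_copy * (cn_causal - cn_causal.mean())
        )
        # intercept tuned so the marginal prevalence matches the spec value
        from scipy.optimize import brentq
        from scipy.special import expit

        a = brentq(
            lambda a0: expit(a0 + eta).mean() - ts.gout_prevalence, -30, 30
        )
        pheno["gout"] = (rng.random(n) < expit(a + eta)).astype(int)

    truth = TruthTables(
        hap_copies=hap_copies,
        cn_by_locus=cn_by_locus,
        cn_by_marker=cn,
        rare_cnvs=rare,
        plate_lrr_effects=plate_lrr,
        plate_trait_effects=plate_trait,
        qc_violators=qc_violators,
    )
    return data, pheno, genotypes, truth
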