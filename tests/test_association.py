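"""Trait association: seasonal adjustment, percentage-change reporting, the
plate random-intercept mixed model, genome scan, SNP-conditional and
haplotype models, and binary outcomes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cnpscan import association as A
from cnpscan import regions
from cnpscan import simulate as sim


def make_cohort(n=1500, seed=0, **trait_kwargs):
    trait_kwargs.setdefault("residual_sd", 0.2)
    cfg = sim.SimConfig(
        n_subjects=n, chrom_lengths={"chr4": 120_000}, marker_spacing=2000,
        cnp_loci=[sim.CNPSpec("chr4", 40_000, 60_000, 0.3)],
        n_plates=12, trait_model=sim.TraitSpec(**trait_kwargs), seed=seed,
    )
    mmap = sim.simulate_marker_map(cfg)
    data, pheno, geno, truth = sim.simulate_cohort(mmap, cfg)
    return pheno, truth.cn_by_locus[:, 0].astype(float), truth


def _harmonic_amplitude(pheno, y):
    day = (pheno["draw_date"] - pheno["draw_date"].min()).dt.days.to_numpy()
    X = np.column_stack([np.ones_like(day), np.sin(2 * np.pi * day / 365),
                         np.cos(2 * np.pi * day / 365)])
    b = np.linalg.lstsq(X, y, rcond=None)[0]
    return float(np.hypot(b[1], b[2]))


class TestSeasonalAdjust:
    def test_without_seasonality_is_nearly_identity(self):
        pheno, *_ = make_cohort(seed=1, seasonal_amplitude=0.0)
        adj = A.seasonal_adjust(pheno)
        rms = np.sqrt(np.mean((adj["adj_log_trait"] - np.log(pheno["trait"])) ** 2))
        assert rms < 0.2 / 10  # residual_sd / 10

    def test_removes_injected_annual_cycle(self):
        pheno, *_ = make_cohort(n=3000, seed=2, seasonal_amplitude=0.05)
        adj = A.seasonal_adjust(pheno)
        assert _harmonic_amplitude(pheno, np.log(pheno["trait"].to_numpy())) > 0.035
        assert _harmonic_amplitude(pheno, adj["adj_log_trait"].to_numpy()) < 0.01

    def test_sexes_adjusted_independently(self):
        # opposite-phase seasonality by sex cancels in the pooled series but
        # must still be removed within each stratum
        pheno, *_ = make_cohort(n=3000, seed=3, seasonal_amplitude=0.0)
        day = (pheno["draw_date"] - pheno["draw_date"].min()).dt.days.to_numpy()
        male = (pheno["sex"] == "M").to_numpy()
        phase = np.where(male, 1.0, -1.0)
        pheno = pheno.copy()
        pheno["trait"] = pheno["trait"] * np.exp(
            0.06 * phase * np.sin(2 * np.pi * day / 365)
        )
        adj = A.seasonal_adjust(pheno)
        for sel in (male, ~male):
            amp = _harmonic_amplitude(pheno[sel], adj.loc[sel, "adj_log_trait"].to_numpy())
            assert amp < 0.015

    def test_tiny_stratum_passes_through_with_warning(self):
        pheno, *_ = make_cohort(n=100, seed=4)
        pheno = pheno.copy()
        pheno.loc[pheno.index[:5], "sex"] = "F"
        pheno.loc[pheno.index[5:], "sex"] = "M"
        with pytest.warns(UserWarning):
            adj = A.seasonal_adjust(pheno)
        f = (adj["sex"] == "F").to_numpy()
        assert np.allclose(adj.loc[f, "adj_log_trait"],
                           np.log(adj.loc[f, "trait"]))


class TestPctChange:
    def test_zero_beta_is_zero_triple(self):
        e = A.pct_change(0.0, 0.0)
        assert (e.p2_5, e.p50, e.p97_5) == (0.0, 0.0, 0.0)

    def test_paper_style_magnitude(self):
        e = A.pct_change(np.log(1.0493), 0.0)
        assert e.p50 == pytest.approx(4.93, abs=1e-10)

    def test_per_deleted_copy_flips_sign(self):
        e = A.pct_change(-np.log(1.0493), 0.0, per_deleted_copy=True)
        assert e.p50 == pytest.approx(4.93, abs=1e-10)

    @settings(deadline=None, max_examples=100)
    @given(st.floats(-0.5, 0.5), st.floats(0.0, 0.3))
    def test_exact_inversion_and_ordering(self, beta, se):
        e = A.pct_change(beta, se)
        assert np.log1p(e.p50 / 100) == pytest.approx(beta, abs=1e-12)
        assert e.p2_5 <= e.p50 <= e.p97_5

    def test_strictly_increasing_in_beta(self):
        vals = [A.pct_change(b, 0.1).p50 for b in np.linspace(-1, 1, 21)]
        assert (np.diff(vals) > 0).all()


class TestBaselineModel:
    def test_plate_variance_and_age_recovery(self):
        cfg = sim.SimConfig(
            n_subjects=8500, chrom_lengths={"chr4": 60_000}, marker_spacing=2000,
            n_plates=100,
            trait_model=sim.TraitSpec(plate_sd=0.05, residual_sd=0.2),
            seed=5,
        )
        mmap = sim.simulate_marker_map(cfg)
        _, pheno, _, _ = sim.simulate_cohort(mmap, cfg)
        fit = A.fit_baseline(pheno)
        res = fit.null_fit
        plate_var = float(res.cov_re.iloc[0, 0]) if hasattr(res, "cov_re") else 0.0
        assert 0.5 * 0.05**2 < plate_var < 1.5 * 0.05**2
        b_age = float(res.params["age"])
        se_age = float(res.bse["age"])
        assert abs(b_age - 0.004) < 3 * se_age

    def test_zero_plate_variance_hits_boundary(self):
        pheno, *_ = make_cohort(n=2000, seed=6, plate_sd=0.0)
        res = A.fit_baseline(pheno).null_fit
        if hasattr(res, "cov_re"):
            assert float(res.cov_re.iloc[0, 0]) < 1e-3

    def test_single_plate_rejected(self):
        pheno, *_ = make_cohort(n=200, seed=7)
        pheno = pheno.assign(plate="P0")
        with pytest.raises(ValueError):
            A.fit_baseline(pheno)

    def test_singular_design_names_columns(self):
        pheno, cn, _ = make_cohort(n=300, seed=8)
        dup = {"snp1": cn, "snp2": cn}  # identical columns
        with pytest.raises(ValueError, match="collinear"):
            A.CNPAssociationModel(pheno, cn=cn, snp_dosages=dup).fit()


class TestCNPModel:
    def test_permuted_cn_has_no_effect(self):
        pheno, cn, _ = make_cohort(n=2000, seed=9, cn_effect_female=0.05,
                                   cn_effect_male=0.05)
        rng = np.random.default_rng(0)
        res = A.fit_cnp(pheno, rng.permutation(cn))
        assert abs(res.overall.beta) < 3 * res.overall.se
        assert res.lrt_p > 0.001

    def test_monomorphic_cn_rejected(self):
        pheno, cn, _ = make_cohort(n=200, seed=10)
        with pytest.raises(ValueError, match="monomorphic"):
            A.fit_cnp(pheno, np.full_like(cn, 2.0))

    def test_one_plate_equals_ols(self):
        pheno, cn, _ = make_cohort(n=500, seed=11, cn_effect_female=0.04,
                                   cn_effect_male=0.04)
        pheno = pheno.assign(plate="P0")
        res = A.CNPAssociationModel(pheno, cn=cn).fit()
        X = A._baseline_design(pheno)
        X["cn"] = cn
        beta_ols = np.linalg.lstsq(
            X.to_numpy(float), np.log(pheno["trait"].to_numpy()), rcond=None
        )[0][list(X.columns).index("cn")]
        b, _ = res._slope("overall")
        assert b == pytest.approx(beta_ols, abs=1e-8)

    def test_lrt_invariant_to_affine_covariate_recoding(self):
        pheno, cn, _ = make_cohort(n=1000, seed=12, cn_effect_female=0.04,
                                   cn_effect_male=0.02)
        r1 = A.fit_cnp(pheno, cn, sex_interaction=True)
        recoded = pheno.copy()
        recoded["age"] = recoded["age"] * 10 - 100
        recoded["log_bmi"] = recoded["log_bmi"] / 3 + 1
        r2 = A.fit_cnp(recoded, cn, sex_interaction=True)
        assert r1.lrt_stat == pytest.approx(r2.lrt_stat, abs=1e-4)

    def test_sex_specific_slopes_recover_truth(self):
        f_eff, m_eff = -np.log(1.0493), -np.log(1.0136)
        pheno, cn, _ = make_cohort(n=4000, seed=13, cn_effect_female=f_eff,
                                   cn_effect_male=m_eff)
        res = A.fit_cnp(pheno, cn, sex_interaction=True, per_deleted_copy=True)
        assert res.female.p50 == pytest.approx(4.93, abs=3 * res.female.se * 100)
        assert res.lrt_df == 2


class TestGenomeScan:
    def _matrix(self, rng, n_sub, n_int, causal=None, cn_causal=None):
        ivs, rows = [], {}
        for i in range(n_int):
            start = 1000 * (i + 1)
            iv = regions.DisjointInterval("chr1", start, start + 999, 2)
            if causal is not None and i == causal:
                cnv = cn_causal
            else:
                cnv = np.where(rng.random(n_sub) < 0.05,
                               rng.choice([1, 3], n_sub), 2)
            iv.carrier_count = int((cnv != 2).sum())
            iv.carrier_freq = iv.carrier_count / n_sub
            ivs.append(iv)
            rows[iv.key] = cnv
        cols = [f"S{i:05d}" for i in range(n_sub)]
        cn = pd.DataFrame.from_dict(rows, orient="index")
        cn.columns = cols
        return regions.CopyNumberMatrix(ivs, cn)

    def test_null_scan_calibration(self):
        rng = np.random.default_rng(14)
        pheno, _, _ = make_cohort(n=400, seed=15)
        mat = self._matrix(rng, 400, 200)
        scan = A.genome_scan(mat, pheno)
        assert len(scan) == 200
        assert scan["significant"].sum() == 0
        # QQ: observed p-values compatible with uniform
        from scipy.stats import kstest
        assert kstest(scan["p"], "uniform").pvalue > 0.01
        # figure helpers run on scan output
        from cnpscan import plots
        plots.manhattan_plot(scan)
        plots.qq_plot(scan)

    def test_causal_interval_attains_minimum_p(self):
        rng = np.random.default_rng(16)
        pheno, cn, _ = make_cohort(n=2000, seed=17, cn_effect_female=0.05,
                                   cn_effect_male=0.05)
        mat = self._matrix(rng, 2000, 30, causal=7, cn_causal=cn.astype(int))
        scan = A.genome_scan(mat, pheno)
        assert scan.loc[scan["p"].idxmin(), "interval"].startswith("chr1:8000")
        assert scan.loc[scan["p"].idxmin(), "significant"]


class TestConditional:
    def test_near_perfect_tag_absorbs_signal(self):
        pheno, cn, _ = make_cohort(n=2000, seed=18, cn_effect_female=0.05,
                                   cn_effect_male=0.05)
        rng = np.random.default_rng(1)
        tag = cn.copy()
        flip = rng.random(cn.size) < 0.02
        tag[flip] = rng.integers(0, 3, flip.sum())
        marginal = A.fit_cnp(pheno, cn, sex_interaction=True)
        cond = A.conditional_fit(pheno, cn, {"tag": tag})
        assert cond.lrt_stat < 0.2 * marginal.lrt_stat

    def test_independent_cn_effect_survives_conditioning(self):
        pheno, cn, _ = make_cohort(n=2000, seed=19, cn_effect_female=0.05,
                                   cn_effect_male=0.05)
        rng = np.random.default_rng(2)
        snp = rng.binomial(2, 0.3, cn.size).astype(float)  # unlinked SNP
        marginal = A.fit_cnp(pheno, cn, sex_interaction=True)
        cond = A.conditional_fit(pheno, cn, {"snp": snp})
        assert cond.lrt_p < min(marginal.lrt_p * 100, 0.05)

    def test_invalid_dosage_rejected(self):
        pheno, cn, _ = make_cohort(n=200, seed=20)
        with pytest.raises(ValueError, match="dosages"):
            A.conditional_fit(pheno, cn, {"snp": np.full(cn.size, 0.5)})


class TestHaplotypes:
    def _phased(self, pheno, truth, snp_of_hap):
        n = len(pheno)
        hap = truth.hap_copies[:, :, 0]  # copies per haplotype at locus 0
        return pd.DataFrame(
            {
                "snp_hap1": [snp_of_hap(hap[i, 0]) for i in range(n)],
                "snp_hap2": [snp_of_hap(hap[i, 1]) for i in range(n)],
                "cnp_hap1": [str(hap[i, 0]) for i in range(n)],
                "cnp_hap2": [str(hap[i, 1]) for i in range(n)],
            }
        )

    def test_no_cnp_variation_yields_no_strata(self):
        pheno, cn, truth = make_cohort(n=500, seed=21)
        phased = pd.DataFrame(
            {"snp_hap1": ["a"] * 500, "snp_hap2": ["a"] * 500,
             "cnp_hap1": ["1"] * 500, "cnp_hap2": ["1"] * 500}
        )
        assert A.haplotype_association(pheno, phased) == []

    def test_female_specific_haplotype_effect_detected(self):
        pheno, cn, truth = make_cohort(n=4000, seed=22)
        # all subjects share one SNP haplotype pair; CNP haplotypes vary.
        phased = self._phased(pheno, truth, lambda copies: "a")
        pheno = pheno.copy()
        female = (pheno["sex"] == "F").to_numpy()
        deleted = 2.0 - cn
        pheno["trait"] = pheno["trait"] * np.exp(0.05 * deleted * female)
        results = {r.name: r for r in A.haplotype_association(pheno, phased)}
        assert results["a|a[F]"].lrt_p < 0.001
        assert results["a|a[M]"].lrt_p > 0.01

    def test_subject_cn_is_sum_of_phased_copies(self, small_cohort):
        *_, truth = small_cohort
        assert np.array_equal(truth.cn_by_locus,
                              truth.hap_copies.sum(axis=1))


class TestBinaryOutcome:
    def test_mediation_through_the_trait(self):
        cfg = sim.SimConfig(
            n_subjects=6000, chrom_lengths={"chr4": 120_000}, marker_spacing=2000,
            cnp_loci=[sim.CNPSpec("chr4", 40_000, 60_000, 0.5)], n_plates=8,
            trait_model=sim.TraitSpec(cn_effect_female=0.1, cn_effect_male=0.1,
                                      residual_sd=0.2, gout_prevalence=0.07),
            seed=23,
        )
        mmap = sim.simulate_marker_map(cfg)
        _, pheno, _, truth = sim.simulate_cohort(mmap, cfg)
        cn = truth.cn_by_locus[:, 0].astype(float)
        or_marginal, _, p_marginal = A.binary_outcome_fit(pheno, cn)
        or_adj, ci_adj, _ = A.binary_outcome_fit(pheno, cn, adjust_trait=True)
        assert or_marginal > 1.1 and p_marginal < 0.05
        assert ci_adj[0] < 1.0 < ci_adj[1]  # attenuated to null

    def test_no_path_gives_null_or(self):
        pheno, cn, _ = make_cohort(n=3000, seed=24, gout_prevalence=0.07,
                                   gout_logor_per_log_trait=0.0)
        orr, ci, p = A.binary_outcome_fit(pheno, cn)
        assert ci[0] < 1.0 < ci[1]

    def test_monomorphic_outcome_rejected(self):
        pheno, cn, _ = make_cohort(n=200, seed=25)
        pheno = pheno.assign(gout=0)
        with pytest.raises(ValueError):
            A.binary_outcome_fit(pheno, cn)


class TestMeta:
    def test_inverse_variance_combination(self):
        e1 = A.pct_change(0.05, 0.01)
        e2 = A.pct_change(0.03, 0.02)
        comb = A.inverse_variance_combine([e1, e2])
        w1, w2 = 1 / 0.01**2, 1 / 0.02**2
        expected = (w1 * 0.05 + w2 * 0.03) / (w1 + w2)
        assert comb.beta == pytest.approx(expected)
        assert comb.se < min(e1.se, e2.se)
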