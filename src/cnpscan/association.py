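"""Mixed-model association of copy number with a log-normal quantitative
trait.

The baseline model for the seasonally adjusted log trait has fixed effects
for study center, age, log BMI, sex, and age and log BMI by sex
interactions, plus a chemistry-plate random intercept.  CNP models extend it
with copy number (0-4, continuous) and optionally a copy-number-by-sex
interaction, tested against the baseline by likelihood-ratio tests (models
fitted by maximum likelihood, not REML, so fixed-effect LRTs are valid).
Because the trait is log transformed, slopes are reported as the percentage
change per integer copy via 100*(exp(beta)-1); the paper-style
(2.5, 50, 97.5) percentile triple is the Wald interval transformed to that
scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "EffectEstimate",
    "AssociationResult",
    "seasonal_adjust",
    "CNPAssociationModel",
    "CNPAssociationResults",
    "fit_baseline",
    "fit_cnp",
    "pct_change",
    "genome_scan",
    "conditional_fit",
    "haplotype_association",
    "binary_outcome_fit",
    "inverse_variance_combine",
]

Z975 = 1.959964


@dataclass
class EffectEstimate:
    """Percentage-change triple (2.5, 50, 97.5 percentiles) plus the
    underlying log-scale slope."""

    p2_5: float
    p50: float
    p97_5: float
    beta: float
    se: float
    p_value: float

    def __post_init__(self) -> None:
        if not (self.p2_5 <= self.p50 <= self.p97_5):
            raise ValueError("percentile triple must be ordered")

    def __str__(self) -> str:
        return f"_{self.p2_5:.2f}_{self.p50:.2f}_{self.p97_5:.2f}_ (p={self.p_value:.3g})"


@dataclass
class AssociationResult:
    name: str
    overall: Optional[EffectEstimate]
    female: Optional[EffectEstimate]
    male: Optional[EffectEstimate]
    lrt_stat: float
    lrt_df: int
    lrt_p: float

    def __post_init__(self) -> None:
        if self.lrt_stat < -1e-8:
            raise ValueError("LRT statistic must be non-negative")
        self.lrt_stat = max(self.lrt_stat, 0.0)


def pct_change(beta: float, se: float, per_deleted_copy: bool = False) -> EffectEstimate:
    """Percentage change of the trait per integer copy increase.

    p50 = 100*(exp(beta)-1) with Wald 2.5/97.5 percentiles; the
    per-deleted-copy framing applies the same transform to -beta.
    """
    if se < 0:
        raise ValueError("se must be non-negative")
    b = -beta if per_deleted_copy else beta
    lo, hi = b - Z975 * se, b + Z975 * se
    if se > 0:
        p = 2 * stats.norm.sf(abs(beta) / se)
    else:
        p = 0.0 if beta != 0 else 1.0
    return EffectEstimate(
        p2_5=100 * (np.exp(lo) - 1),
        p50=100 * (np.exp(b) - 1),
        p97_5=100 * (np.exp(hi) - 1),
        beta=b,
        se=se,
        p_value=float(p),
    )


def seasonal_adjust(pheno: pd.DataFrame, bandwidth_days: float = 110.0) -> pd.DataFrame:
    """Remove seasonal trends from log(trait) by a lowess smoother over the
    draw date, fitted to women and men independently.

    The bandwidth is expressed in days and converted to the lowess fraction
    over each stratum's date range.  Returns a copy of the table with an
    ``adj_log_trait`` column: residual from the smoother plus the stratum's
    grand mean.  Strata with fewer than 10 subjects pass through unadjusted
    with a warning.
    """
    out = pheno.copy()
    y = np.log(out["trait"].to_numpy(dtype=float))
    days = (
        pd.to_datetime(out["draw_date"]) - pd.to_datetime(out["draw_date"]).min()
    ).dt.days.to_numpy(dtype=float)
    adj = y.copy()
    for sex in out["sex"].unique():
        sel = (out["sex"] == sex).to_numpy()
        if sel.sum() < 10:
            warnings.warn(f"sex stratum {sex!r} has <10 subjects; not adjusted")
            continue
        span = days[sel].max() - days[sel].min()
        frac = min(max(bandwidth_days / max(span, 1.0), 0.05), 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            fitted = sm.nonparametric.lowess(
                y[sel], days[sel], frac=frac, return_sorted=False
            )
        # tied dates with few neighbours can defeat the local fit; leave
        # those observations unadjusted
        fitted = np.where(np.isfinite(fitted), fitted, y[sel].mean())
        adj[sel] = y[sel] - fitted + y[sel].mean()
    out["adj_log_trait"] = adj
    return out


def _response(pheno: pd.DataFrame) -> np.ndarray:
    if "adj_log_trait" in pheno.columns:
        return pheno["adj_log_trait"].to_numpy(dtype=float)
    return np.log(pheno["trait"].to_numpy(dtype=float))


def _baseline_design(pheno: pd.DataFrame) -> pd.DataFrame:
    male = (pheno["sex"].to_numpy() == "M").astype(float)
    X = pd.DataFrame({"const": 1.0}, index=pheno.index)
    centers = pd.get_dummies(pheno["center"], prefix="center", drop_first=True)
    for c in centers.columns:
        X[c] = centers[c].astype(float)
    X["age"] = pheno["age"].to_numpy(dtype=float)
    X["log_bmi"] = pheno["log_bmi"].to_numpy(dtype=float)
    X["male"] = male
    X["age:male"] = X["age"] * male
    X["log_bmi:male"] = X["log_bmi"] * male
    return X


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < X.shape[1]:
        bad, cols = [], []
        for name in X.columns:
            cols.append(X[name].to_numpy(dtype=float))
            if np.linalg.matrix_rank(np.column_stack(cols)) < len(cols):
                bad.append(name)
                cols.pop()
        raise ValueError(f"singular design matrix; collinear columns: {bad}")


def _fit_lmm(y: np.ndarray, X: pd.DataFrame, groups: np.ndarray):
    """Plate random-intercept LMM by ML; one plate degenerates to OLS."""
    _check_rank(X)
    if len(np.unique(groups)) < 2:
        res = sm.OLS(y, X).fit()
        return res, float(res.llf)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups)
        res = None
        for method in (None, "powell", "cg"):
            kw = {} if method is None else {"method": method}
            try:
                cand = model.fit(reml=False, **kw)
            except Exception:
                continue
            if np.isfinite(cand.llf) and np.isfinite(cand.params).all():
                res = cand
                break
        if res is None:
            # plate variance pinned at the zero boundary: the ML solution
            # coincides with OLS
            res = sm.OLS(y, X).fit()
    return res, float(res.llf)


class CNPAssociationModel:
    """Mixed-effects model of the adjusted log trait on copy number.

    Parameters
    ----------
    pheno : DataFrame
        One row per subject with trait, draw_date, sex, age, log_bmi,
        center, plate (and adj_log_trait if seasonally adjusted).
    cn : array-like, optional
        Integer copy number per subject, aligned with ``pheno`` rows;
        omit for the baseline (covariates-only) model.
    sex_interaction : bool
        Add a copy-number-by-sex interaction (the 2-df test of the CN main
        effect and interaction jointly).
    snp_dosages : dict, optional
        name -> B-allele dosage (0/1/2) vectors entering both the null and
        extended models (SNP-conditional analysis).
    """

    def __init__(
        self,
        pheno: pd.DataFrame,
        cn=None,
        sex_interaction: bool = False,
        snp_dosages: Optional[Dict[str, Sequence]] = None,
    ):
        self.pheno = pheno.reset_index(drop=True)
        self.cn = None if cn is None else np.asarray(cn, dtype=float)
        if self.cn is not None and self.cn.size != len(self.pheno):
            raise ValueError("cn vector not aligned with phenotype table")
        if self.cn is not None and np.unique(self.cn[np.isfinite(self.cn)]).size < 2:
            raise ValueError("monomorphic copy number")
        self.sex_interaction = sex_interaction
        self.snp_dosages = {
            k: np.asarray(v, dtype=float) for k, v in (snp_dosages or {}).items()
        }

    def _null_design(self) -> pd.DataFrame:
        X = _baseline_design(self.pheno)
        for name, dos in self.snp_dosages.items():
            X[name] = dos
        return X

    def fit(self, per_deleted_copy: bool = False) -> "CNPAssociationResults":
        y = _response(self.pheno)
        groups = self.pheno["plate"].to_numpy()
        mask = np.ones(len(self.pheno), dtype=bool)
        if self.cn is not None:
            mask &= np.isfinite(self.cn)
        X0 = self._null_design()
        res0, llf0 = _fit_lmm(y[mask], X0.loc[mask], groups[mask])
        if self.cn is None:
            return CNPAssociationResults(
                model=self, null_fit=res0, alt_fit=None, llf_null=llf0,
                llf_alt=llf0, lrt_df=0, per_deleted_copy=per_deleted_copy,
            )
        X1 = X0.loc[mask].copy()
        cn = self.cn[mask]
        X1["cn"] = cn
        if self.sex_interaction:
            X1["cn:male"] = cn * X1["male"].to_numpy()
        res1, llf1 = _fit_lmm(y[mask], X1, groups[mask])
        return CNPAssociationResults(
            model=self, null_fit=res0, alt_fit=res1, llf_null=llf0,
            llf_alt=llf1, lrt_df=2 if self.sex_interaction else 1,
            per_deleted_copy=per_deleted_copy,
        )


@dataclass
class CNPAssociationResults:
    model: CNPAssociationModel
    null_fit: object
    alt_fit: object
    llf_null: float
    llf_alt: float
    lrt_df: int
    per_deleted_copy: bool = False

    @property
    def lrt_stat(self) -> float:
        return max(2.0 * (self.llf_alt - self.llf_null), 0.0)

    @property
    def lrt_p(self) -> float:
        if self.lrt_df == 0:
            return float("nan")
        return float(stats.chi2.sf(self.lrt_stat, self.lrt_df))

    def _slope(self, which: str):
        """(beta, se) of the per-copy slope: overall, female or male."""
        params = self.alt_fit.params
        cov = self.alt_fit.cov_params()
        b_cn = float(params["cn"])
        v_cn = float(cov.loc["cn", "cn"])
        if which == "overall" or not self.model.sex_interaction:
            return b_cn, np.sqrt(v_cn)
        if which == "female":
            return b_cn, np.sqrt(v_cn)
        b_int = float(params["cn:male"])
        v_int = float(cov.loc["cn:male", "cn:male"])
        c = float(cov.loc["cn", "cn:male"])
        return b_cn + b_int, np.sqrt(v_cn + v_int + 2 * c)

    def effect(self, which: str = "overall") -> EffectEstimate:
        beta, se = self._slope(which)
        return pct_change(beta, se, per_deleted_copy=self.per_deleted_copy)

    def as_result(self, name: str = "cnp") -> AssociationResult:
        if self.alt_fit is None:
            raise ValueError("baseline-only fit has no copy-number effect")
        if self.model.sex_interaction:
            return AssociationResult(
                name=name, overall=None,
                female=self.effect("female"), male=self.effect("male"),
                lrt_stat=self.lrt_stat, lrt_df=self.lrt_df, lrt_p=self.lrt_p,
            )
        return AssociationResult(
            name=name, overall=self.effect("overall"), female=None, male=None,
            lrt_stat=self.lrt_stat, lrt_df=self.lrt_df, lrt_p=self.lrt_p,
        )

    def summary(self) -> str:
        unit = "per deleted copy" if self.per_deleted_copy else "per copy"
        lines = [
            f"CNP association (plate random-intercept LMM, ML): "
            f"LRT={self.lrt_stat:.2f} df={self.lrt_df} p={self.lrt_p:.3g}"
        ]
        if self.alt_fit is not None:
            if self.model.sex_interaction:
                lines.append(f"  women {unit}: {self.effect('female')}")
                lines.append(f"  men   {unit}: {self.effect('male')}")
            else:
                lines.append(f"  combined {unit}: {self.effect('overall')}")
        return "\n".join(lines)


def fit_baseline(pheno: pd.DataFrame) -> CNPAssociationResults:
    """Covariates-only mixed model (no copy-number term)."""
    if pheno["plate"].nunique() < 2:
        raise ValueError("baseline model requires at least 2 plates")
    return CNPAssociationModel(pheno).fit()


def fit_cnp(
    pheno: pd.DataFrame,
    cn,
    sex_interaction: bool = False,
    per_deleted_copy: bool = False,
) -> AssociationResult:
    """Extend the baseline with copy number (continuous 0-4) and test it by
    a 1-df (main effect) or 2-df (main effect + sex interaction) LRT."""
    fit = CNPAssociationModel(pheno, cn=cn, sex_interaction=sex_interaction).fit(
        per_deleted_copy=per_deleted_copy
    )
    return fit.as_result()


def conditional_fit(
    pheno: pd.DataFrame,
    cn,
    snp_dosages: Dict[str, Sequence],
    sex_interaction: bool = True,
) -> AssociationResult:
    """Test copy number on top of a null model that already carries SNP
    B-allele dosages (0/1/2, continuous) as fixed effects."""
    for name, dos in snp_dosages.items():
        arr = np.asarray(dos, dtype=float)
        if not np.isin(arr[np.isfinite(arr)], [0, 1, 2]).all():
            raise ValueError(f"dosages for {name} must be 0, 1 or 2")
    fit = CNPAssociationModel(
        pheno, cn=cn, sex_interaction=sex_interaction, snp_dosages=snp_dosages
    ).fit()
    return fit.as_result(name="cnp|snp")


def genome_scan(
    matrix,
    pheno: pd.DataFrame,
    sex_interaction: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fit the CNP model at every interval of a frequency-filtered
    copy-number matrix.

    Returns one row per interval with coordinates, slope, LRT, p,
    -log10(p), the expected quantile for a QQ plot, and a Bonferroni flag at
    ``alpha / n_intervals``.
    """
    rows = []
    subj = list(pheno["subject_id"])
    ph = pheno.reset_index(drop=True)
    y = _response(ph)
    groups = ph["plate"].to_numpy()
    X0 = _baseline_design(ph)
    _, llf0 = _fit_lmm(y, X0, groups)   # identical for every interval
    lrt_df = 2 if sex_interaction else 1
    for iv in matrix.intervals:
        cn = matrix.cn.loc[iv.key, subj].to_numpy(dtype=float)
        if np.unique(cn).size < 2:
            continue
        X1 = X0.copy()
        X1["cn"] = cn
        if sex_interaction:
            X1["cn:male"] = cn * X1["male"].to_numpy()
        try:
            res1, llf1 = _fit_lmm(y, X1, groups)
        except ValueError:
            continue
        lrt = max(2.0 * (llf1 - llf0), 0.0)
        beta = float(res1.params["cn"])
        se = float(np.sqrt(res1.cov_params().loc["cn", "cn"]))
        rows.append(
            (iv.key, iv.chrom, iv.start, iv.end, iv.carrier_freq,
             beta, se, lrt, lrt_df, float(stats.chi2.sf(lrt, lrt_df)))
        )
    out = pd.DataFrame(
        rows,
        columns=["interval", "chrom", "start", "end", "carrier_freq",
                 "beta", "se", "lrt_stat", "lrt_df", "p"],
    )
    n = len(out)
    if n:
        out["neg_log10_p"] = -np.log10(np.clip(out["p"], 1e-300, None))
        out["bonferroni_threshold"] = alpha / n
        out["significant"] = out["p"] < alpha / n
        ranks = out["p"].rank(method="first").to_numpy()
        out["expected_p"] = (ranks - 0.5) / n
    return out


def haplotype_association(
    pheno: pd.DataFrame, phased: pd.DataFrame, min_stratum: int = 20
) -> List[AssociationResult]:
    """Regress the adjusted log trait on CNP-haplotype-pair categories within
    strata of identical SNP-haplotype pairs.

    ``phased`` has one row per subject (aligned with ``pheno``) and columns
    snp_hap1, snp_hap2 (allele strings) and cnp_hap1, cnp_hap2 (copy strings,
    one '0'/'1' character per CNP locus).  Within each SNP-pair stratum that
    shows variation in the CNP pair, the most common CNP pair is the
    reference; the LRT df is the number of non-reference categories.  Sexes
    are analyzed separately and combined.  Strata or sex subsets without
    CNP variation are skipped.
    """
    df = pheno.reset_index(drop=True).copy()
    ph = phased.reset_index(drop=True)
    hap_pairs = [
        tuple(sorted([(ph["snp_hap1"][i], ph["cnp_hap1"][i]),
                      (ph["snp_hap2"][i], ph["cnp_hap2"][i])]))
        for i in range(len(ph))
    ]
    df["snp_pair"] = ["|".join(s for s, _ in p) for p in hap_pairs]
    df["cnp_pair"] = ["|".join(c for _, c in p) for p in hap_pairs]
    y_all = _response(df)
    results: List[AssociationResult] = []
    for snp_pair, g in df.groupby("snp_pair"):
        if len(g) < min_stratum or g["cnp_pair"].nunique() < 2:
            continue
        for label, sel in (
            ("both", np.ones(len(g), dtype=bool)),
            ("F", (g["sex"] == "F").to_numpy()),
            ("M", (g["sex"] == "M").to_numpy()),
        ):
            sub = g.loc[g.index[sel]]
            if len(sub) < min_stratum or sub["cnp_pair"].nunique() < 2:
                continue
            y = y_all[sub.index.to_numpy()]
            X0 = pd.DataFrame({"const": 1.0}, index=sub.index)
            X0["age"] = sub["age"].to_numpy(dtype=float)
            X0["log_bmi"] = sub["log_bmi"].to_numpy(dtype=float)
            if label == "both":
                X0["male"] = (sub["sex"] == "M").astype(float).to_numpy()
            ref = sub["cnp_pair"].value_counts().idxmax()
            cats = [c for c in sorted(sub["cnp_pair"].unique()) if c != ref]
            X1 = X0.copy()
            for c in cats:
                X1[f"cnp[{c}]"] = (sub["cnp_pair"] == c).astype(float).to_numpy()
            try:
                _check_rank(X1)
            except ValueError:
                continue
            r0 = sm.OLS(y, X0).fit()
            r1 = sm.OLS(y, X1).fit()
            lrt = max(2.0 * (r1.llf - r0.llf), 0.0)
            dfree = len(cats)
            results.append(
                AssociationResult(
                    name=f"{snp_pair}[{label}]",
                    overall=None, female=None, male=None,
                    lrt_stat=lrt, lrt_df=dfree,
                    lrt_p=float(stats.chi2.sf(lrt, dfree)),
                )
            )
    return results


def binary_outcome_fit(
    pheno: pd.DataFrame,
    cn,
    outcome: str = "gout",
    adjust_trait: bool = False,
):
    """Logistic model for a binary outcome with the trait-model covariates
    (plate as fixed effect here) and copy number as continuous exposure.

    Returns (odds ratio per copy, (lo, hi) 95% CI, p-value).  Optionally
    adjusts for log(trait) to assess mediation of the copy-number effect.
    """
    yb = pheno[outcome].to_numpy(dtype=float)
    if np.unique(yb).size < 2:
        raise ValueError("outcome is monomorphic")
    X = _baseline_design(pheno)
    plates = pd.get_dummies(pheno["plate"], prefix="plate", drop_first=True)
    for c in plates.columns:
        X[c] = plates[c].astype(float).to_numpy()
    if adjust_trait:
        X["log_trait"] = np.log(pheno["trait"].to_numpy(dtype=float))
    X["cn"] = np.asarray(cn, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(yb, X).fit(disp=False, maxiter=200)
    b, se = float(res.params["cn"]), float(res.bse["cn"])
    return (
        float(np.exp(b)),
        (float(np.exp(b - Z975 * se)), float(np.exp(b + Z975 * se))),
        float(res.pvalues["cn"]),
    )


def inverse_variance_combine(estimates: Sequence[EffectEstimate]) -> EffectEstimate:
    """Fixed-effect meta-analysis of log-scale slopes across cohorts."""
    betas = np.array([e.beta for e in estimates])
    ws = np.array([1.0 / e.se**2 for e in estimates])
    beta = float((ws * betas).sum() / ws.sum())
    se = float(np.sqrt(1.0 / ws.sum()))
    return pct_change(beta, se)
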