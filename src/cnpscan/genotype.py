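"""Bayesian genotyping of a CNP locus from region-averaged log R ratios.

At a deletion polymorphism the per-subject average LRR over the locus is a
mixture of three normal components induced by the latent copy number
(0: homozygous deletion, 1: hemizygous, 2: diploid).  ``CopyNumberMixture``
fits the 3-component normal mixture by a conjugate Gibbs sampler and the
results object assigns each subject the maximum-a-posteriori component as
its integer copy number.

Model, for subject i with region-averaged LRR x_i:

    x_i | z_i = k  ~  Normal(mu_k, sigma_k^2)
    z_i            ~  Categorical(w),         w ~ Dirichlet(1, 1, 1)
    mu_k           ~  Normal(m0_k, 1),        sigma_k^2 ~ InvGamma(2, 0.05)

Identifiability under label switching is enforced by relabeling components in
ascending mean order every sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "MixturePriors",
    "CopyNumberMixture",
    "CopyNumberMixtureResults",
    "region_mean_lrr",
    "gibbs_mixture",
    "map_assign",
    "genotype_concordance",
]


@dataclass
class MixturePriors:
    """Conjugate priors. ``mean_centers`` defaults to the empirical tertile
    centers of the data (set at fit time when None)."""

    mean_centers: Optional[np.ndarray] = None
    mean_sd: float = 1.0
    var_shape: float = 2.0
    var_scale: float = 0.05
    weight_conc: np.ndarray = field(default_factory=lambda: np.ones(3))


class CopyNumberMixture:
    """3-component normal mixture on region-averaged log R ratios.

    Parameters
    ----------
    values : array-like
        Per-subject average LRR over the CNP locus; NaN entries are dropped
        (their subjects receive no copy-number call).
    """

    def __init__(self, values, k: int = 3):
        values = np.asarray(values, dtype=float)
        self.k = int(k)
        self._mask = np.isfinite(values)
        self.values = values
        self.endog = values[self._mask]
        if self.endog.size < 3 * self.k:
            raise ValueError(f"need at least {3 * self.k} finite observations")

    def fit(
        self,
        n_iter: int = 4000,
        burn_in: int = 1000,
        seed: int = 0,
        priors: Optional[MixturePriors] = None,
    ) -> "CopyNumberMixtureResults":
        if burn_in >= n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        priors = priors or MixturePriors()
        rng = np.random.default_rng(seed)
        x = self.endog
        n, k = x.size, self.k

        if priors.mean_centers is None:
            qs = np.quantile(x, (np.arange(k) + 0.5) / k)
            m0 = np.asarray(qs, dtype=float)
        else:
            m0 = np.asarray(priors.mean_centers, dtype=float)
        t0_var = priors.mean_sd**2
        a0, b0 = priors.var_shape, priors.var_scale
        alpha = np.asarray(priors.weight_conc, dtype=float)

        mu = m0.copy()
        s2 = np.full(k, max(x.var(), 1e-4))
        w = np.full(k, 1.0 / k)

        keep = n_iter - burn_in
        resp_sum = np.zeros((n, k))
        mu_draws = np.empty((keep, k))
        s2_draws = np.empty((keep, k))
        w_draws = np.empty((keep, k))
        n_empty_sweeps = 0

        for it in range(n_iter):
            # z | params  (Gumbel-max categorical sampling, vectorized)
            logp = (
                np.log(w)[None, :]
                - 0.5 * np.log(2 * np.pi * s2)[None, :]
                - 0.5 * (x[:, None] - mu[None, :]) ** 2 / s2[None, :]
            )
            g = rng.gumbel(size=(n, k))
            z = np.argmax(logp + g, axis=1)
            counts = np.bincount(z, minlength=k)
            if (counts == 0).any():
                n_empty_sweeps += 1

            # mu | z, s2
            sums = np.bincount(z, weights=x, minlength=k)
            post_var = 1.0 / (counts / s2 + 1.0 / t0_var)
            post_mean = post_var * (sums / s2 + m0 / t0_var)
            mu = rng.normal(post_mean, np.sqrt(post_var))

            # s2 | z, mu
            sq = np.bincount(z, weights=(x - mu[z]) ** 2, minlength=k)
            s2 = 1.0 / rng.gamma(a0 + counts / 2.0, 1.0 / (b0 + sq / 2.0))

            # w | z
            w = rng.dirichlet(alpha + counts)

            # relabel by ascending mean (identifiability)
            order = np.argsort(mu)
            mu, s2, w = mu[order], s2[order], w[order]

            if it >= burn_in:
                j = it - burn_in
                mu_draws[j], s2_draws[j], w_draws[j] = mu, s2, w
                logp = (
                    np.log(np.clip(w, 1e-300, None))[None, :]
                    - 0.5 * np.log(2 * np.pi * s2)[None, :]
                    - 0.5 * (x[:, None] - mu[None, :]) ** 2 / s2[None, :]
                )
                r = np.exp(logp - logp.max(axis=1, keepdims=True))
                resp_sum += r / r.sum(axis=1, keepdims=True)

        posterior = np.full((self.values.size, k), np.nan)
        posterior[self._mask] = resp_sum / keep
        return CopyNumberMixtureResults(
            model=self,
            means=mu_draws.mean(axis=0),
            means_sd=mu_draws.std(axis=0),
            variances=s2_draws.mean(axis=0),
            weights=w_draws.mean(axis=0),
            posterior_prob=posterior,
            n_iter=n_iter,
            burn_in=burn_in,
            seed=seed,
            degenerate=n_empty_sweeps > 0.5 * n_iter,
            n_empty_sweeps=n_empty_sweeps,
        )


@dataclass
class CopyNumberMixtureResults:
    """Posterior summaries of the fitted mixture.

    Component index equals inferred copy number (0, 1, 2) since means are
    ordered ascending and lower LRR means fewer copies.
    """

    model: CopyNumberMixture
    means: np.ndarray
    means_sd: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    posterior_prob: np.ndarray   # (n_subjects, k); NaN rows for missing input
    n_iter: int
    burn_in: int
    seed: int
    degenerate: bool
    n_empty_sweeps: int

    @property
    def map_cn(self) -> np.ndarray:
        """MAP copy number per subject; ties resolve to the lower copy
        number; -1 marks subjects with no finite input."""
        out = np.full(self.posterior_prob.shape[0], -1, dtype=np.int64)
        ok = np.isfinite(self.posterior_prob).all(axis=1)
        out[ok] = np.argmax(self.posterior_prob[ok], axis=1)  # first max -> lower CN
        return out

    def summary(self) -> str:
        lines = [
            "3-component normal mixture (Gibbs), "
            f"{self.n_iter} sweeps, burn-in {self.burn_in}, seed {self.seed}",
            f"{'CN':>3} {'mean':>9} {'sd(mean)':>9} {'variance':>9} {'weight':>8} {'n_MAP':>7}",
        ]
        cn_counts = np.bincount(self.map_cn[self.map_cn >= 0], minlength=len(self.means))
        for k in range(len(self.means)):
            lines.append(
                f"{k:>3} {self.means[k]:>9.4f} {self.means_sd[k]:>9.4f} "
                f"{self.variances[k]:>9.4f} {self.weights[k]:>8.4f} {cn_counts[k]:>7d}"
            )
        if self.degenerate:
            lines.append("WARNING: empty component in >50% of sweeps")
        return "\n".join(lines)

    def to_frame(self, subject_ids=None) -> pd.DataFrame:
        n = self.posterior_prob.shape[0]
        idx = subject_ids if subject_ids is not None else np.arange(n)
        df = pd.DataFrame(
            self.posterior_prob, index=idx,
            columns=[f"p_cn{k}" for k in range(self.posterior_prob.shape[1])],
        )
        df["map_cn"] = self.map_cn
        return df


def region_mean_lrr(data, region) -> np.ndarray:
    """Per-subject arithmetic mean LRR over the markers of a region.

    ``region`` is (chrom, start, end), 1-based closed.  Missing markers are
    skipped; a subject with no observed marker gets NaN.
    """
    chrom, start, end = region
    sel = (
        (data.map["chrom"].to_numpy() == chrom)
        & (data.map["pos"].to_numpy() >= start)
        & (data.map["pos"].to_numpy() <= end)
    )
    if not sel.any():
        raise ValueError(f"region {chrom}:{start}-{end} contains no markers")
    with np.errstate(invalid="ignore"):
        block = data.lrr[:, sel]
        out = np.full(block.shape[0], np.nan)
        ok = np.isfinite(block).any(axis=1)
        out[ok] = np.nanmean(block[ok], axis=1)
    return out


def gibbs_mixture(
    values, k: int = 3, priors: Optional[MixturePriors] = None,
    n_iter: int = 4000, burn_in: int = 1000, seed: int = 0,
) -> CopyNumberMixtureResults:
    """Convenience wrapper: fit the mixture and return the results object."""
    return CopyNumberMixture(values, k=k).fit(
        n_iter=n_iter, burn_in=burn_in, seed=seed, priors=priors
    )


def map_assign(fit: CopyNumberMixtureResults) -> np.ndarray:
    """Integer copy number from the component of highest posterior
    probability (ascending-mean order; ties toward the lower copy number)."""
    return fit.map_cn


def genotype_concordance(map_cn: np.ndarray, calls: Sequence) -> pd.DataFrame:
    """Contingency table of inferred copy number vs biallelic genotype call.

    Calls are 'A', 'AB', 'B' or missing (None/NaN); hemizygous subjects can
    only populate the homozygous-looking A and B clusters, and homozygous
    deletions should be missing.
    """
    call_labels = [
        "missing" if (c is None or (isinstance(c, float) and np.isnan(c))) else str(c)
        for c in calls
    ]
    return pd.crosstab(
        pd.Series(map_cn, name="map_cn"), pd.Series(call_labels, name="genotype")
    )
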