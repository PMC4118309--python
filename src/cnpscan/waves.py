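"""Genomic-wave correction: residualize log R ratios on local GC content.

Genomic waves are slow, GC-correlated spatial trends in array log R ratios
that inflate false-positive copy-number calls.  The correction regresses each
subject's LRR on a windowed-GC covariate and keeps the residuals, recentered
to the subject's original mean so that genome-wide copy-number dosage is
untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .simulate import IntensityData

__all__ = ["WaveFit", "windowed_gc", "select_window", "correct_waves",
           "DEFAULT_WINDOWS"]

DEFAULT_WINDOWS = (10_000, 50_000, 250_000, 1_000_000)


@dataclass
class WaveFit:
    """Diagnostics from one wave-correction pass."""

    chosen_window: int
    beta: np.ndarray              # per-subject slope of LRR on windowed GC
    r2: np.ndarray                # per-subject squared correlation
    acf10_pre: np.ndarray
    acf10_post: np.ndarray
    degenerate: bool = False      # constant GC covariate -> correction skipped

    def to_frame(self, subject_ids) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": subject_ids,
                "window": self.chosen_window,
                "beta": self.beta,
                "r2": self.r2,
                "acf10_pre": self.acf10_pre,
                "acf10_post": self.acf10_post,
            }
        )


def windowed_gc(mmap: pd.DataFrame, window: int) -> np.ndarray:
    """Mean GC over markers within +-window/2 bp of each marker.

    Windows are computed within chromosome; edge windows truncate.  A window
    smaller than the local marker spacing degenerates to the marker's own GC.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    out = np.empty(len(mmap))
    half = window / 2.0
    for _, g in mmap.groupby("chrom", sort=False):
        pos = g["pos"].to_numpy(dtype=float)
        gc = g["gc"].to_numpy()
        lo = np.searchsorted(pos, pos - half, side="left")
        hi = np.searchsorted(pos, pos + half, side="right")
        csum = np.concatenate(([0.0], np.cumsum(gc)))
        out[g.index.to_numpy()] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def _corr_rows(lrr: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Pearson correlation of every LRR row with the covariate x."""
    xc = x - x.mean()
    denom_x = np.sqrt((xc**2).sum())
    yc = lrr - lrr.mean(axis=1, keepdims=True)
    denom_y = np.sqrt((yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (yc @ xc) / (denom_y * denom_x)
    return np.nan_to_num(r)


def select_window(data: IntensityData, candidate_windows=DEFAULT_WINDOWS) -> int:
    """Pick the GC window maximizing the median (over subjects) squared
    correlation between LRR and windowed GC; ties go to the smallest window.
    """
    candidates = sorted(int(w) for w in candidate_windows)
    if not candidates:
        raise ValueError("need at least one candidate window")
    best_w, best_score = candidates[0], -np.inf
    for w in candidates:
        x = windowed_gc(data.map, w)
        score = float(np.median(_corr_rows(data.lrr, x) ** 2))
        if score > best_score + 1e-15:
            best_w, best_score = w, score
    return best_w


def lag_autocorr(rows: np.ndarray, lag: int = 10) -> np.ndarray:
    """Row-wise lag-k autocorrelation with biased (1/n) normalization."""
    yc = rows - rows.mean(axis=1, keepdims=True)
    var = (yc**2).mean(axis=1)
    cov = (yc[:, lag:] * yc[:, :-lag]).sum(axis=1) / rows.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = cov / var
    return np.where(var > 0, out, 0.0)


def correct_waves(data: IntensityData, window: int):
    """Residualize each subject's LRR on the windowed-GC covariate.

    Returns ``(corrected: IntensityData, fit: WaveFit)``.  Per subject the
    least-squares projection onto the covariate is removed and the residual
    recentered to the subject's original mean LRR; BAF is untouched.  A
    constant covariate makes the regression degenerate: the data pass through
    unchanged with ``fit.degenerate`` set.
    """
    x = windowed_gc(data.map, window)
    acf_pre = lag_autocorr(data.lrr)
    xc = x - x.mean()
    ssx = float((xc**2).sum())
    n_sub = data.n_subjects
    if ssx <= 1e-12 * len(x):
        fit = WaveFit(
            chosen_window=int(window),
            beta=np.zeros(n_sub),
            r2=np.zeros(n_sub),
            acf10_pre=acf_pre,
            acf10_post=acf_pre.copy(),
            degenerate=True,
        )
        return data, fit
    mean_lrr = data.lrr.mean(axis=1, keepdims=True)
    yc = data.lrr - mean_lrr
    beta = (yc @ xc) / ssx
    resid = data.lrr - beta[:, None] * xc[None, :]
    # projection removes a zero-mean covariate, so the subject mean is
    # already preserved; recenter explicitly to pin it exactly
    resid += mean_lrr - resid.mean(axis=1, keepdims=True)
    r2 = _corr_rows(data.lrr, x) ** 2
    corrected = replace(data, lrr=resid)
    fit = WaveFit(
        chosen_window=int(window),
        beta=beta,
        r2=r2,
        acf10_pre=acf_pre,
        acf10_post=lag_autocorr(resid),
        degenerate=False,
    )
    return corrected, fit
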