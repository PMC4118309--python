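"""Six-state hidden Markov segmentation of wave-corrected SNP-array
intensities.

The chain has five distinct copy-number levels (0-4) plus a copy-neutral
run-of-homozygosity state: CN0, CN1, CN2, CN2-ROH, CN3, CN4.  The ROH state
shares the diploid LRR level with CN2 but permits only homozygous B allele
frequency clusters, absorbing long homozygous stretches that would otherwise
masquerade as deletions.  Emissions combine a Gaussian LRR term with a
genotype-cluster BAF mixture at SNPs; nonpolymorphic markers contribute LRR
only.  Transitions decay with inter-marker distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .simulate import IntensityData

__all__ = [
    "STATE_LABELS",
    "STATE_CN",
    "HMMParams",
    "CNVSegment",
    "emission_loglik",
    "transition_matrix",
    "decode_states",
    "viterbi_segments",
    "forward_backward",
    "filter_min_markers",
    "segments_to_frame",
]

STATE_LABELS = ("CN0", "CN1", "CN2", "CN2-ROH", "CN3", "CN4")
STATE_CN = np.array([0, 1, 2, 2, 3, 4])

# permitted BAF cluster centers per state; None -> Uniform(0,1) (no signal)
_BAF_CLUSTERS = (
    None,                                   # CN0: noise
    np.array([0.0, 1.0]),                   # CN1: hemizygous A or B
    np.array([0.0, 0.5, 1.0]),              # CN2
    np.array([0.0, 1.0]),                   # CN2-ROH: homozygous only
    np.array([0.0, 1 / 3, 2 / 3, 1.0]),     # CN3
    np.array([0.0, 0.25, 0.5, 0.75, 1.0]),  # CN4
)


@dataclass
class HMMParams:
    lrr_mean: np.ndarray = field(
        default_factory=lambda: np.array([-2.0, -0.55, 0.0, 0.0, 0.35, 0.65])
    )
    lrr_sd: np.ndarray = field(
        default_factory=lambda: np.array([0.50, 0.25, 0.20, 0.20, 0.25, 0.30])
    )
    baf_sd: float = 0.03
    stationary: np.ndarray = field(
        default_factory=lambda: np.array([0.005, 0.03, 0.90, 0.01, 0.04, 0.015])
    )
    offdiag_total: float = 0.01     # epsilon: maximal per-step leave probability
    transition_decay: float = 100_000.0  # bp scale D

    def __post_init__(self) -> None:
        self.lrr_mean = np.asarray(self.lrr_mean, dtype=float)
        self.lrr_sd = np.asarray(self.lrr_sd, dtype=float)
        self.stationary = np.asarray(self.stationary, dtype=float)
        if (self.lrr_sd <= 0).any():
            raise ValueError("lrr_sd must be positive")
        if abs(self.stationary.sum() - 1.0) > 1e-8 or (self.stationary < 0).any():
            raise ValueError("stationary must be a probability simplex")


@dataclass
class CNVSegment:
    subject_id: str
    chrom: str
    start: int          # 1-based, closed, at marker positions
    end: int
    cn: int
    state_label: str
    n_markers: int
    mean_lrr: float


def _trunc_norm_logpdf(x: np.ndarray, center: float, sd: float) -> np.ndarray:
    """Log density of a normal truncated to [0, 1]."""
    z = norm.cdf((1.0 - center) / sd) - norm.cdf((0.0 - center) / sd)
    return norm.logpdf(x, loc=center, scale=sd) - np.log(z)


def _baf_logdensity(baf: np.ndarray, state: int, sd: float) -> np.ndarray:
    """Equal-weight mixture over the state's permitted clusters; CN0 is
    uniform on [0,1] (log density 0)."""
    clusters = _BAF_CLUSTERS[state]
    if clusters is None:
        return np.zeros_like(baf, dtype=float)
    comps = np.stack([_trunc_norm_logpdf(baf, c, sd) for c in clusters])
    from scipy.special import logsumexp

    return logsumexp(comps, axis=0) - np.log(len(clusters))


def emission_loglik(
    lrr_value: float,
    baf_value: Optional[float],
    state: int,
    is_snp: bool,
    params: Optional[HMMParams] = None,
) -> float:
    """Log emission density of one marker under one state.

    Missing (NaN) LRR contributes 0; BAF enters only at SNPs with an
    observed value.
    """
    params = params or HMMParams()
    total = 0.0
    if lrr_value is not None and np.isfinite(lrr_value):
        total += float(
            norm.logpdf(lrr_value, params.lrr_mean[state], params.lrr_sd[state])
        )
    if is_snp and baf_value is not None and np.isfinite(baf_value):
        total += float(_baf_logdensity(np.asarray([baf_value]), state, params.baf_sd)[0])
    return total


def emission_matrix(
    lrr: np.ndarray, baf: np.ndarray, is_snp: np.ndarray, params: HMMParams
) -> np.ndarray:
    """(n_markers, 6) log emission matrix for one subject's chromosome."""
    m = lrr.shape[0]
    out = np.zeros((m, 6))
    ok_lrr = np.isfinite(lrr)
    for s in range(6):
        out[ok_lrr, s] = norm.logpdf(
            lrr[ok_lrr], params.lrr_mean[s], params.lrr_sd[s]
        )
    ok_baf = np.asarray(is_snp, bool) & np.isfinite(baf)
    if ok_baf.any():
        b = baf[ok_baf]
        for s in range(6):
            out[ok_baf, s] += _baf_logdensity(b, s, params.baf_sd)
    return out


def transition_matrix(distance_bp: float, params: Optional[HMMParams] = None) -> np.ndarray:
    """Distance-dependent 6x6 stochastic matrix.

    Stay probability 1 - eps*(1 - exp(-d/D)); the leave mass is split over
    the other states proportionally to their stationary probabilities.
    """
    params = params or HMMParams()
    if distance_bp < 0:
        raise ValueError("distance must be non-negative")
    eps = params.offdiag_total
    leave = eps * (1.0 - np.exp(-distance_bp / params.transition_decay))
    pi = params.stationary
    T = np.empty((6, 6))
    for s in range(6):
        other = pi.copy()
        other[s] = 0.0
        tot = other.sum()
        if tot <= 0 or leave <= 0:
            T[s] = 0.0
            T[s, s] = 1.0
            continue
        T[s] = leave * other / tot
        T[s, s] = 1.0 - leave
    return T


def _chrom_blocks(mmap: pd.DataFrame):
    for chrom, g in mmap.groupby("chrom", sort=False):
        yield chrom, g.index.to_numpy()


def decode_states(
    data: IntensityData, subject: str, params: Optional[HMMParams] = None
) -> np.ndarray:
    """Viterbi state path (length n_markers) for one subject, decoded
    independently per chromosome."""
    params = params or HMMParams()
    i = data.subject_ids.index(subject)
    lrr, baf = data.lrr[i], data.baf[i]
    if not np.isfinite(lrr).any():
        raise ValueError(f"subject {subject} has no observed LRR values")
    is_snp = data.map["is_snp"].to_numpy()
    pos = data.map["pos"].to_numpy()
    path = np.empty(data.n_markers, dtype=np.int64)
    log_pi = np.log(np.clip(params.stationary, 1e-300, None))
    for _, idx in _chrom_blocks(data.map):
        E = emission_matrix(lrr[idx], baf[idx], is_snp[idx], params)
        m = len(idx)
        delta = log_pi + E[0]
        back = np.zeros((m, 6), dtype=np.int64)
        for t in range(1, m):
            logT = np.log(
                np.clip(transition_matrix(pos[idx[t]] - pos[idx[t - 1]], params),
                        1e-300, None)
            )
            cand = delta[:, None] + logT
            back[t] = cand.argmax(axis=0)
            delta = cand.max(axis=0) + E[t]
        states = np.empty(m, dtype=np.int64)
        states[-1] = int(delta.argmax())
        for t in range(m - 2, -1, -1):
            states[t] = back[t + 1, states[t + 1]]
        path[idx] = states
    return path


def path_loglik(
    data: IntensityData, subject: str, states: np.ndarray,
    params: Optional[HMMParams] = None,
) -> float:
    """Joint log likelihood of a given state path (used to certify decoding
    optimality against ground truth)."""
    params = params or HMMParams()
    i = data.subject_ids.index(subject)
    lrr, baf = data.lrr[i], data.baf[i]
    is_snp = data.map["is_snp"].to_numpy()
    pos = data.map["pos"].to_numpy()
    total = 0.0
    for _, idx in _chrom_blocks(data.map):
        E = emission_matrix(lrr[idx], baf[idx], is_snp[idx], params)
        s = states[idx]
        total += np.log(params.stationary[s[0]] + 1e-300) + E[0, s[0]]
        for t in range(1, len(idx)):
            T = transition_matrix(pos[idx[t]] - pos[idx[t - 1]], params)
            total += np.log(T[s[t - 1], s[t]] + 1e-300) + E[t, s[t]]
    return float(total)


def forward_backward(
    data: IntensityData, subject: str, params: Optional[HMMParams] = None
) -> np.ndarray:
    """Scaled forward-backward marginal posteriors, (n_markers, 6)."""
    params = params or HMMParams()
    i = data.subject_ids.index(subject)
    lrr, baf = data.lrr[i], data.baf[i]
    is_snp = data.map["is_snp"].to_numpy()
    pos = data.map["pos"].to_numpy()
    post = np.empty((data.n_markers, 6))
    for _, idx in _chrom_blocks(data.map):
        E_log = emission_matrix(lrr[idx], baf[idx], is_snp[idx], params)
        E = np.exp(E_log - E_log.max(axis=1, keepdims=True))
        m = len(idx)
        Ts = [transition_matrix(pos[idx[t]] - pos[idx[t - 1]], params) for t in range(1, m)]
        alpha = np.empty((m, 6))
        c = np.empty(m)
        a = params.stationary * E[0]
        c[0] = a.sum()
        alpha[0] = a / c[0]
        for t in range(1, m):
            a = (alpha[t - 1] @ Ts[t - 1]) * E[t]
            c[t] = a.sum()
            alpha[t] = a / c[t]
        beta = np.empty((m, 6))
        beta[-1] = 1.0
        for t in range(m - 2, -1, -1):
            beta[t] = (Ts[t] @ (E[t + 1] * beta[t + 1])) / c[t + 1]
        g = alpha * beta
        post[idx] = g / g.sum(axis=1, keepdims=True)
    return post


def viterbi_segments(
    data: IntensityData, subject: str, params: Optional[HMMParams] = None
) -> List[CNVSegment]:
    """Decode one subject and collapse the path into CNV segments.

    Maximal runs of a constant state become segments; only non-diploid runs
    (CN != 2) are emitted as CNVs — CN2 and CN2-ROH runs are copy-neutral.
    """
    params = params or HMMParams()
    path = decode_states(data, subject, params)
    i = data.subject_ids.index(subject)
    lrr = data.lrr[i]
    pos = data.map["pos"].to_numpy()
    chroms = data.map["chrom"].to_numpy()
    segments: List[CNVSegment] = []
    for chrom, idx in _chrom_blocks(data.map):
        s = path[idx]
        change = np.flatnonzero(np.diff(s)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(s)]))
        for a, b in zip(starts, ends):
            st = int(s[a])
            if STATE_CN[st] == 2:
                continue
            sel = idx[a:b]
            with np.errstate(invalid="ignore"):
                mean_lrr = float(np.nanmean(lrr[sel]))
            segments.append(
                CNVSegment(
                    subject_id=subject,
                    chrom=str(chrom),
                    start=int(pos[sel[0]]),
                    end=int(pos[sel[-1]]),
                    cn=int(STATE_CN[st]),
                    state_label=STATE_LABELS[st],
                    n_markers=int(b - a),
                    mean_lrr=mean_lrr,
                )
            )
    return segments


def filter_min_markers(
    segments: Sequence[CNVSegment], min_markers: int = 10
) -> List[CNVSegment]:
    """Drop CNV calls supported by fewer than ``min_markers`` markers."""
    return [s for s in segments if s.n_markers >= min_markers]


def segments_to_frame(segments: Sequence[CNVSegment]) -> pd.DataFrame:
    """BED-like table: 0-based half-open start0/end plus call metadata."""
    rows = [
        (s.chrom, s.start - 1, s.end, s.subject_id, s.cn, s.state_label,
         s.n_markers, s.mean_lrr)
        for s in segments
    ]
    return pd.DataFrame(
        rows,
        columns=["chrom", "start0", "end", "subject_id", "cn", "state_label",
                 "n_markers", "mean_lrr"],
    )
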