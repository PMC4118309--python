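"""Per-sample quality control and CNV burden summaries.

Samples with residual genomic waves show high spatial autocorrelation and
spread in their log R ratios, and inflated CNV call counts.  The exclusion
rule is: lag-10 autocorrelation > 0.03, or normal-consistent MAD > 0.32, or
more than 100 CNV calls — all strict inequalities, so values exactly at a
cutoff are retained.  A genotype-cluster signal-to-noise ratio is reported as
an array-quality diagnostic but never used for exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .hmm import CNVSegment

__all__ = [
    "QCRecord",
    "lag_autocorrelation",
    "robust_spread",
    "snr_metric",
    "compute_qc_metrics",
    "apply_qc",
    "burden_summary",
]

MAD_SCALE = 1.4826  # normal-consistency constant
SNR_CAP = 1e6


@dataclass
class QCRecord:
    subject_id: str
    lag10_acf: float
    lrr_mad: float
    n_cnv: int
    snr: Optional[float] = None
    excluded: bool = False
    reasons: List[str] = field(default_factory=list)


def lag_autocorrelation(lrr_row: np.ndarray, lag: int = 10) -> float:
    """Autocorrelation of the genome-ordered LRR series at the given lag.

    Mean-centered with biased (1/n) normalization, computed across the
    concatenated autosomes in map order.  A constant series returns 0.
    """
    x = np.asarray(lrr_row, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < lag + 2:
        raise ValueError(f"need at least {lag + 2} markers for lag-{lag} ACF")
    xc = x - x.mean()
    var = float((xc**2).mean())
    if var == 0:
        return 0.0
    return float((xc[lag:] * xc[:-lag]).sum() / x.size / var)


def robust_spread(lrr_row: np.ndarray) -> float:
    """Normal-consistent median absolute deviation:
    1.4826 * median(|x - median(x)|)."""
    x = np.asarray(lrr_row, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need at least 2 markers")
    return float(MAD_SCALE * np.median(np.abs(x - np.median(x))))


def snr_metric(cluster_values: Dict[str, np.ndarray]) -> Optional[float]:
    """Genotype-cluster separation: between-cluster variance of the allelic
    contrast over the mean within-cluster variance.

    ``cluster_values`` maps genotype label -> contrast values of the samples
    called in that cluster.  Fewer than 2 observed clusters yields None;
    perfectly tight clusters are capped at 1e6.
    """
    groups = [np.asarray(v, float) for v in cluster_values.values() if len(v) > 0]
    if len(groups) < 2:
        return None
    centers = np.array([g.mean() for g in groups])
    sizes = np.array([len(g) for g in groups], dtype=float)
    w = sizes / sizes.sum()
    grand = float((w * centers).sum())
    between = float((w * (centers - grand) ** 2).sum())
    within = float(np.mean([g.var() for g in groups]))
    if within == 0:
        return SNR_CAP if between > 0 else 0.0
    return min(between / within, SNR_CAP)


def compute_qc_metrics(
    data, segments_by_subject: Dict[str, Sequence[CNVSegment]],
    snr: Optional[Dict[str, float]] = None,
) -> List[QCRecord]:
    """Assemble pre-decision QC records from intensities and CNV calls."""
    records = []
    for i, sid in enumerate(data.subject_ids):
        records.append(
            QCRecord(
                subject_id=sid,
                lag10_acf=lag_autocorrelation(data.lrr[i]),
                lrr_mad=robust_spread(data.lrr[i]),
                n_cnv=len(segments_by_subject.get(sid, [])),
                snr=None if snr is None else snr.get(sid),
            )
        )
    return records


def apply_qc(
    records: Sequence[QCRecord],
    acf_max: float = 0.03,
    mad_max: float = 0.32,
    cnv_max: int = 100,
) -> List[QCRecord]:
    """Mark exclusions: acf > acf_max OR mad > mad_max OR n_cnv > cnv_max.

    Strict inequalities — a sample exactly at a threshold passes.
    """
    out = []
    for r in records:
        reasons = []
        if r.lag10_acf > acf_max:
            reasons.append("autocorrelation")
        if r.lrr_mad > mad_max:
            reasons.append("mad")
        if r.n_cnv > cnv_max:
            reasons.append("cnv_count")
        out.append(
            QCRecord(
                subject_id=r.subject_id,
                lag10_acf=r.lag10_acf,
                lrr_mad=r.lrr_mad,
                n_cnv=r.n_cnv,
                snr=r.snr,
                excluded=bool(reasons),
                reasons=reasons,
            )
        )
    return out


def qc_frame(records: Sequence[QCRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "lag10_acf": [r.lag10_acf for r in records],
            "lrr_mad": [r.lrr_mad for r in records],
            "n_cnv": [r.n_cnv for r in records],
            "snr": [r.snr for r in records],
            "excluded": [r.excluded for r in records],
            "reasons": [";".join(r.reasons) for r in records],
        }
    )


def burden_summary(segments: Sequence[CNVSegment]) -> pd.DataFrame:
    """Per-subject CNV burden: counts, deletion/duplication split, cumulative
    kb, and size classes (<25 kb, 25-200 kb, >200 kb).

    The returned frame has one row per subject plus a 'cohort_median' row.
    """
    per: Dict[str, Dict[str, float]] = {}
    for s in segments:
        d = per.setdefault(
            s.subject_id,
            {"n_cnv": 0, "n_del": 0, "n_dup": 0, "kb": 0.0,
             "n_lt25kb": 0, "n_25_200kb": 0, "n_gt200kb": 0},
        )
        size_kb = (s.end - s.start + 1) / 1000.0
        d["n_cnv"] += 1
        d["n_del" if s.cn < 2 else "n_dup"] += 1
        d["kb"] += size_kb
        if size_kb < 25:
            d["n_lt25kb"] += 1
        elif size_kb <= 200:
            d["n_25_200kb"] += 1
        else:
            d["n_gt200kb"] += 1
    if not per:
        cols = ["n_cnv", "n_del", "n_dup", "kb", "n_lt25kb", "n_25_200kb", "n_gt200kb"]
        empty = pd.DataFrame(columns=cols)
        empty.loc["cohort_median"] = 0
        empty.index.name = "subject_id"
        return empty
    out = pd.DataFrame.from_dict(per, orient="index").sort_index()
    out.index.name = "subject_id"
    out.loc["cohort_median"] = out.median()
    return out
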