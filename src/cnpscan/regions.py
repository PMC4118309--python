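"""Disjoint genomic intervals from cohort CNV breakpoints, the copy-number
matrix, and carrier-frequency selection of copy-number polymorphisms.

Across samples CNVs partially overlap; cutting the covered territory at every
observed start/end coordinate yields maximal disjoint intervals on which every
subject's copy number is constant ("unambiguous"), so a rectangular
interval x subject matrix of integer copy number is well defined.  Intervals
where at least 1% of subjects carry a deletion or duplication constitute the
CNPs; genomically adjacent retained intervals merge into loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd

from .hmm import CNVSegment

__all__ = [
    "DisjointInterval",
    "CopyNumberMatrix",
    "breakpoint_union",
    "build_cn_matrix",
    "frequency_filter",
    "group_loci",
    "intervals_to_frame",
]


@dataclass
class DisjointInterval:
    chrom: str
    start: int      # 1-based closed
    end: int
    n_markers: int
    carrier_count: int = 0
    carrier_freq: float = 0.0

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class CopyNumberMatrix:
    """Intervals x subjects integer copy number (2 where no CNV overlaps)."""

    intervals: List[DisjointInterval]
    cn: pd.DataFrame   # index = interval keys, columns = subject ids

    def __post_init__(self) -> None:
        if len(self.intervals) != len(self.cn):
            raise ValueError("intervals and matrix rows disagree")
        vals = self.cn.to_numpy()
        if vals.size and not np.isin(vals, [0, 1, 2, 3, 4]).all():
            raise ValueError("copy number entries must be integers 0..4")


def breakpoint_union(
    segments: Sequence[CNVSegment], mmap: pd.DataFrame
) -> List[DisjointInterval]:
    """Cut the CNV-covered territory at every segment boundary.

    Per chromosome, the union of start and end coordinates across all CNVs
    defines cut points; the covered bases split into maximal disjoint pieces
    such that every segment is an exact union of pieces.  Pieces containing no
    marker are dropped.
    """
    out: List[DisjointInterval] = []
    by_chrom: dict = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    pos_by_chrom = {c: np.sort(g["pos"].to_numpy()) for c, g in mmap.groupby("chrom")}
    for chrom in sorted(by_chrom):
        segs = by_chrom[chrom]
        starts = np.array([s.start for s in segs])
        ends = np.array([s.end for s in segs])
        cuts = np.unique(np.concatenate([starts, ends + 1]))
        pieces = np.column_stack([cuts[:-1], cuts[1:] - 1])
        # a piece lies inside the covered union iff some segment spans it
        covered = np.zeros(len(pieces), dtype=bool)
        for s in segs:
            covered |= (pieces[:, 0] >= s.start) & (pieces[:, 1] <= s.end)
        pos = pos_by_chrom.get(chrom, np.array([], dtype=int))
        for a, b in pieces[covered]:
            nm = int(
                np.searchsorted(pos, b, side="right")
                - np.searchsorted(pos, a, side="left")
            )
            if nm >= 1:
                out.append(DisjointInterval(chrom=chrom, start=int(a), end=int(b),
                                            n_markers=nm))
    return out


def build_cn_matrix(
    intervals: Sequence[DisjointInterval],
    segments: Sequence[CNVSegment],
    subject_ids: Sequence[str],
) -> CopyNumberMatrix:
    """Fill the intervals x subjects matrix from the CNV calls.

    Every interval overlapped by a subject's segment must be fully contained
    in it (guaranteed when intervals come from ``breakpoint_union`` on the
    same calls); partial overlap, or two same-subject segments with different
    copy number on one interval, is a contract violation.
    """
    keys = [iv.key for iv in intervals]
    mat = pd.DataFrame(2, index=keys, columns=list(subject_ids), dtype=np.int64)
    by_chrom: dict = {}
    for j, iv in enumerate(intervals):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, keys[j]))
    for s in segments:
        for a, b, key in by_chrom.get(s.chrom, []):
            if b < s.start or a > s.end:
                continue
            if not (a >= s.start and b <= s.end):
                raise ValueError(
                    f"segment {s.subject_id} {s.chrom}:{s.start}-{s.end} "
                    f"partially overlaps interval {key}"
                )
            prev = mat.at[key, s.subject_id]
            if prev != 2 and prev != s.cn:
                raise ValueError(
                    f"ambiguous copy number for {s.subject_id} at {key}"
                )
            mat.at[key, s.subject_id] = s.cn
    ivs = [
        DisjointInterval(iv.chrom, iv.start, iv.end, iv.n_markers) for iv in intervals
    ]
    carriers = (mat.to_numpy() != 2).sum(axis=1)
    n = len(subject_ids)
    for iv, c in zip(ivs, carriers):
        iv.carrier_count = int(c)
        iv.carrier_freq = float(c) / n if n else 0.0
    return CopyNumberMatrix(intervals=ivs, cn=mat)


def frequency_filter(
    matrix: CopyNumberMatrix, min_freq: float = 0.01
) -> CopyNumberMatrix:
    """Keep intervals where carriers (copy number != 2) are at least
    ``min_freq`` of the cohort."""
    keep = [i for i, iv in enumerate(matrix.intervals) if iv.carrier_freq >= min_freq]
    return CopyNumberMatrix(
        intervals=[matrix.intervals[i] for i in keep],
        cn=matrix.cn.iloc[keep],
    )


def group_loci(
    intervals: Sequence[DisjointInterval], mmap: pd.DataFrame
) -> pd.DataFrame:
    """Merge genomically adjacent retained intervals into CNP loci.

    Adjacency is marker-relative: two retained intervals belong to the same
    locus when no marker lies strictly between them.  Returns a frame with
    chrom, start, end, n_intervals, n_markers.
    """
    pos_by_chrom = {c: np.sort(g["pos"].to_numpy()) for c, g in mmap.groupby("chrom")}
    rows = []
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start))
    i = 0
    while i < len(ivs):
        chrom, start, end = ivs[i].chrom, ivs[i].start, ivs[i].end
        n_int, n_mark = 1, ivs[i].n_markers
        pos = pos_by_chrom.get(chrom, np.array([], dtype=int))
        j = i + 1
        while j < len(ivs) and ivs[j].chrom == chrom:
            between = int(
                np.searchsorted(pos, ivs[j].start, side="left")
                - np.searchsorted(pos, end, side="right")
            )
            if between > 0:
                break
            end = max(end, ivs[j].end)
            n_int += 1
            n_mark += ivs[j].n_markers
            j += 1
        rows.append((chrom, start, end, n_int, n_mark))
        i = j
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_intervals",
                                       "n_markers"])


def intervals_to_frame(intervals: Sequence[DisjointInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in intervals],
            "start": [iv.start for iv in intervals],
            "end": [iv.end for iv in intervals],
            "n_markers": [iv.n_markers for iv in intervals],
            "carrier_count": [iv.carrier_count for iv in intervals],
            "carrier_freq": [iv.carrier_freq for iv in intervals],
        }
    )
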