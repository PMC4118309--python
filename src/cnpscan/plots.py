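"""Manhattan and QQ figures for genome-scan results."""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

__all__ = ["manhattan_plot", "qq_plot"]


def manhattan_plot(scan, ax=None, alpha: float = 0.05):
    """-log10(p) against genomic position with the Bonferroni line.

    ``scan`` is the frame returned by ``association.genome_scan``.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    offset = 0
    for i, (chrom, g) in enumerate(scan.groupby("chrom", sort=False)):
        ax.scatter(g["start"] + offset, g["neg_log10_p"], s=8,
                   color="C0" if i % 2 == 0 else "C1", label=None)
        offset += g["end"].max()
    if len(scan):
        thr = alpha / len(scan)
        ax.axhline(-np.log10(thr), color="red", ls="--", lw=1)
    ax.set_xlabel("genomic position (bp)")
    ax.set_ylabel(r"$-\log_{10}\,p$")
    return ax


def qq_plot(scan, ax=None):
    """Observed vs expected -log10(p) quantiles for the scan."""
    if ax is None:
        _, ax = plt.subplots(figsize=(3.5, 3.5))
    obs = -np.log10(np.sort(np.clip(scan["p"].to_numpy(), 1e-300, None)))
    exp = -np.log10((np.arange(len(obs)) + 0.5) / len(obs))[::-1]
    ax.scatter(np.sort(exp), np.sort(obs), s=8)
    lim = max(exp.max(), obs.max()) if len(obs) else 1.0
    ax.plot([0, lim], [0, lim], color="gray", lw=1)
    ax.set_xlabel(r"expected $-\log_{10}\,p$")
    ax.set_ylabel(r"observed $-\log_{10}\,p$")
    return ax
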