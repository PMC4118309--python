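"""Plain-text (TSV/JSON) persistence for every pipeline stage.

Intensity matrices are written markers-as-rows, subjects-as-columns; all
coordinates in TSVs are 1-based closed except BED exports, which are 0-based
half-open.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .simulate import IntensityData

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_manifest",
]


def write_cohort(
    outdir,
    data: IntensityData,
    pheno: Optional[pd.DataFrame] = None,
    genotypes: Optional[pd.DataFrame] = None,
) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    data.map.to_csv(out / "marker_map.tsv", sep="\t", index=False)
    idx = data.map["marker_id"]
    pd.DataFrame(data.lrr.T, index=idx, columns=data.subject_ids).to_csv(
        out / "lrr.tsv", sep="\t", float_format="%.5f"
    )
    pd.DataFrame(data.baf.T, index=idx, columns=data.subject_ids).to_csv(
        out / "baf.tsv", sep="\t", float_format="%.5f"
    )
    if pheno is not None:
        pheno.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    if genotypes is not None:
        genotypes.to_csv(out / "genotypes.tsv", sep="\t")


def read_cohort(indir):
    ind = Path(indir)
    mmap = pd.read_csv(ind / "marker_map.tsv", sep="\t")
    lrr = pd.read_csv(ind / "lrr.tsv", sep="\t", index_col=0)
    baf = pd.read_csv(ind / "baf.tsv", sep="\t", index_col=0)
    data = IntensityData(
        lrr=lrr.to_numpy().T,
        baf=baf.to_numpy().T,
        map=mmap,
        subject_ids=list(lrr.columns),
    )
    pheno = None
    if (ind / "phenotypes.tsv").exists():
        pheno = pd.read_csv(ind / "phenotypes.tsv", sep="\t",
                            parse_dates=["draw_date"])
    return data, pheno


def write_manifest(outdir, **entries) -> None:
    def _clean(v):
        if isinstance(v, (np.integer,)):
            return int(v)
        if isinstance(v, (np.floating,)):
            return float(v)
        return v

    with open(Path(outdir) / "manifest.json", "w") as fh:
        json.dump({k: _clean(v) for k, v in entries.items()}, fh, indent=2)
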