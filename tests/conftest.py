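import numpy as np
import pandas as pd
import pytest

from cnpscan import simulate as sim


@pytest.fixture(scope="session")
def small_cohort():
    """200 subjects, one 20 kb deletion locus (q=0.3) on a 300 kb
    chromosome; no waves, no rare CNVs."""
    cfg = sim.SimConfig(
        n_subjects=200,
        chrom_lengths={"chr4": 300_000},
        marker_spacing=1700,
        cnp_loci=[sim.CNPSpec("chr4", 120_000, 140_000, 0.3)],
        lrr_sd=0.2,
        n_plates=8,
        seed=11,
    )
    mmap = sim.simulate_marker_map(cfg)
    data, pheno, geno, truth = sim.simulate_cohort(mmap, cfg)
    return cfg, mmap, data, pheno, geno, truth


def toy_map(pos, is_snp=None, gc=None, chrom="chr1"):
    """Hand-built marker map for unit tests."""
    pos = np.asarray(pos, dtype=int)
    n = pos.size
    return pd.DataFrame(
        {
            "marker_id": [f"m{i}" for i in range(n)],
            "chrom": chrom,
            "pos": pos,
            "is_snp": np.zeros(n, bool) if is_snp is None else np.asarray(is_snp, bool),
            "gc": np.full(n, 0.4) if gc is None else np.asarray(gc, float),
        }
    )


def toy_intensity(lrr, mmap, baf=None, subject_ids=None):
    lrr = np.atleast_2d(np.asarray(lrr, float))
    n = lrr.shape[0]
    if baf is None:
        baf = np.full_like(lrr, np.nan)
    if subject_ids is None:
        subject_ids = [f"S{i}" for i in range(n)]
    return sim.IntensityData(lrr=lrr, baf=np.atleast_2d(baf), map=mmap,
                             subject_ids=list(subject_ids))
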