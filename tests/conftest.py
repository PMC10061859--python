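import numpy as np
import pandas as pd
import pytest

import trivalent as tv


@pytest.fixture(scope="session")
def small_config():
    return tv.SyntheticConfig(
        n_promoters=60, n_chroms=1, chrom_length=900_000, seed=11,
        n_specific_per_tissue=3,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return tv.make_genome(small_config)


@pytest.fixture(scope="session")
def noiseless_genome():
    cfg = tv.SyntheticConfig(
        n_promoters=60, n_chroms=1, chrom_length=900_000, seed=4,
        noise={"dispersion": None, "mean_scale": 1.0},
        enhancer_amp_sd=0.0, n_specific_per_tissue=3,
    )
    return tv.make_genome(cfg)


@pytest.fixture(scope="session")
def noiseless_matrices(noiseless_genome):
    """Promoter signal matrices for the three methylation marks, both conditions."""
    out = {}
    for mark in ("H3K4me1", "H3K4me3", "H3K27me3"):
        for cond in ("WT", "KO"):
            track = tv.simulate_track(noiseless_genome, mark, cond)
            out[(mark, cond)] = tv.bin_signal(
                track, noiseless_genome.promoters, mark=mark, condition=cond
            )
    return out


def step_track(values, chrom="chr1"):
    """A CoverageTrack from an explicit per-bp array (test helper)."""
    from trivalent.io import CoverageTrack

    return CoverageTrack({chrom: np.asarray(values, dtype=np.float64)})


def brute_force_bin_means(arr, start, end, flank, n_flank, n_body):
    """bp-resolution oracle for bin_signal: per-bin fractional-overlap mean."""
    n = len(arr)
    window = np.zeros(end - start + 2 * flank)
    lo, hi = max(start - flank, 0), min(end + flank, n)
    if lo < hi:
        window[lo - (start - flank): hi - (start - flank)] = np.maximum(arr[lo:hi], 0)
    L = end - start
    edges = np.concatenate([
        np.linspace(0, flank, n_flank + 1)[:-1],
        flank + np.linspace(0, L, n_body + 1)[:-1],
        flank + L + np.linspace(0, flank, n_flank + 1),
    ])
    means = []
    for a, b in zip(edges[:-1], edges[1:]):
        total = 0.0
        for k in range(int(np.floor(a)), int(np.ceil(b))):
            ov = min(b, k + 1) - max(a, k)
            if ov > 0:
                total += ov * window[k]
        means.append(total / (b - a))
    return np.array(means)
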