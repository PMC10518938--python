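import numpy as np
import pytest

from dartf import GenomicInterval, PeakSet, SimConfig


def random_intervals(rng, n, chroms=("chr1", "chr2", "chr3"), span=100_000,
                     max_width=500, scored=False):
    """n random intervals across a few chromosomes."""
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        start = int(rng.integers(0, span))
        width = int(rng.integers(1, max_width + 1))
        score = int(rng.integers(0, 1001)) if scored else None
        out.append(GenomicInterval(chrom, start, start + width, score))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_config():
    """Small but fully planted study configuration for fast end-to-end tests."""
    return SimConfig(
        seed=7,
        n_chroms=2,
        chrom_length=2_000_000,
        n_dars_opened=80,
        n_dars_closed=80,
        n_background=60,
        n_tfs=6,
        experiments_per_tf=2,
        n_decoy_peaks=60,
        planted_tfs=("TF01", "TF02"),
        n_diseases=12,
        n_noise_assoc=10,
    )


def make_peakset(intervals, experiment_id="exp1", antigen="TF1",
                 cell_type_class="all", genome="toy1"):
    return PeakSet(
        experiment_id=experiment_id,
        antigen=antigen,
        cell_type_class=cell_type_class,
        genome=genome,
        intervals=tuple(intervals),
    )
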