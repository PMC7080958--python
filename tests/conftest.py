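import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from cnascape.genome_model import GenomeBuild, make_bins, toy_build
from cnascape.seg_io import Cohort


@pytest.fixture(scope="session")
def build():
    return toy_build()


@pytest.fixture(scope="session")
def grid(build):
    return make_bins(build, 1_000_000)


@pytest.fixture(scope="session")
def tiny_build():
    """Single 10-Mb chromosome without exclusion structure (telomere 0)."""
    return GenomeBuild(
        name="tiny",
        chrom_lengths={"1": 10_000_000},
        centromeres={"1": (4_800_000, 5_200_000)},
        telomere_size=0,
    )


def make_cohort(build, rows):
    """Cohort from (sample, chrom, start, end, log2) tuples."""
    df = pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "log2"])
    return Cohort.from_frame(df, build)


@pytest.fixture
def cohort_factory(build):
    def factory(rows, b=None):
        return make_cohort(b or build, rows)

    return factory


def random_segments(rng, chrom_len, n_max=6, sample="S", chrom="1"):
    """Random non-overlapping sorted segments with sizes spanning the
    10-kb filter boundary and deltas spanning the 0.4 threshold."""
    n = rng.integers(2, n_max + 1)
    cuts = np.sort(rng.choice(np.arange(1, chrom_len), size=n - 1, replace=False))
    bounds = np.r_[0, cuts, chrom_len]
    log2 = rng.choice([-0.8, -0.5, -0.25, 0.0, 0.25, 0.5, 0.8], size=n)
    return pd.DataFrame(
        {
            "sample": sample,
            "chrom": chrom,
            "start": bounds[:-1],
            "end": bounds[1:],
            "log2": log2,
        }
    )
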