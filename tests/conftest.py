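import numpy as np
import pandas as pd
import pytest

from cfentropy.io import ReadPattern
from cfentropy.methbin import MethBinRegion
from cfentropy.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared across read-only tests."""
    cfg = SimulationConfig(
        n_cancer_train=30, n_control_train=30,
        n_cancer_test=15, n_control_test=15,
        n_regions=30, n_informative_binary=6, n_informative_per_type=2,
        n_fragments_per_sample=800, seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def toy_regions():
    return [
        MethBinRegion("R1", "chr1", 100, 300, (110, 150, 200, 250)),
        MethBinRegion("R2", "chr1", 800, 1000, (810, 850, 900)),
        MethBinRegion("R3", "chr2", 0, 200, (10, 60, 110)),
    ]


def make_read(sample="S1", chrom="chr1", positions=(110, 150, 200), calls="MMU",
              start=None, end=None):
    positions = tuple(positions)
    if start is None:
        start = positions[0] - 5
    if end is None:
        end = positions[-1] + 5
    return ReadPattern(sample, chrom, start, end, positions, calls)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
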