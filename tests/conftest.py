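import numpy as np
import pytest
from hypothesis import settings

from g4hub.intervals import GenomicInterval, IntervalSet
from g4hub.simulate import default_config, generate_dataset

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

CHROM_LEN = 10_000  # toy chromosome for mask oracles


def interval_mask(ivset: IntervalSet, chrom: str = "chr1", length: int = CHROM_LEN):
    """Boolean per-bp occupancy mask: the brute-force ground truth."""
    mask = np.zeros(length, dtype=bool)
    for iv in ivset:
        if iv.chrom == chrom:
            mask[iv.start: iv.end] = True
    return mask


def random_interval_set(rng, n=20, chrom="chr1", length=CHROM_LEN, max_width=400, label=""):
    starts = rng.integers(0, length - max_width, size=n)
    widths = rng.integers(1, max_width, size=n)
    return IntervalSet(
        [GenomicInterval(chrom, int(s), int(s + w)) for s, w in zip(starts, widths)],
        label=label,
    )


@pytest.fixture(scope="session")
def toy_dataset():
    """Default-scale synthetic bundle shared across module tests."""
    return generate_dataset(default_config(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
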