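import numpy as np
import pytest

from exoborder import AlignedRead, GenomeAssembly
from exoborder.detection import BorderPeak


@pytest.fixture
def assembly() -> GenomeAssembly:
    return GenomeAssembly(("chr1", "chr2"), (10_000, 5_000))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240)


def make_read(chrom="chr1", start=100, end=150, strand="+", prefix=None, rep=0):
    return AlignedRead(chrom, start, end, strand, prefix, rep)


def make_peak(position, strand="+", signal=10.0, k=5.0, chrom="chr1"):
    return BorderPeak(chrom, position, strand, signal, k, min(1.0, 1.0 / k**2))
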