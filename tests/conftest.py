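import numpy as np
import pytest

from epihotspot.intervals import GenomicInterval, IntervalTrack


def random_track(
    rng: np.random.Generator,
    n: int,
    chroms=("chr1", "chr2"),
    genome_len: int = 10_000,
    max_len: int = 400,
    name: str = "",
) -> IntervalTrack:
    intervals = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, genome_len - max_len))
        length = int(rng.integers(1, max_len))
        intervals.append(GenomicInterval(chrom, start, start + length))
    return IntervalTrack(intervals, name=name)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
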