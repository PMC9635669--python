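import numpy as np
import pytest

from bergerac.genome import GenomeBuild, Interval


@pytest.fixture
def build():
    return GenomeBuild({"chrI": 100_000, "chrII": 50_000})


def random_intervals(rng, build, n, max_len=500):
    """Seeded random intervals across a build, for oracle comparisons."""
    out = []
    chroms = build.chromosomes
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        length = build.length(chrom)
        start = int(rng.integers(0, length - max_len))
        end = start + int(rng.integers(1, max_len))
        out.append(Interval(chrom, start, end))
    return out


def coverage_mask(intervals, build):
    """Per-base boolean occupancy masks, the brute-force coverage oracle."""
    masks = {c: np.zeros(build.length(c), dtype=bool) for c in build.chromosomes}
    for iv in intervals:
        masks[iv.chrom][iv.start:iv.end] = True
    return masks
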