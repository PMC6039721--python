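import numpy as np
import pytest

from chromdyn import FragmentSet, GenomeModel, GenomicInterval


@pytest.fixture
def small_genome():
    return GenomeModel((("chr1", 10_000), ("chr2", 8_000)))


@pytest.fixture
def flat_genome():
    """Single 50-kb chromosome for coordinate-arithmetic tests."""
    return GenomeModel((("chr1", 50_000),))


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=2000, max_len=100):
    """Small random interval sets for oracle-equivalence trials."""
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len + 1))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def random_fragments(rng, n, library_id="lib", chrom="chr1", max_pos=9000,
                     max_len=300):
    starts = rng.integers(0, max_pos, size=n)
    lens = rng.integers(1, max_len + 1, size=n)
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    return FragmentSet(library_id, np.full(n, chrom, dtype=object),
                       starts, starts + lens, strands)
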