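import numpy as np
import pytest
from hypothesis import settings

from bmpchip.core import GenomicInterval, IntervalCollection, Peak

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


def make_coll(spans, name="", chrom="chr1"):
    """Build a collection from (start, end) or (chrom, start, end) tuples."""
    ivs = []
    for span in spans:
        if len(span) == 2:
            ivs.append(GenomicInterval(chrom, *span))
        else:
            ivs.append(GenomicInterval(*span))
    return IntervalCollection(ivs, name=name)


def random_coll(rng, n, chroms=("chr1", "chr2"), span=100_000, max_len=500):
    ivs = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        ivs.append(GenomicInterval(chrom, start, start + length))
    return IntervalCollection(ivs)


def brute_force_overlapping(a, b):
    """All-pairs scan: records of a sharing >=1 base with any record of b."""
    out = []
    for ra in a.records:
        iva = ra.interval if isinstance(ra, Peak) else ra
        for rb in b.records:
            ivb = rb.interval if isinstance(rb, Peak) else rb
            if iva.overlaps(ivb):
                out.append(ra)
                break
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
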