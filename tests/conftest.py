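import numpy as np
import pytest
from hypothesis import settings

from cnsig.io import GenomeAssets, Segment, SegmentProfile

settings.register_profile("suite", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def assets() -> GenomeAssets:
    return GenomeAssets.grch37()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def make_profile(cn_by_chrom: dict[str, list[tuple[int, int, int]]], sample="S1") -> SegmentProfile:
    """Build a profile from {chrom: [(start, end, cn), ...]} without merging."""
    segs = [
        Segment(chrom, start, end, cn)
        for chrom, triples in cn_by_chrom.items()
        for start, end, cn in triples
    ]
    return SegmentProfile(sample, segs).normalized()


def chain_profile(chrom: str, cns: list[int], start=1_000_000, width=2_000_000, sample="S1"):
    """A profile with consecutive equal-width segments carrying the given CNs."""
    triples = [
        (start + i * width, start + (i + 1) * width - 1, cn) for i, cn in enumerate(cns)
    ]
    return make_profile({chrom: triples}, sample=sample)
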