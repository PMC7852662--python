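import numpy as np
import pytest

from mitodemog.alignment import Alignment


def make_aln(*seqs: str, ids=None) -> Alignment:
    if ids is None:
        ids = tuple(f"s{i}" for i in range(len(seqs)))
    return Alignment(ids=tuple(ids), seqs=tuple(seqs))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def star_alignment():
    """Central haplotype (x3) plus 5 singletons, each one private mutation."""
    center = "AAAAA"
    leaves = ["TAAAA", "ATAAA", "AATAA", "AAATA", "AAAAT"]
    return make_aln(center, center, center, *leaves)
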