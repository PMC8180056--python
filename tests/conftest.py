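import random

import numpy as np
import pytest

from csvar.preprocess import ReadRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_read(bases: str, quals=None, rid: str = "r1") -> ReadRecord:
    if quals is None:
        quals = [40] * len(bases)
    return ReadRecord(rid, bases, bytes(quals))


def random_seq(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
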