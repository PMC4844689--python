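"""Shared fixtures: small random instances used across the suite."""

import numpy as np
import pytest

from horizonte.io_formats import SequenceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_aligned_pair(rng, length=200, p_sub=0.05, p_gap=0.05,
                        p_n=0.02):
    """Two aligned sequences differing by random substitutions, with gaps
    and Ns sprinkled in (for pairwise-deletion behaviour)."""
    bases = "ACGT"
    a = rng.choice(list(bases), size=length)
    b = a.copy()
    for i in range(length):
        r = rng.random()
        if r < p_sub:
            b[i] = bases[(bases.index(b[i]) + rng.integers(1, 4)) % 4]
    def sprinkle(arr):
        out = arr.copy()
        for i in range(length):
            r = rng.random()
            if r < p_gap:
                out[i] = "-"
            elif r < p_gap + p_n:
                out[i] = "N"
        return out
    return (SequenceRecord("a", "".join(sprinkle(a))),
            SequenceRecord("b", "".join(sprinkle(b))))
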