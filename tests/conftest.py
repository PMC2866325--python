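import numpy as np
import pytest

import genegauge as gg


def make_alignment(seqs: dict[str, str]) -> gg.Alignment:
    ids = list(seqs)
    length = len(next(iter(seqs.values())))
    data = np.frombuffer(
        "".join(seqs[t] for t in ids).encode("ascii"), dtype="S1"
    ).reshape(len(ids), length).copy()
    return gg.Alignment(ids, data)


def random_alignment(rng, n: int, length: int, missing: float = 0.0
                     ) -> gg.Alignment:
    sym = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
    data = sym[rng.integers(4, size=(n, length))]
    if missing:
        data[rng.random(data.shape) < missing] = b"N"
    return gg.Alignment([f"t{i}" for i in range(n)], data)


@pytest.fixture
def balanced_quartet():
    return gg.tree_from_newick("((a,b),(c,d));")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20100507)
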