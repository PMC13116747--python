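import numpy as np
import pytest

from satellome.align import AlignmentParams


@pytest.fixture(scope="session")
def params():
    return AlignmentParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_dna(n, rng, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join("ACGT"[i] for i in rng.choice(4, size=n, p=p))


def mutate(seq, rate, rng):
    out = []
    for ch in seq:
        if rng.random() < rate:
            out.append("ACGT"[(("ACGT".index(ch)) + int(rng.integers(1, 4))) % 4])
        else:
            out.append(ch)
    return "".join(out)


@pytest.fixture(scope="session")
def e2e():
    """One full synthetic study shared by the acceptance tests: five planted
    families (40-2500 bp monomers, ~100-4900 copies, 1-8 chromosomes of a
    ~5 Mb genome), 10x short reads, 15x long reads >= 10 kb, fixed seed."""
    from satellome.pipeline import run_end_to_end

    return run_end_to_end(seed=1)
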