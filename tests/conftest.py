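import numpy as np
import pytest

from mesophylo.popdata import PopulationAssignment, SequenceAlignment


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_alignment():
    """5 sequences of 1000 sites with one singleton difference.

    The configuration implied by a sample of five with two haplotypes at
    counts {4, 1} and a single segregating site.
    """
    base = "A" * 1000
    variant = "C" + "A" * 999
    return SequenceAlignment.from_strings(
        [("s1", base), ("s2", base), ("s3", base), ("s4", base), ("s5", variant)]
    )


@pytest.fixture
def two_pop_assignment():
    pop_of = {f"s{i}": ("north" if i <= 3 else "south") for i in range(1, 6)}
    return PopulationAssignment(pop_of, {"north": "N", "south": "S"})


def random_alignment(rng, n, L, alphabet="ACGT"):
    letters = np.array(list(alphabet), dtype="U1")
    mat = letters[rng.integers(0, len(letters), size=(n, L))]
    return SequenceAlignment(tuple(f"r{i}" for i in range(n)), mat)
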