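import numpy as np
import pytest

from phyllopipe.redundancy import Contig
from phyllopipe.simulate import SimSpec


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_spec():
    """A compact but fully featured synthetic experiment."""
    return SimSpec(seed=11, n_base_transcripts=60, codonpair_params=(60, 60, 0.03, 0.2))


def random_contig(rng, cid: str, length: int) -> Contig:
    return Contig(cid, "".join(rng.choice(list("ACGT"), size=length)))


@pytest.fixture
def dummy_contigs():
    """Id-only contigs for count-level tests (sequences unused)."""

    def make(n: int) -> list[Contig]:
        return [Contig(f"c{i:05d}", "A") for i in range(n)]

    return make
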