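import numpy as np
import pytest

from foldadm import ProteinChain, SequenceRecord, fixtures


@pytest.fixture(scope="session")
def helix20() -> ProteinChain:
    return fixtures.ideal_helix(20)


@pytest.fixture(scope="session")
def toy_corpus() -> list[ProteinChain]:
    """Three small chains with mixed residue types for statistics oracles."""
    rng = np.random.default_rng(42)
    letters = "ACDEFGHIKLMNPQRSTVWY"
    chains = []
    for c, n in enumerate([24, 30, 18]):
        seq = "".join(rng.choice(list(letters), size=n))
        coords = fixtures.grow_self_avoiding(n, rng=rng)
        chains.append(ProteinChain(f"toy{c}", seq, coords))
    return chains


@pytest.fixture(scope="session")
def planted_pair() -> fixtures.PlantedPairStats:
    return fixtures.planted_pair_stats()


@pytest.fixture()
def query_seq() -> SequenceRecord:
    return SequenceRecord("q", "MKVLILAGLV")
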