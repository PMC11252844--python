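import numpy as np
import pytest

import eqppis as eq


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_chain():
    """One 30-residue synthetic chain, reused across read-only tests."""
    return eq.generate_chain(eq.SyntheticSpec(n_residues=30, seed=11))


@pytest.fixture(scope="session")
def small_graph(small_chain):
    return small_chain.graph


def random_graph(rng, n, hidden=None):
    """A random labelled ProteinGraph for property tests (not chain-like)."""
    coords = rng.uniform(-15, 15, size=(n, 3))
    spec_width = 62 if hidden is None else hidden
    return eq.ProteinGraph(
        coords=coords,
        features=rng.normal(size=(n, spec_width)),
        adjacency=eq.build_adjacency(coords, 14.0),
        labels=rng.integers(0, 2, size=n),
    )
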