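import numpy as np
import pytest

from rnm import (
    InteractionRecord,
    NodeRecord,
    RegulatoryNetwork,
    SimulationConfig,
    generate_paper_like_fixture,
    generate_toy_motifs,
    run_baseline_ensemble,
)


def make_net(edges, nodes=None, categories=None):
    """Build a small network from (source, target, effect) triples."""
    names = []
    seen = set()
    for u, v, _ in edges:
        for n in (u, v):
            if n not in seen:
                seen.add(n)
                names.append(n)
    for n in nodes or []:
        if n not in seen:
            seen.add(n)
            names.append(n)
    categories = categories or {}
    return RegulatoryNetwork(
        nodes=[NodeRecord(name=n, category=categories.get(n, "other")) for n in names],
        interactions=[
            InteractionRecord(source=u, target=v, effect=s) for u, v, s in edges
        ],
    )


@pytest.fixture(scope="session")
def cfg():
    return SimulationConfig()


@pytest.fixture(scope="session")
def motifs():
    return generate_toy_motifs()


@pytest.fixture(scope="session")
def fixture_net():
    return generate_paper_like_fixture(seed=0)


@pytest.fixture(scope="session")
def fixture_baseline(fixture_net):
    """A modest baseline ensemble on the disc fixture, shared across tests."""
    return run_baseline_ensemble(
        fixture_net, SimulationConfig(), n_runs=30, seed_base=0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
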