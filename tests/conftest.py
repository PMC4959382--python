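"""Shared fixtures: small hand-built networks and synthetic bundles."""

import numpy as np
import pytest

from clashnet import (
    AssociationMatrix,
    ClashConfig,
    DiseaseNetwork,
    ExternalEvidence,
    ReferenceStandard,
    SSLConfig,
    SyntheticSpec,
    generate,
)


def make_network(nodes, edges):
    """Network from an id-keyed edge dict {(a, b): w}."""
    nodes = tuple(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    W = np.zeros((len(nodes), len(nodes)))
    for (a, b), w in edges.items():
        W[idx[a], idx[b]] = W[idx[b], idx[a]] = w
    return DiseaseNetwork(nodes, W)


@pytest.fixture
def path_graph():
    """a - b - c chain with unit weights."""
    return make_network("abc", {("a", "b"): 1.0, ("b", "c"): 1.0})


@pytest.fixture
def star_graph():
    """Hub h with four leaves of equal weight."""
    return make_network(
        ("h", "l1", "l2", "l3", "l4"),
        {("h", leaf): 0.8 for leaf in ("l1", "l2", "l3", "l4")},
    )


@pytest.fixture
def walkthrough():
    """Eight-node scenario: five connected nodes, three disconnected.

    The disconnected query v6 has external-evidence support to candidates
    v1, v2, v3 with graded strengths; propagation ranks them v1 > v2 > v3,
    the gate accepts v1 and v2 and rejects v3 (its edge lowers the
    validation AUC on the untouched nodes). Validation nodes are v4, v5.
    """
    net = make_network(
        [f"v{i}" for i in range(1, 9)],
        {
            ("v4", "v3"): 0.65,
            ("v4", "v2"): 0.41,
            ("v4", "v5"): 0.17,
            ("v4", "v1"): 0.43,
            ("v3", "v2"): 0.81,
            ("v3", "v5"): 0.12,
            ("v2", "v5"): 0.17,
        },
    )
    evidence = ExternalEvidence(
        {("v6", "v1"): 2.69, ("v6", "v2"): 1.55, ("v6", "v3"): 1.35}
    )
    standard = ReferenceStandard(
        frozenset(
            {
                ("v3", "v4"),
                ("v4", "v5"),
                ("v1", "v4"),
                ("v2", "v3"),
                ("v3", "v5"),
                ("v3", "v6"),
                ("v2", "v5"),
                ("v1", "v6"),
            }
        )
    )
    return net, evidence, standard


@pytest.fixture(scope="session")
def synthetic_bundle():
    """Default synthetic dataset: 60 diseases, 3 blocks, 10% disconnected,
    faithful evidence covering every true edge."""
    spec = SyntheticSpec(seed=11)
    return generate(spec)


@pytest.fixture
def default_ssl_cfg():
    return SSLConfig()


@pytest.fixture
def permissive_cfg():
    return ClashConfig(epsilon=1.0)


def random_network(rng, n, p=0.4):
    """Random weighted graph on n nodes (possibly with isolated nodes)."""
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                W[i, j] = W[j, i] = rng.uniform(0.05, 1.0)
    return DiseaseNetwork(tuple(f"n{i}" for i in range(n)), W)
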