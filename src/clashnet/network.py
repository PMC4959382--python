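"""Weighted disease networks built from disease–feature association profiles.

A disease network is an undirected weighted graph ``G = (V, W)``: nodes are
diseases and the weight of an edge is the cosine similarity between the two
diseases' feature (e.g. protein-association) vectors. Diseases whose vectors
share no support with any other disease end up with zero degree — they are
the *disconnected* nodes that the complementation algorithm targets.

This module holds the two central containers (:class:`AssociationMatrix`,
:class:`DiseaseNetwork`) plus construction, density, degree-partition and
the random edge-deletion ("damage") operation used by the evaluation
protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "AssociationMatrix",
    "DiseaseNetwork",
    "build_network",
    "partition_nodes",
    "network_density",
    "damage_network",
]


def _check_unique(ids, what: str) -> tuple[str, ...]:
    ids = tuple(str(i) for i in ids)
    if len(set(ids)) != len(ids):
        raise InvalidInputError(f"duplicate {what} identifiers")
    return ids


@dataclass(frozen=True)
class AssociationMatrix:
    """Non-negative disease × feature association strengths.

    Parameters
    ----------
    diseases
        Ordered, unique disease identifiers (one per row).
    features
        Ordered, unique feature identifiers (one per column).
    values
        Array of shape ``(len(diseases), len(features))`` with entries >= 0.
        An all-zero row is a disease with no known feature associations.
    """

    diseases: tuple[str, ...]
    features: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "diseases", _check_unique(self.diseases, "disease"))
        object.__setattr__(self, "features", _check_unique(self.features, "feature"))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2 or values.shape != (len(self.diseases), len(self.features)):
            raise InvalidInputError(
                f"values shape {values.shape} does not match "
                f"{len(self.diseases)} diseases x {len(self.features)} features"
            )
        if len(self.diseases) < 2 or len(self.features) < 1:
            raise InvalidInputError("need at least 2 diseases and 1 feature")
        if not np.isfinite(values).all():
            raise InvalidInputError("association values must be finite")
        if (values < 0).any():
            raise InvalidInputError("association values must be non-negative")

    @property
    def n_diseases(self) -> int:
        return len(self.diseases)

    @property
    def n_features(self) -> int:
        return len(self.features)


@dataclass
class DiseaseNetwork:
    """Undirected weighted graph over diseases.

    ``weights`` is a symmetric matrix with zero diagonal and entries in
    [0, 1]. The node order is significant and preserved by every operation
    in this package.
    """

    nodes: tuple[str, ...]
    weights: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.nodes = _check_unique(self.nodes, "node")
        W = np.asarray(self.weights, dtype=float)
        n = len(self.nodes)
        if W.shape != (n, n):
            raise InvalidInputError(f"weight matrix shape {W.shape} != ({n}, {n})")
        if not np.isfinite(W).all():
            raise InvalidInputError("edge weights must be finite")
        if not np.allclose(W, W.T, atol=0):
            raise InvalidInputError("weight matrix must be symmetric")
        if np.diagonal(W).any():
            raise InvalidInputError("self-edges are not allowed (nonzero diagonal)")
        if (W < 0).any() or (W > 1).any():
            raise InvalidInputError("edge weights must lie in [0, 1]")
        self.weights = W
        self._index = {v: i for i, v in enumerate(self.nodes)}

    # -- basic queries -----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def index(self, node: str) -> int:
        try:
            return self._index[node]
        except KeyError:
            raise InvalidInputError(f"unknown node id: {node!r}") from None

    def degree(self, node: str) -> int:
        """Number of positive-weight edges incident to ``node``."""
        return int((self.weights[self.index(node)] > 0).sum())

    def has_edge(self, a: str, b: str) -> bool:
        return self.weights[self.index(a), self.index(b)] > 0

    def edge_weight(self, a: str, b: str) -> float:
        return float(self.weights[self.index(a), self.index(b)])

    def edges(self) -> list[tuple[str, str, float]]:
        """All positive edges as (a, b, weight), id-lexicographic a < b."""
        out = []
        for i, j in zip(*np.nonzero(np.triu(self.weights, k=1))):
            a, b = self.nodes[i], self.nodes[j]
            if b < a:
                a, b = b, a
            out.append((a, b, float(self.weights[i, j])))
        out.sort()
        return out

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {(a, b) for a, b, _ in self.edges()}

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, k=1)))

    def copy(self) -> "DiseaseNetwork":
        return DiseaseNetwork(self.nodes, self.weights.copy())

    # -- mutation (keeps symmetry) ----------------------------------------

    def add_edge(self, a: str, b: str, weight: float) -> None:
        i, j = self.index(a), self.index(b)
        if i == j:
            raise InvalidInputError("self-edges are not allowed")
        if not 0 < weight <= 1:
            raise InvalidInputError("edge weight must lie in (0, 1]")
        self.weights[i, j] = self.weights[j, i] = weight

    def remove_edge(self, a: str, b: str) -> None:
        i, j = self.index(a), self.index(b)
        self.weights[i, j] = self.weights[j, i] = 0.0

    def to_networkx(self):
        """Export as a ``networkx.Graph`` (isolated nodes included)."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(self.edges())
        return g


def build_network(assoc: AssociationMatrix, min_weight: float = 0.0) -> DiseaseNetwork:
    """Build the cosine-similarity disease network from association profiles.

    The weight of the edge (i, j) is the cosine similarity of rows i and j,
    kept only if strictly greater than ``min_weight``. All-zero rows have
    similarity 0 with every partner (such diseases become isolated nodes,
    not NaNs). No self-edges are produced.
    """
    if not isinstance(assoc, AssociationMatrix):
        raise InvalidInputError("assoc must be an AssociationMatrix")
    if not 0.0 <= min_weight <= 1.0:
        raise InvalidInputError("min_weight must lie in [0, 1]")
    X = assoc.values
    norms = np.linalg.norm(X, axis=1)
    safe = np.where(norms > 0, norms, 1.0)  # zero rows stay zero after division
    Xn = X / safe[:, None]
    S = np.clip(Xn @ Xn.T, 0.0, 1.0)
    np.fill_diagonal(S, 0.0)
    S[S <= min_weight] = 0.0
    return DiseaseNetwork(assoc.diseases, S)


def partition_nodes(net: DiseaseNetwork) -> tuple[set[str], set[str]]:
    """Split nodes into (connected, disconnected) by positive degree.

    A node is *disconnected* when every incident weight is zero; these are
    the complementation targets.
    """
    deg = (net.weights > 0).sum(axis=1)
    connected = {v for v, d in zip(net.nodes, deg) if d > 0}
    disconnected = set(net.nodes) - connected
    return connected, disconnected


def network_density(net: DiseaseNetwork) -> float:
    """Fraction of realizable node pairs joined by a positive-weight edge."""
    n = net.n_nodes
    if n < 2:
        raise InvalidInputError("density needs at least 2 nodes")
    return net.n_edges / (n * (n - 1) / 2)


def damage_network(
    net: DiseaseNetwork, fraction: float, seed: int
) -> tuple[DiseaseNetwork, set[tuple[str, str]]]:
    """Delete ``round(fraction * E)`` edges uniformly at random.

    Returns the damaged network (still symmetric, original node order) and
    the set of deleted id pairs (lexicographically ordered within pair).
    ``round`` is Python's half-to-even; the draw is reproducible from
    ``seed``. ``fraction=0`` returns an identical copy, ``fraction=1`` an
    edgeless network.
    """
    if not 0.0 <= fraction <= 1.0:
        raise InvalidInputError("fraction must lie in [0, 1]")
    edges = net.edges()
    k = round(fraction * len(edges))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(edges), size=k, replace=False) if k else []
    damaged = net.copy()
    deleted: set[tuple[str, str]] = set()
    for idx in chosen:
        a, b, _ = edges[int(idx)]
        damaged.remove_edge(a, b)
        deleted.add((a, b))
    return damaged, deleted
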