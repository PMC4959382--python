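"""Graph-based semi-supervised scoring (label propagation with Laplacian
regularization).

Given a weighted graph with weight matrix ``W`` and a label vector ``y``
(here: 1 on a single query disease, 0 elsewhere), the per-node score
vector ``f`` minimizes

    (f - y)' (f - y) + mu * f' L f,

where ``L`` is a graph Laplacian of ``W`` and ``mu > 0`` controls how far
labels are allowed to diffuse along edges. The unique minimizer solves the
symmetric positive-definite system ``(I + mu L) f = y``.

With the unnormalized Laplacian ``L = D - W`` the solution inherits two
properties used throughout the package and its tests: the scores stay in
``[min(y), max(y)]`` and their sum equals ``sum(y)`` (L annihilates the
constant vector). A node's score grows with the strength and number of its
connections to the labeled node, which is exactly the ranking signal the
complementation algorithm needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg

from .errors import InvalidInputError
from .network import DiseaseNetwork

__all__ = ["SSLConfig", "ssl_scores", "loo_scores", "loo_score_matrix", "laplacian"]

_LAPLACIANS = ("unnormalized", "symmetric-normalized")
_SOLVERS = ("direct", "iterative")


@dataclass(frozen=True)
class SSLConfig:
    """Configuration of the propagation solver.

    mu
        Regularization strength (> 0). Small mu keeps ``f`` close to the
        labels; large mu smooths scores toward the per-component mean.
    laplacian
        ``"unnormalized"`` (D - W, the default — preserves the range and
        sum-conservation invariants) or ``"symmetric-normalized"``.
    solver
        ``"direct"`` (dense Cholesky-backed solve) or ``"iterative"``
        (conjugate gradients on the SPD system).
    tol, max_iter
        Iterative-solver controls; ``max_iter=None`` means ``10 * n``.
    """

    mu: float = 1.0
    laplacian: str = "unnormalized"
    solver: str = "direct"
    tol: float = 1e-10
    max_iter: int | None = None

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise InvalidInputError("mu must be positive")
        if not self.tol > 0:
            raise InvalidInputError("tol must be positive")
        if self.laplacian not in _LAPLACIANS:
            raise InvalidInputError(f"laplacian must be one of {_LAPLACIANS}")
        if self.solver not in _SOLVERS:
            raise InvalidInputError(f"solver must be one of {_SOLVERS}")
        if self.max_iter is not None and self.max_iter < 1:
            raise InvalidInputError("max_iter must be a positive integer")


def laplacian(net: DiseaseNetwork, kind: str = "unnormalized") -> np.ndarray:
    """Graph Laplacian of the network's weight matrix.

    For the symmetric-normalized variant, isolated nodes get an all-zero
    row (their scores then stay pinned to their labels).
    """
    W = net.weights
    d = W.sum(axis=1)
    if kind == "unnormalized":
        return np.diag(d) - W
    if kind == "symmetric-normalized":
        inv_sqrt = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
        L = -(inv_sqrt[:, None] * W * inv_sqrt[None, :])
        L[np.diag_indices_from(L)] = (d > 0).astype(float)
        return L
    raise InvalidInputError(f"laplacian must be one of {_LAPLACIANS}")


def _system(net: DiseaseNetwork, cfg: SSLConfig) -> np.ndarray:
    A = laplacian(net, cfg.laplacian)
    A *= cfg.mu
    A[np.diag_indices_from(A)] += 1.0
    return A


def ssl_scores(net: DiseaseNetwork, labels, cfg: SSLConfig | None = None) -> np.ndarray:
    """Solve ``(I + mu L) f = y`` and return the score vector ``f``.

    ``labels`` is a length-n vector with entries in [0, 1], ordered like
    ``net.nodes``.
    """
    cfg = cfg or SSLConfig()
    y = np.asarray(labels, dtype=float)
    if y.shape != (net.n_nodes,):
        raise InvalidInputError(
            f"label vector length {y.shape} does not match {net.n_nodes} nodes"
        )
    if (y < 0).any() or (y > 1).any():
        raise InvalidInputError("labels must lie in [0, 1]")
    A = _system(net, cfg)
    if cfg.solver == "direct":
        return scipy.linalg.solve(A, y, assume_a="pos")
    max_iter = cfg.max_iter if cfg.max_iter is not None else 10 * net.n_nodes
    f, info = scipy.sparse.linalg.cg(
        scipy.sparse.csr_matrix(A), y, rtol=cfg.tol, maxiter=max_iter
    )
    if info != 0:
        # CG on an SPD system: non-convergence only under extreme max_iter
        raise InvalidInputError(f"conjugate-gradient solver did not converge (info={info})")
    return f


def loo_scores(net: DiseaseNetwork, target: str, cfg: SSLConfig | None = None) -> np.ndarray:
    """Scores with the held-out indicator label: y = 1 on ``target``, 0 else.

    The entries at every node except ``target`` are the leave-one-out
    ranking output for that disease.
    """
    y = np.zeros(net.n_nodes)
    y[net.index(target)] = 1.0
    return ssl_scores(net, y, cfg)


def loo_score_matrix(net: DiseaseNetwork, cfg: SSLConfig | None = None) -> np.ndarray:
    """All leave-one-out score vectors at once.

    Column ``j`` equals ``loo_scores(net, nodes[j])``; computed by a single
    Cholesky factorization of ``I + mu L`` (its inverse, column by column).
    Used by the evaluation layer, where every node in turn is the query.
    """
    cfg = cfg or SSLConfig()
    A = _system(net, cfg)
    c, low = scipy.linalg.cho_factor(A)
    return scipy.linalg.cho_solve((c, low), np.eye(net.n_nodes))
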