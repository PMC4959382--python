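"""Synthetic disease–feature data with known ground truth.

The generator emulates the shape of the real inputs — a binary disease ×
protein association table, a comorbidity-style external evidence table,
and a binary reference standard — in a block (disease-class) structure:
diseases in the same block share features, diseases in different blocks do
not, so the cosine-similarity network consists of within-block communities
and the "true" associations are known by construction.

A controllable fraction of diseases have their feature rows zeroed out
*after* the ground-truth network is built: these are diseases whose
molecular associations are unknown (the disconnected nodes the
complementation algorithm targets) but whose true class membership — and
hence their true edges, recorded in the truth network and the reference
standard — still exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ExternalEvidence
from .errors import InvalidInputError
from .evaluate import ReferenceStandard
from .network import AssociationMatrix, DiseaseNetwork, build_network

__all__ = ["SyntheticSpec", "generate"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    within_block_feature_overlap
        Probability that two same-block diseases share at least one
        feature (i.e. the within-block edge probability of the truth
        network). The per-feature Bernoulli rate is derived from it.
        The default 0.2 emulates sparsely characterized disease classes:
        each disease carries only a handful of the block's features, so
        the within-block graph is sparse with low-degree nodes, as in the
        poorly-annotated disease groups the method is aimed at.
    disconnect_fraction
        Fraction of diseases whose association rows are zeroed (unknown
        molecular profile); they keep their block membership in the truth
        network.
    evidence_fidelity
        Probability that an evidence pair is a true edge of the truth
        network rather than a uniformly random pair. 1.0 emulates a
        faithful external source, 0.0 the random-noise control.
    evidence_count
        Number of evidence pairs; ``None`` means one per truth edge (at
        fidelity 1 the evidence then equals the full truth edge set).
    """

    n_diseases: int = 60
    n_features: int = 300
    n_blocks: int = 3
    within_block_feature_overlap: float = 0.2
    disconnect_fraction: float = 0.1
    evidence_fidelity: float = 1.0
    evidence_count: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_diseases < 2 or self.n_features < 1 or self.n_blocks < 1:
            raise InvalidInputError("counts must be positive (and >= 2 diseases)")
        if self.n_blocks > self.n_diseases // 2:
            raise InvalidInputError("every block needs at least 2 diseases")
        if self.n_features < self.n_blocks:
            raise InvalidInputError("need at least one feature per block")
        for name in ("within_block_feature_overlap", "disconnect_fraction", "evidence_fidelity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidInputError(f"{name} must lie in [0, 1]")
        if self.evidence_count is not None and self.evidence_count < 0:
            raise InvalidInputError("evidence_count must be >= 0")


def _feature_rate(pair_overlap: float, n_block_features: int) -> float:
    """Per-feature presence rate p such that two independent Bernoulli(p)
    rows over m features share >= 1 feature with the given probability."""
    if pair_overlap >= 1.0:
        return 1.0
    return float(np.sqrt(1.0 - (1.0 - pair_overlap) ** (1.0 / n_block_features)))


def generate(
    spec: SyntheticSpec,
) -> tuple[AssociationMatrix, DiseaseNetwork, ExternalEvidence, ReferenceStandard]:
    """Generate (association matrix, truth network, evidence, standard).

    Deterministic given ``spec.seed``. The truth network is the cosine
    network of the *full* association matrix (before any rows are zeroed);
    the returned association matrix has the disconnect rows zeroed; the
    reference standard is exactly the positive pairs of the truth network.
    Every disease is guaranteed at least one within-block partner in the
    truth network (a shared feature is injected where sampling left a
    disease isolated), so with ``disconnect_fraction=0`` the built network
    has no disconnected nodes.
    """
    rng = np.random.default_rng(spec.seed)
    diseases = tuple(f"D{i:03d}" for i in range(spec.n_diseases))
    features = tuple(f"F{j:04d}" for j in range(spec.n_features))

    disease_blocks = np.array_split(np.arange(spec.n_diseases), spec.n_blocks)
    feature_blocks = np.array_split(np.arange(spec.n_features), spec.n_blocks)

    X = np.zeros((spec.n_diseases, spec.n_features))
    for d_idx, f_idx in zip(disease_blocks, feature_blocks):
        p = _feature_rate(spec.within_block_feature_overlap, len(f_idx))
        block = (rng.random((len(d_idx), len(f_idx))) < p).astype(float)
        X[np.ix_(d_idx, f_idx)] = block

    # repair: every disease must share >= 1 feature with some block-mate
    for d_idx, f_idx in zip(disease_blocks, feature_blocks):
        for i in d_idx:
            mates = [j for j in d_idx if j != i]
            if any((X[i, f_idx] * X[j, f_idx]).sum() > 0 for j in mates):
                continue
            j = int(rng.choice(mates))
            mate_feats = f_idx[X[j, f_idx] > 0]
            feat = int(rng.choice(mate_feats)) if mate_feats.size else int(rng.choice(f_idx))
            X[i, feat] = 1.0
            X[j, feat] = 1.0

    truth = build_network(AssociationMatrix(diseases, features, X), min_weight=0.0)
    standard = ReferenceStandard(frozenset(truth.edge_pairs()))

    # zero out the "unknown profile" diseases, spread uniformly at random
    n_disc = round(spec.disconnect_fraction * spec.n_diseases)
    disc_idx = rng.choice(spec.n_diseases, size=n_disc, replace=False) if n_disc else []
    X_obs = X.copy()
    for i in disc_idx:
        X_obs[int(i), :] = 0.0
    assoc = AssociationMatrix(diseases, features, X_obs)

    # external evidence: true edges with probability `evidence_fidelity`,
    # uniformly random pairs otherwise
    truth_edges = sorted(truth.edge_pairs())
    count = spec.evidence_count if spec.evidence_count is not None else len(truth_edges)
    n_true = min(round(spec.evidence_fidelity * count), len(truth_edges))
    chosen: set[tuple[str, str]] = set()
    if n_true:
        picks = rng.choice(len(truth_edges), size=n_true, replace=False)
        chosen.update(truth_edges[int(k)] for k in picks)
    max_pairs = spec.n_diseases * (spec.n_diseases - 1) // 2
    while len(chosen) < min(count, max_pairs):
        i, j = rng.integers(0, spec.n_diseases, size=2)
        if i != j:
            a, b = diseases[int(i)], diseases[int(j)]
            chosen.add((a, b) if a < b else (b, a))
    evidence = ExternalEvidence({pair: 1.0 for pair in chosen})

    return assoc, truth, evidence, standard
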