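"""The four-step complementation loop: anchoring, scoring, connecting,
stopping.

A disconnected disease (the *query*) is first **anchored**: every
connected node that co-occurs with it in the external evidence source
becomes a candidate, and provisional query–candidate edges are laid down.
**Scoring** labels the query 1 (all others 0) and propagates scores over
the anchored configuration; each candidate's score measures how coherent
a permanent link to the query would be with the existing network.
**Connecting** then walks the candidates in descending-score priority
groups (exact-tie candidates connect together) and keeps a group's edges
only if the network's leave-one-out AUC on the validation nodes — every
node other than the query and its candidates — does not drop by more than
``epsilon``. The loop **stops** when no disconnected nodes remain, the
evidence is exhausted, or connections are blocked because performance
would decrease.

The original network is never modified beyond the addition of accepted
edges: existing weights are preserved bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .errors import EvaluationUndefinedError, InvalidInputError
from .evaluate import ReferenceStandard, canonical_pair, validation_auc
from .network import DiseaseNetwork, partition_nodes
from .ssl import SSLConfig, ssl_scores

__all__ = [
    "ExternalEvidence",
    "CandidateSet",
    "ClashConfig",
    "ClashResult",
    "anchor",
    "score_candidates",
    "order_candidates",
    "try_connect",
    "run_clash",
]

# exact-tie grouping allowance: scores equal up to solver noise share priority
_TIE_TOL = 1e-9

_WEIGHT_POLICIES = ("evidence_normalized", "mean_existing", "fixed")
_ORDER_POLICIES = ("most_evidence_first", "input_order")


@dataclass(frozen=True)
class ExternalEvidence:
    """Unordered disease-pair -> positive strength map.

    The complementary source (e.g. comorbidity co-mentions). Presence-only
    sources carry strength 1.0 for every pair.
    """

    pairs: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        canon: dict[tuple[str, str], float] = {}
        for (a, b), s in self.pairs.items():
            s = float(s)
            if not s > 0:
                raise InvalidInputError(f"evidence strength must be > 0 for pair ({a}, {b})")
            canon[canonical_pair(a, b)] = s
        object.__setattr__(self, "pairs", canon)

    def __len__(self) -> int:
        return len(self.pairs)

    def partners(self, node: str) -> dict[str, float]:
        out = {}
        for (a, b), s in self.pairs.items():
            if a == node:
                out[b] = s
            elif b == node:
                out[a] = s
        return out

    def strength(self, a: str, b: str) -> float | None:
        return self.pairs.get(canonical_pair(a, b))

    @property
    def max_strength(self) -> float:
        return max(self.pairs.values()) if self.pairs else 0.0

    @property
    def presence_only(self) -> bool:
        """True when every strength is 1.0 (no graded co-mention counts)."""
        return all(s == 1.0 for s in self.pairs.values())


@dataclass
class CandidateSet:
    """A query's anchored candidates, optionally carrying f-scores."""

    query: str
    candidates: list[tuple[str, float | None]]

    @property
    def ids(self) -> list[str]:
        return [c for c, _ in self.candidates]


@dataclass(frozen=True)
class ClashConfig:
    """Knobs of the connecting gate and the loop.

    epsilon
        Maximum tolerated drop in validation AUC per accepted priority
        group (>= 0). Improvements are always accepted.
    new_edge_weight_policy
        Weight assigned to a complemented edge: ``evidence_normalized``
        (strength / max strength, falling back to ``mean_existing`` for
        presence-only sources), ``mean_existing`` (mean positive weight of
        the network at run start), or ``fixed`` (``fixed_weight``).
    node_order_policy
        Order in which disconnected nodes are processed:
        ``most_evidence_first`` (descending evidence count, seeded random
        tie-break) or ``input_order``.
    rescore_after_accept
        When True, remaining candidates are re-scored on the updated
        network after each accepted group instead of keeping the anchored-
        configuration scores for the whole query.
    """

    epsilon: float = 0.01
    new_edge_weight_policy: str = "evidence_normalized"
    fixed_weight: float = 0.5
    node_order_policy: str = "most_evidence_first"
    rescore_after_accept: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise InvalidInputError("epsilon must be >= 0")
        if not 0 < self.fixed_weight <= 1:
            raise InvalidInputError("fixed_weight must lie in (0, 1]")
        if self.new_edge_weight_policy not in _WEIGHT_POLICIES:
            raise InvalidInputError(f"new_edge_weight_policy must be one of {_WEIGHT_POLICIES}")
        if self.node_order_policy not in _ORDER_POLICIES:
            raise InvalidInputError(f"node_order_policy must be one of {_ORDER_POLICIES}")

    def with_seed(self, seed: int) -> "ClashConfig":
        return dataclasses.replace(self, seed=int(seed))


@dataclass
class ClashResult:
    """Complete, replayable log of one complementation run.

    Applying ``accepted`` (query, candidate, weight) edges to the input
    network reproduces ``network`` exactly.
    """

    network: DiseaseNetwork
    accepted: list[dict]  # query, candidate, weight, perf_before, perf_after
    rejected: list[dict]  # query, candidate, reason
    trace: list[dict]  # one entry per gate attempt (whole priority group)
    stop_reason: str  # no_disconnected_nodes | evidence_exhausted | performance_decreased
    config: dict
    seed: int

    def to_dict(self) -> dict:
        return {
            "accepted": self.accepted,
            "rejected": self.rejected,
            "trace": self.trace,
            "stop_reason": self.stop_reason,
            "config": self.config,
            "seed": self.seed,
            "edges": [[a, b, w] for a, b, w in self.network.edges()],
            "nodes": list(self.network.nodes),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def anchor(query: str, net: DiseaseNetwork, evidence: ExternalEvidence) -> CandidateSet:
    """Candidates for a disconnected query: connected nodes sharing an
    evidence pair with it. Scores are not yet populated."""
    if net.degree(query) != 0:
        raise InvalidInputError(f"query {query!r} is not disconnected")
    connected, _ = partition_nodes(net)
    partners = evidence.partners(query)
    cands = sorted(v for v in partners if v in connected)
    return CandidateSet(query=query, candidates=[(v, None) for v in cands])


def _edge_weight(
    query: str,
    candidate: str,
    evidence: ExternalEvidence | None,
    cfg: ClashConfig,
    mean_existing: float,
) -> float:
    policy = cfg.new_edge_weight_policy
    if policy == "evidence_normalized" and evidence is not None and not evidence.presence_only:
        s = evidence.strength(query, candidate)
        if s is None:
            policy = "mean_existing"
        else:
            return float(min(1.0, max(s / evidence.max_strength, np.finfo(float).tiny)))
    if policy in ("evidence_normalized", "mean_existing"):
        return mean_existing
    return cfg.fixed_weight


def _mean_positive_weight(net: DiseaseNetwork, cfg: ClashConfig) -> float:
    w = net.weights[np.triu_indices(net.n_nodes, k=1)]
    w = w[w > 0]
    return float(w.mean()) if w.size else cfg.fixed_weight


def score_candidates(
    cand: CandidateSet,
    net: DiseaseNetwork,
    evidence: ExternalEvidence,
    ssl_cfg: SSLConfig | None = None,
    clash_cfg: ClashConfig | None = None,
) -> CandidateSet:
    """Score candidates over the anchored configuration.

    The query is provisionally attached to *all* of its candidates, labeled
    1 against 0 elsewhere, and scores are propagated; each candidate's
    score is read off and the provisional edges are removed again.
    """
    if not cand.candidates:
        raise InvalidInputError("candidate set is empty")
    ssl_cfg = ssl_cfg or SSLConfig()
    clash_cfg = clash_cfg or ClashConfig()
    mean_w = _mean_positive_weight(net, clash_cfg)
    added = []
    for c in cand.ids:
        w = _edge_weight(cand.query, c, evidence, clash_cfg, mean_w)
        net.add_edge(cand.query, c, w)
        added.append(c)
    try:
        y = np.zeros(net.n_nodes)
        y[net.index(cand.query)] = 1.0
        f = ssl_scores(net, y, ssl_cfg)
        scored = [(c, float(f[net.index(c)])) for c in cand.ids]
    finally:
        for c in added:
            net.remove_edge(cand.query, c)
    return CandidateSet(query=cand.query, candidates=scored)


def order_candidates(cand: CandidateSet) -> list[set[str]]:
    """Priority groups by strictly descending f-score.

    Candidates whose scores coincide (within solver noise) share a group
    and will be connected with the same priority.
    """
    if any(s is None for _, s in cand.candidates):
        raise InvalidInputError("candidates must be scored before ordering")
    ordered = sorted(cand.candidates, key=lambda cs: (-cs[1], cs[0]))
    groups: list[set[str]] = []
    last_score: float | None = None
    for c, s in ordered:
        if last_score is not None and abs(s - last_score) <= _TIE_TOL:
            groups[-1].add(c)
        else:
            groups.append({c})
            last_score = s
    return groups


def try_connect(
    query: str,
    group: set[str],
    net: DiseaseNetwork,
    standard: ReferenceStandard,
    cfg: ClashConfig | None = None,
    ssl_cfg: SSLConfig | None = None,
    *,
    evidence: ExternalEvidence | None = None,
    exclude=None,
    weights: dict[str, float] | None = None,
    perf_before: float | None = None,
) -> tuple[bool, float, float]:
    """Gate one priority group: add its edges iff validation AUC survives.

    Validation nodes are all nodes except the query and ``exclude`` (the
    query's full candidate set; defaults to ``group``). The group's edges
    are added provisionally, the leave-one-out AUC on the validation nodes
    is recomputed, and the edges are kept iff
    ``perf_before - perf_after <= cfg.epsilon``; otherwise they are removed
    again. On acceptance the network is mutated in place.

    Returns ``(accepted, perf_before, perf_after)``.
    """
    cfg = cfg or ClashConfig()
    ssl_cfg = ssl_cfg or SSLConfig()
    exclude = set(exclude) if exclude is not None else set(group)
    validation = [v for v in net.nodes if v != query and v not in exclude]

    evaluable = 0
    for t in validation:
        labels = {standard.label(t, v) for v in net.nodes if v != t}
        if labels == {0, 1}:
            evaluable += 1
    if evaluable < 2:
        raise EvaluationUndefinedError(
            "need at least 2 validation nodes with both a positive and a negative pair"
        )

    if perf_before is None:
        perf_before = validation_auc(net, standard, validation, ssl_cfg)
    mean_w = _mean_positive_weight(net, cfg)
    added: list[tuple[str, float]] = []
    for c in sorted(group):
        w = weights[c] if weights is not None else _edge_weight(query, c, evidence, cfg, mean_w)
        net.add_edge(query, c, w)
        added.append((c, w))
    perf_after = validation_auc(net, standard, validation, ssl_cfg)
    accept = (perf_before - perf_after) <= cfg.epsilon
    if not accept:
        for c, _ in added:
            net.remove_edge(query, c)
    return accept, float(perf_before), float(perf_after)


def _node_order(
    disconnected: set[str], evidence: ExternalEvidence, net: DiseaseNetwork, cfg: ClashConfig
) -> list[str]:
    if cfg.node_order_policy == "input_order":
        return [v for v in net.nodes if v in disconnected]
    rng = np.random.default_rng(cfg.seed)
    nodes = sorted(disconnected)
    rng.shuffle(nodes)  # seeded tie-break among equal evidence counts
    return sorted(nodes, key=lambda v: -len(evidence.partners(v)))


def run_clash(
    net: DiseaseNetwork,
    evidence: ExternalEvidence,
    standard: ReferenceStandard,
    cfg: ClashConfig | None = None,
    ssl_cfg: SSLConfig | None = None,
) -> ClashResult:
    """Run the full anchoring/scoring/connecting/stopping loop.

    The input network is not modified; the result carries the complemented
    copy together with a complete accept/reject log and per-attempt
    performance trace.
    """
    cfg = cfg or ClashConfig()
    ssl_cfg = ssl_cfg or SSLConfig()
    work = net.copy()
    accepted: list[dict] = []
    rejected: list[dict] = []
    trace: list[dict] = []
    _, disconnected = partition_nodes(work)
    gate_blocked: set[str] = set()

    for query in _node_order(disconnected, evidence, work, cfg):
        cand = anchor(query, work, evidence)
        if not cand.candidates:
            continue
        cand = score_candidates(cand, work, evidence, ssl_cfg, cfg)
        mean_w = _mean_positive_weight(work, cfg)
        weights = {
            c: _edge_weight(query, c, evidence, cfg, mean_w) for c in cand.ids
        }
        groups = order_candidates(cand)
        exclude = set(cand.ids)
        perf: float | None = None
        gi = 0
        while gi < len(groups):
            group = groups[gi]
            accept, before, after = try_connect(
                query,
                group,
                work,
                standard,
                cfg,
                ssl_cfg,
                evidence=evidence,
                exclude=exclude,
                weights=weights,
                perf_before=perf,
            )
            trace.append(
                {
                    "query": query,
                    "group_index": gi,
                    "group": sorted(group),
                    "perf_before": before,
                    "perf_after": after,
                    "accepted": accept,
                }
            )
            if accept:
                for c in sorted(group):
                    accepted.append(
                        {
                            "query": query,
                            "candidate": c,
                            "weight": weights[c],
                            "perf_before": before,
                            "perf_after": after,
                        }
                    )
                perf = after
                if cfg.rescore_after_accept and gi + 1 < len(groups):
                    remaining = [c for g in groups[gi + 1 :] for c in g]
                    re = score_candidates(
                        CandidateSet(query, [(c, None) for c in remaining]),
                        work,
                        evidence,
                        ssl_cfg,
                        cfg,
                    )
                    # query now has real edges, so re-anchoring only spans
                    # the not-yet-attempted candidates
                    groups = groups[: gi + 1] + order_candidates(re)
                gi += 1
            else:
                for c in sorted(group):
                    rejected.append(
                        {"query": query, "candidate": c, "reason": "performance_drop"}
                    )
                for g in groups[gi + 1 :]:
                    for c in sorted(g):
                        rejected.append(
                            {
                                "query": query,
                                "candidate": c,
                                "reason": "not_attempted_lower_priority",
                            }
                        )
                gate_blocked.add(query)
                break

    _, still_disconnected = partition_nodes(work)
    if not still_disconnected:
        stop_reason = "no_disconnected_nodes"
    elif still_disconnected & gate_blocked:
        stop_reason = "performance_decreased"
    else:
        stop_reason = "evidence_exhausted"

    return ClashResult(
        network=work,
        accepted=accepted,
        rejected=rejected,
        trace=trace,
        stop_reason=stop_reason,
        config=dataclasses.asdict(cfg) | {"ssl": dataclasses.asdict(ssl_cfg)},
        seed=cfg.seed,
    )
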