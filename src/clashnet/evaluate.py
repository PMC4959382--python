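"""Evaluation layer: leave-one-out ROC-AUC against a binary reference
standard, disease ranking, and the damage/recovery experiment protocol.

The reference standard is a set of disease pairs with literature support
(label 1); every other pair is implicitly 0. Network quality is measured by
leave-one-out validation: each target disease in turn is labeled 1, scores
are propagated to all other diseases, and the ROC-AUC of those scores
against the target's standard labels is computed. The reported AUC is the
macro average over targets (a pair-pooled micro average is emitted
alongside, since the aggregation convention is not uniquely determined by
the protocol).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import EvaluationUndefinedError, InvalidInputError
from .network import (
    AssociationMatrix,
    DiseaseNetwork,
    build_network,
    damage_network,
    network_density,
    partition_nodes,
)
from .ssl import SSLConfig, loo_score_matrix

__all__ = [
    "ReferenceStandard",
    "EvaluationReport",
    "roc_auc",
    "loo_auc",
    "validation_auc",
    "rank_associated_diseases",
    "run_damage_experiment",
]


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Unordered pair as an id-lexicographic tuple."""
    if a == b:
        raise InvalidInputError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class ReferenceStandard:
    """Binary gold standard: the set of positively-labeled disease pairs."""

    positives: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "positives",
            frozenset(canonical_pair(a, b) for a, b in self.positives),
        )

    def label(self, a: str, b: str) -> int:
        return 1 if canonical_pair(a, b) in self.positives else 0

    def __len__(self) -> int:
        return len(self.positives)


@dataclass
class EvaluationReport:
    """Leave-one-out evaluation summary for one network."""

    auc: float  # macro average over evaluable targets
    auc_micro: float  # pooled over all (target, partner) pairs
    per_target_auc: dict[str, float]
    n_targets: int  # evaluable targets
    n_skipped: int  # targets with single-class labels
    density: float


def roc_auc(scores, labels) -> float:
    """ROC-AUC via the rank (Mann–Whitney) formulation, ties counted 1/2.

    Equals the probability that a uniformly random positive outscores a
    uniformly random negative, with ties contributing one half.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise InvalidInputError("scores and labels must be 1-d and equal length")
    if not np.isin(y, (0, 1)).all():
        raise InvalidInputError("labels must be 0/1")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationUndefinedError("AUC needs at least one positive and one negative")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def loo_auc(
    net: DiseaseNetwork,
    standard: ReferenceStandard,
    targets=None,
    ssl_cfg: SSLConfig | None = None,
) -> EvaluationReport:
    """Leave-one-out AUC of a network against the reference standard.

    For each target, all other nodes are scored with the target's indicator
    label held out, and scored against the 0/1 standard labels of the pairs
    (target, other). Targets whose labels are single-class are skipped and
    counted, not imputed.
    """
    ssl_cfg = ssl_cfg or SSLConfig()
    if targets is None:
        targets = net.nodes
    targets = list(targets)
    for t in targets:
        net.index(t)  # validates membership
    F = loo_score_matrix(net, ssl_cfg)
    per_target: dict[str, float] = {}
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    n_skipped = 0
    for t in targets:
        j = net.index(t)
        mask = np.ones(net.n_nodes, dtype=bool)
        mask[j] = False
        scores = F[mask, j]
        labels = np.array([standard.label(t, v) for v in net.nodes if v != t])
        if labels.min() == labels.max():
            n_skipped += 1
            continue
        per_target[t] = roc_auc(scores, labels)
        pooled_scores.append(scores)
        pooled_labels.append(labels)
    if not per_target:
        raise EvaluationUndefinedError("every target had single-class labels")
    return EvaluationReport(
        auc=float(np.mean(list(per_target.values()))),
        auc_micro=roc_auc(np.concatenate(pooled_scores), np.concatenate(pooled_labels)),
        per_target_auc=per_target,
        n_targets=len(per_target),
        n_skipped=n_skipped,
        density=network_density(net),
    )


def validation_auc(
    net: DiseaseNetwork,
    standard: ReferenceStandard,
    validation_nodes,
    ssl_cfg: SSLConfig | None = None,
) -> float:
    """Macro leave-one-out AUC restricted to the given validation targets.

    This is the quantity the connecting gate monitors while deciding
    whether a provisional edge preserves the network's behaviour.
    """
    return loo_auc(net, standard, targets=validation_nodes, ssl_cfg=ssl_cfg).auc


def rank_associated_diseases(
    net: DiseaseNetwork,
    target: str,
    k: int = 10,
    ssl_cfg: SSLConfig | None = None,
) -> list[tuple[str, float]]:
    """Top-k diseases associated with ``target`` by leave-one-out score.

    Descending score; ties (scores equal up to solver precision, 1e-9)
    broken id-lexicographically. ``k`` larger than n-1 returns all
    non-target nodes.
    """
    if k < 1:
        raise InvalidInputError("k must be >= 1")
    from .ssl import loo_scores

    f = loo_scores(net, target, ssl_cfg)
    scored = [(v, float(f[i])) for i, v in enumerate(net.nodes) if v != target]
    # group numerically-tied scores so symmetric nodes sort by id
    scored.sort(key=lambda vs: -vs[1])
    rank_key: dict[str, int] = {}
    last = None
    for v, s in scored:
        if last is not None and abs(s - last) <= 1e-9:
            rank_key[v] = rank_key[prev_v]
        else:
            rank_key[v] = len(rank_key)
            last = s
        prev_v = v
    scored.sort(key=lambda vs: (rank_key[vs[0]], vs[0]))
    return scored[:k]


def _random_pairs(nodes, count: int, rng: np.random.Generator) -> set[tuple[str, str]]:
    """``count`` distinct random unordered pairs over ``nodes``."""
    nodes = list(nodes)
    n = len(nodes)
    all_pairs = n * (n - 1) // 2
    count = min(count, all_pairs)
    chosen: set[tuple[str, str]] = set()
    while len(chosen) < count:
        i, j = rng.integers(0, n, size=2)
        if i != j:
            chosen.add(canonical_pair(nodes[int(i)], nodes[int(j)]))
    return chosen


def run_damage_experiment(
    assoc: AssociationMatrix,
    evidence,
    standard: ReferenceStandard,
    fractions,
    repeats: int = 10,
    *,
    clash_cfg=None,
    ssl_cfg: SSLConfig | None = None,
    noise_clash_cfg=None,
    min_weight: float = 0.0,
    base_seed: int = 0,
    noise_arm: bool = True,
) -> pd.DataFrame:
    """Damage/recovery protocol: damage the network, complement, measure.

    For every ``fraction`` × ``repeat`` (seeded reproducibly from
    ``base_seed``): build the reference network from ``assoc``, delete the
    given fraction of its edges at random, run the complementation
    algorithm with the supplied external evidence, and record density and
    leave-one-out AUC for the reference, damaged and complemented networks.
    When ``noise_arm`` is set, a fourth arm repeats the complementation
    with the evidence replaced by uniformly random disease pairs (the
    robustness control). The amount of injected noise matches the number
    of edges the main arm actually accepted for that damaged network, so
    the noisy and complemented networks receive comparable numbers of new
    edges; the noise arm runs under ``noise_clash_cfg`` (default: same
    configuration as the main arm).

    Returns a tidy table with one row per (fraction, repeat, arm):
    fraction, repeat, seed, arm, density, auc, auc_micro, accepted_edges,
    deleted_edges, query_incident_deleted, recovered_edges,
    recovered_fraction.
    """
    from .core import ClashConfig, run_clash  # local import: core depends on this module

    ssl_cfg = ssl_cfg or SSLConfig()
    clash_cfg = clash_cfg or ClashConfig()
    noise_clash_cfg = noise_clash_cfg or clash_cfg
    fractions = list(fractions)
    if any(not 0.0 <= f <= 1.0 for f in fractions):
        raise InvalidInputError("fractions must lie in [0, 1]")
    if repeats < 1:
        raise InvalidInputError("repeats must be >= 1")

    reference = build_network(assoc, min_weight)
    ref_report = loo_auc(reference, standard, ssl_cfg=ssl_cfg)
    rows = []

    def _row(fraction, repeat, seed, arm, report, **extra):
        rows.append(
            {
                "fraction": fraction,
                "repeat": repeat,
                "seed": seed,
                "arm": arm,
                "density": report.density,
                "auc": report.auc,
                "auc_micro": report.auc_micro,
                "accepted_edges": extra.get("accepted_edges", 0),
                "deleted_edges": extra.get("deleted_edges", 0),
                "query_incident_deleted": extra.get("query_incident_deleted", 0),
                "recovered_edges": extra.get("recovered_edges", 0),
                "recovered_fraction": extra.get("recovered_fraction", float("nan")),
            }
        )

    for fi, fraction in enumerate(fractions):
        for repeat in range(repeats):
            seed = int(
                np.random.SeedSequence([base_seed, fi, repeat]).generate_state(1)[0]
                % (2**31)
            )
            damaged, deleted = damage_network(reference, fraction, seed)
            _, disconnected = partition_nodes(damaged)
            query_incident = {
                pair for pair in deleted if pair[0] in disconnected or pair[1] in disconnected
            }
            dam_report = loo_auc(damaged, standard, ssl_cfg=ssl_cfg)
            _row(fraction, repeat, seed, "reference", ref_report)
            _row(
                fraction,
                repeat,
                seed,
                "damaged",
                dam_report,
                deleted_edges=len(deleted),
                query_incident_deleted=len(query_incident),
            )

            result = run_clash(
                damaged,
                evidence,
                standard,
                cfg=clash_cfg.with_seed(seed),
                ssl_cfg=ssl_cfg,
            )
            comp_pairs = result.network.edge_pairs()
            recovered = deleted & comp_pairs
            rec_frac = (
                len(recovered & query_incident) / len(query_incident)
                if query_incident
                else float("nan")
            )
            comp_report = loo_auc(result.network, standard, ssl_cfg=ssl_cfg)
            _row(
                fraction,
                repeat,
                seed,
                "complemented",
                comp_report,
                accepted_edges=len(result.accepted),
                deleted_edges=len(deleted),
                query_incident_deleted=len(query_incident),
                recovered_edges=len(recovered),
                recovered_fraction=rec_frac,
            )

            if noise_arm:
                from .core import ExternalEvidence

                rng = np.random.default_rng(seed + 1)
                noisy_pairs = _random_pairs(damaged.nodes, len(result.accepted), rng)
                noisy_evidence = ExternalEvidence({p: 1.0 for p in noisy_pairs})
                noisy_result = run_clash(
                    damaged,
                    noisy_evidence,
                    standard,
                    cfg=noise_clash_cfg.with_seed(seed),
                    ssl_cfg=ssl_cfg,
                )
                noisy_report = loo_auc(noisy_result.network, standard, ssl_cfg=ssl_cfg)
                _row(
                    fraction,
                    repeat,
                    seed,
                    "noisy",
                    noisy_report,
                    accepted_edges=len(noisy_result.accepted),
                    deleted_edges=len(deleted),
                )
    return pd.DataFrame(rows)
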