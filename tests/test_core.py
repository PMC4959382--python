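"""The anchoring / scoring / connecting / stopping loop."""

import json

import numpy as np
import pytest

from clashnet import (
    CandidateSet,
    ClashConfig,
    EvaluationUndefinedError,
    ExternalEvidence,
    InvalidInputError,
    ReferenceStandard,
    SSLConfig,
    anchor,
    damage_network,
    order_candidates,
    partition_nodes,
    run_clash,
    score_candidates,
    try_connect,
)
from .conftest import make_network


class TestEvidence:
    def test_pairs_canonicalized_and_queried_both_ways(self):
        ev = ExternalEvidence({("b", "a"): 2.0, ("a", "c"): 1.0})
        assert ev.strength("a", "b") == 2.0 == ev.strength("b", "a")
        assert ev.partners("a") == {"b": 2.0, "c": 1.0}
        assert ev.max_strength == 2.0 and not ev.presence_only

    def test_invalid_pairs_rejected(self):
        with pytest.raises(InvalidInputError):
            ExternalEvidence({("a", "a"): 1.0})
        with pytest.raises(InvalidInputError):
            ExternalEvidence({("a", "b"): 0.0})


class TestAnchor:
    def test_connected_evidence_partners_become_candidates(self, walkthrough):
        net, evidence, _ = walkthrough
        cand = anchor("v6", net, evidence)
        assert cand.query == "v6"
        assert cand.ids == ["v1", "v2", "v3"]

    def test_disconnected_partners_are_not_candidates(self, walkthrough):
        net, _, _ = walkthrough
        ev = ExternalEvidence({("v6", "v7"): 1.0, ("v6", "v8"): 1.0})
        assert anchor("v6", net, ev).candidates == []

    def test_no_evidence_means_no_candidates(self, walkthrough):
        net, _, _ = walkthrough
        assert anchor("v6", net, ExternalEvidence({("v1", "v2"): 1.0})).candidates == []

    def test_connected_query_rejected(self, walkthrough):
        net, evidence, _ = walkthrough
        with pytest.raises(InvalidInputError):
            anchor("v1", net, evidence)


class TestScoring:
    def test_walkthrough_scores_rank_by_query_connectivity(self, walkthrough):
        # v1 carries the strongest external link to the query, v3 the weakest
        net, evidence, _ = walkthrough
        cand = score_candidates(anchor("v6", net, evidence), net, evidence)
        scores = dict(cand.candidates)
        assert scores["v1"] > scores["v2"] > scores["v3"]

    def test_provisional_edges_are_removed(self, walkthrough):
        net, evidence, _ = walkthrough
        before = net.weights.copy()
        score_candidates(anchor("v6", net, evidence), net, evidence)
        np.testing.assert_array_equal(net.weights, before)

    def test_automorphic_candidates_score_equally(self):
        # square a-b-c-d-a: b and d are exchangeable by the symmetry fixing q
        net = make_network(
            "abcdq",
            {("a", "b"): 0.6, ("b", "c"): 0.4, ("c", "d"): 0.4, ("a", "d"): 0.6},
        )
        ev = ExternalEvidence({("q", "b"): 1.0, ("q", "d"): 1.0})
        cand = score_candidates(anchor("q", net, ev), net, ev)
        scores = dict(cand.candidates)
        assert abs(scores["b"] - scores["d"]) <= 1e-10

    def test_empty_candidate_set_rejected(self, walkthrough):
        net, evidence, _ = walkthrough
        with pytest.raises(InvalidInputError):
            score_candidates(CandidateSet("v6", []), net, evidence)


class TestOrdering:
    def test_distinct_scores_give_singleton_groups(self):
        cand = CandidateSet("q", [("v1", 0.9), ("v2", 0.8), ("v3", 0.6)])
        assert order_candidates(cand) == [{"v1"}, {"v2"}, {"v3"}]

    def test_all_equal_scores_share_one_group(self):
        cand = CandidateSet("q", [("a", 0.5), ("b", 0.5), ("c", 0.5)])
        assert order_candidates(cand) == [{"a", "b", "c"}]

    def test_partial_ties_group_together(self):
        cand = CandidateSet("q", [("a", 0.7), ("b", 0.7), ("c", 0.2)])
        assert order_candidates(cand) == [{"a", "b"}, {"c"}]

    def test_matches_sort_and_group_oracle(self):
        rng = np.random.default_rng(8)
        vals = rng.choice([0.1, 0.4, 0.4, 0.7, 0.9], size=6)
        cand = CandidateSet("q", [(f"c{i}", float(v)) for i, v in enumerate(vals)])
        # brute-force oracle: sort descending, split on strict inequality
        order = sorted(range(6), key=lambda i: -vals[i])
        oracle = []
        for i in order:
            if oracle and vals[i] == vals[oracle[-1][-1]]:
                oracle[-1].append(i)
            else:
                oracle.append([i])
        expected = [{f"c{i}" for i in g} for g in oracle]
        assert order_candidates(cand) == expected

    def test_unscored_candidates_rejected(self):
        with pytest.raises(InvalidInputError):
            order_candidates(CandidateSet("q", [("a", None)]))


class TestGate:
    def test_permissive_epsilon_accepts_everything(self, walkthrough):
        net, evidence, standard = walkthrough
        work = net.copy()
        accept, before, after = try_connect(
            "v6", {"v3"}, work, standard, ClashConfig(epsilon=1.0), evidence=evidence,
            exclude={"v1", "v2", "v3"},
        )
        assert accept and work.has_edge("v6", "v3")

    def test_zero_epsilon_rejects_harmful_edge_and_restores_network(self, walkthrough):
        net, evidence, standard = walkthrough
        work = net.copy()
        work.add_edge("v6", "v1", 1.0)
        work.add_edge("v6", "v2", 1.55 / 2.69)
        before_w = work.weights.copy()
        accept, before, after = try_connect(
            "v6", {"v3"}, work, standard, ClashConfig(epsilon=0.0), evidence=evidence,
            exclude={"v1", "v2", "v3"},
        )
        assert not accept and after < before
        np.testing.assert_array_equal(work.weights, before_w)

    def test_too_small_validation_set_is_undefined(self):
        net = make_network("abq", {("a", "b"): 0.5})
        std = ReferenceStandard(frozenset({("a", "b")}))
        with pytest.raises(EvaluationUndefinedError):
            try_connect("q", {"a"}, net, std, ClashConfig())


class TestRunClash:
    def test_walkthrough_accepts_top_two_and_drops_third(self, walkthrough):
        net, evidence, standard = walkthrough
        result = run_clash(net, evidence, standard, ClashConfig(epsilon=0.0))
        assert [r["candidate"] for r in result.accepted] == ["v1", "v2"]
        assert [r["candidate"] for r in result.rejected
                if r["reason"] == "performance_drop"] == ["v3"]
        assert result.network.has_edge("v6", "v1")
        assert result.network.has_edge("v6", "v2")
        assert not result.network.has_edge("v6", "v3")
        # v7, v8 had no evidence at all
        assert result.stop_reason == "evidence_exhausted"

    def test_all_disconnected_nodes_connected_with_full_evidence(self, walkthrough):
        net, _, standard = walkthrough
        ev = ExternalEvidence(
            {("v6", "v1"): 2.0, ("v6", "v2"): 1.0,
             ("v7", "v4"): 1.5, ("v7", "v2"): 1.0,
             ("v8", "v5"): 1.5, ("v8", "v1"): 1.0}
        )
        result = run_clash(net, ev, standard, ClashConfig(epsilon=1.0))
        assert partition_nodes(result.network)[1] == set()
        assert result.stop_reason == "no_disconnected_nodes"

    def test_no_disconnected_nodes_is_a_noop(self, walkthrough):
        net, evidence, standard = walkthrough
        sub = make_network(
            net.nodes[:5],
            {(a, b): net.edge_weight(a, b)
             for a, b, _ in net.edges()},
        )
        result = run_clash(sub, evidence, standard, ClashConfig())
        np.testing.assert_array_equal(result.network.weights, sub.weights)
        assert result.stop_reason == "no_disconnected_nodes"
        assert result.accepted == [] and result.trace == []

    def test_empty_evidence_exhausts(self, walkthrough):
        net, _, standard = walkthrough
        result = run_clash(net, ExternalEvidence({}), standard, ClashConfig())
        np.testing.assert_array_equal(result.network.weights, net.weights)
        assert result.stop_reason == "evidence_exhausted"

    def test_original_edges_preserved_bit_for_bit(self, walkthrough):
        net, evidence, standard = walkthrough
        original = net.weights.copy()
        result = run_clash(net, evidence, standard, ClashConfig(epsilon=1.0))
        mask = original > 0
        np.testing.assert_array_equal(result.network.weights[mask], original[mask])
        np.testing.assert_array_equal(net.weights, original)  # input untouched

    def test_identical_seeds_give_identical_results(self, synthetic_bundle):
        from clashnet import build_network

        assoc, truth, evidence, standard = synthetic_bundle
        net = build_network(assoc)
        cfg = ClashConfig(epsilon=0.02, seed=123)
        r1 = run_clash(net, evidence, standard, cfg)
        r2 = run_clash(net, evidence, standard, cfg)
        assert r1.to_json() == r2.to_json()

    def test_result_is_replayable(self, walkthrough):
        net, evidence, standard = walkthrough
        result = run_clash(net, evidence, standard, ClashConfig(epsilon=0.0))
        replay = net.copy()
        for rec in result.accepted:
            replay.add_edge(rec["query"], rec["candidate"], rec["weight"])
        np.testing.assert_array_equal(replay.weights, result.network.weights)

    def test_safety_bound_on_trace(self, synthetic_bundle):
        from clashnet import build_network

        assoc, truth, evidence, standard = synthetic_bundle
        net = build_network(assoc)
        cfg = ClashConfig(epsilon=0.01)
        result = run_clash(net, evidence, standard, cfg)
        accepted_steps = [t for t in result.trace if t["accepted"]]
        total_drop = sum(
            max(0.0, t["perf_before"] - t["perf_after"]) for t in accepted_steps
        )
        assert all(
            t["perf_before"] - t["perf_after"] <= cfg.epsilon for t in accepted_steps
        )
        assert total_drop <= cfg.epsilon * len(accepted_steps) + 1e-12

    def test_deleted_edges_of_disconnected_nodes_are_reattempted(self, synthetic_bundle):
        # evidence = exactly the deleted pairs; every deleted edge touching a
        # node that became disconnected must be anchored (attempted)
        from clashnet import build_network

        assoc, truth, evidence, standard = synthetic_bundle
        net = build_network(assoc)
        damaged, deleted = damage_network(net, 0.6, seed=4)
        ev = ExternalEvidence({pair: 1.0 for pair in deleted})
        result = run_clash(damaged, ev, standard, ClashConfig(epsilon=1.0))
        attempted = {
            (min(r["query"], r["candidate"]), max(r["query"], r["candidate"]))
            for r in result.accepted + result.rejected
        }
        _, disconnected = partition_nodes(damaged)
        final_connected, _ = partition_nodes(result.network)
        for a, b in deleted:
            if a in disconnected and b not in disconnected:
                assert (a, b) in attempted
            # pairs between two disconnected nodes are attempted once the
            # partner has been linked into the connected component
            elif a in disconnected and b in disconnected:
                if (a, b) not in attempted:
                    assert a not in final_connected or b not in final_connected
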