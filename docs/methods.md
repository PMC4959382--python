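# Methods

## Model

A disease network is an undirected weighted graph *G = (V, W)* over
disease identifiers. The network is built from a non-negative disease ×
feature association matrix *X*: *W<sub>ij</sub>* is the cosine similarity
of rows *i* and *j*, retained when strictly greater than a configurable
`min_weight` (default 0, i.e. every positive similarity becomes an edge;
real association matrices may warrant pruning near-zero weights). Rows
that are entirely zero — diseases with no known feature associations —
receive similarity 0 with every partner rather than NaN; these are
precisely the disconnected nodes the complementation loop targets. No
self-edges are created.

### Propagation scoring

Given labels *y* ∈ [0,1]ⁿ, the score vector is the minimizer of
(f−y)ᵀ(f−y) + μ fᵀLf, i.e. the solution of the SPD system
(I + μL) f = y. This is the standard Laplacian-regularized
semi-supervised formulation; we use it because it reproduces every
qualitative property the procedure relies on: a node's score grows with
the strength and number of its paths to the labeled node, and with the
unnormalized Laplacian *L = D − W* the solution satisfies

* **range containment**: min(y) ≤ f ≤ max(y), because (I+μL) is an
  M-matrix whose inverse is entrywise non-negative with unit row sums;
* **sum conservation**: Σf = Σy, because L annihilates constants;
* the μ→0 limit returns the labels and the μ→∞ limit (connected graph)
  the label mean.

Parameters: μ > 0 (default 1.0 — scores then mix label fidelity and
smoothness on an equal footing; there is no principled external value for
it, so it is exposed in `SSLConfig`); Laplacian `unnormalized` (default)
or `symmetric-normalized` (isolated nodes get zero rows so their scores
stay pinned to their labels; the range/conservation invariants hold only
for the unnormalized variant); solver `direct` (Cholesky-backed dense
solve) or `iterative` (conjugate gradients, tol 1e−10, max 10·n
iterations). Leave-one-out scoring for all targets at once is a single
factorization of (I + μL) applied to the identity.

### The complementation loop

Anchoring, scoring, connecting and stopping are implemented exactly as
described in the README. Design points that were genuinely open:

* **Gate direction.** The gate is one-sided: a group is accepted iff
  `perf_before − perf_after ≤ ε`. Improvements are always accepted; only
  drops are penalized (the procedure stops when performance *decreases*).
  Default ε = 0.01: one hundredth of an AUC point per accepted group is
  small against the metric's sampling noise on realistic validation sets,
  while ε = 0 would reject edges for sub-noise fluctuations.
* **Gate metric.** The gate monitors the same quantity the experiments
  report — macro-averaged leave-one-out AUC restricted to the validation
  nodes (all nodes except the query and its candidates) — rather than a
  cheaper proxy, so gate decisions and reported performance cannot
  diverge. Within one query the candidate set is fixed, hence so is the
  validation set; with ε = 0 the accepted chain of a query is therefore
  monotone in validation AUC by construction.
* **New-edge weights.** A complemented disease has no feature vector, so
  its edge weight cannot be a cosine. Default policy
  `evidence_normalized`: strength divided by the maximum strength in the
  evidence table, clipped to (0,1]. Presence-only evidence (all strengths
  equal) carries no gradation, so the weight falls back to the mean
  positive edge weight of the network at run start (`mean_existing`),
  keeping new edges on the scale of the existing cosine weights. A
  `fixed` policy is available.
* **Processing order.** Disconnected nodes are processed most-evidence
  first (descending evidence-pair count, seeded random tie-break):
  information-rich queries connect early and then count as connected
  anchors for later queries. `input_order` is available for
  reproducibility studies.
* **Rescoring.** By default candidate scores are computed once per query
  in the anchored configuration and used for the whole priority walk; a
  `rescore_after_accept` flag re-scores the remaining candidates on the
  updated network after each accepted group. The anchored-once reading is
  the default because the priority order is defined by the anchored
  picture; no claim is made that either variant is uniquely faithful.
* **Ties.** Candidates whose scores agree within 1e−9 (solver noise on
  symmetric configurations) share one priority group and are connected —
  and gated — together. The same tolerance breaks ranking ties
  id-lexicographically in `rank_associated_diseases`.
* **Stop reason.** `no_disconnected_nodes` if every node ends connected;
  otherwise `performance_decreased` if some remaining disconnected node
  was blocked by the gate, else `evidence_exhausted`.

### Evaluation

ROC-AUC uses the rank (Mann–Whitney) formulation with ties counted ½.
Leave-one-out evaluation scores every target against all other nodes with
the target's indicator label held out and compares the scores with the
0/1 reference-standard labels of the target's pairs. Targets whose labels
are single-class are skipped and counted, not imputed at 0.5 (imputation
would drag every network toward chance). The reported AUC is the macro
average over evaluable targets; a pair-pooled micro average is emitted
alongside because the aggregation convention for "one AUC over all
targets" is not uniquely determined — the two are reported side by side
in the experiment table.

Network density is the fraction of realizable node pairs with positive
weight. Damage removes round(fraction · E) edges uniformly at random
(half-to-even rounding; E counts positive upper-triangle entries), seeded
and reproducible.

### The damage/recovery/noise experiment

For every damage fraction × repeat (seeds derived deterministically from
a base seed): build the reference network, delete the edge fraction, run
the loop with the supplied evidence, and record density, AUC, accepted
and recovered edges for the reference, damaged and complemented networks.
The **noise control** replaces the evidence with uniformly random disease
pairs, with the amount of injected noise matched to the number of edges
the main arm accepted for that damaged network, so both arms add
comparable numbers of edges; the control runs under the algorithm's
default gate (ε = 0.01) — robustness to noise is a property of the
procedure *including* its gate, so the control must not disable it.
Recovery is reported as the fraction of deleted edges incident to a
disconnected node that reappear in the complemented network (only such
edges are recoverable, since the loop adds edges to disconnected nodes
only).

## Synthetic data

The generator emulates the shape of the real inputs: a binary disease ×
feature matrix with block (disease-class) structure, an external evidence
pair table, and a reference standard. Diseases and features are split
into `n_blocks` contiguous blocks; a disease carries each feature of its
block with rate *p* chosen so that two same-block diseases share at least
one feature with probability `within_block_feature_overlap` (default 0.2
— each disease then carries only a handful of block features, giving the
sparse, low-degree within-block graphs typical of poorly characterized
disease classes). Between-block cosine similarity is exactly zero. A
repair pass guarantees every disease at least one shared feature with a
block-mate, so `disconnect_fraction = 0` yields no accidentally isolated
nodes. The truth network is built from the full matrix; then
`disconnect_fraction` of rows (default 10 %) are zeroed in the returned
association matrix — these diseases keep their true edges in the truth
network and reference standard but are disconnected in the observed
network. Evidence consists of `evidence_count` pairs (default: one per
truth edge), each a truth edge with probability `evidence_fidelity`
(default 1.0) and a uniformly random pair otherwise; strengths are 1.0
(presence-only). Everything is deterministic given the seed.

What the generator does **not** emulate: the heavy-tailed degree
distributions, weighted association counts, inter-class similarity and
the scale of real disease–protein data (hundreds of diseases by tens of
thousands of proteins), or evidence whose
noise is correlated with the network (random-pair noise is the easiest
noise to reject). Passing tests therefore demonstrate the mechanics and
safety properties of the procedure, not its performance on real data.

## Problem sizes and numerical choices

The default study conditions — 60 diseases, 3 blocks, 300 features, 10 %
disconnected, damage fractions 20–80 %, 10 repeats — keep a full
protocol run (160 network evaluations plus ~80 complementation runs) in
the tens of seconds while leaving every measured effect far from its
decision boundary. Direct solves are used throughout at these sizes; the
conjugate-gradient solver is cross-checked against dense inversion to
1e−8. Floating-point allowances: 1e−12 on range containment and gate
comparisons, 1e−9 for score ties.

## Known limitations

* The gate bounds the *per-step validation* drop; it does not bound the
  global AUC change across queries with different validation sets (the
  experiments measure that empirically).
* With presence-only evidence all candidates of a query receive equal
  provisional anchor weights, so candidate ranking is driven by dilution
  through the existing graph rather than by evidence strength.
* Acceptance granularity is the priority group: tied candidates are
  accepted or rejected together.
* One external source per run; no multi-source fusion, no edge deletion
  or reweighting of the original network, and no learning of μ or ε.
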