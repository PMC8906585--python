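# Methods

## Model and assumptions

The reasoning operates on a directed multigraph of chemicals, proteins and
diseases whose edges assert signed causal influence: +1 activation, −1
inhibition.  Only three edge strata are admitted — chemical→protein,
protein→protein, protein→disease — so every directed walk from a chemical
passes exclusively through proteins before reaching a disease.  Self-edges
are rejected at load (they can only create cycles, which the method excludes
anyway), and parallel contradictory edges between the same ordered node pair
are retained as two distinct edges: aggregated knowledge graphs routinely
carry conflicting assertions from different sources, and each signed variant
is a distinct mechanistic hypothesis that path enumeration should keep
separate.

A candidate mechanism is a node-simple path from drug to disease of 2 to
`lmax` edges.  Sign propagation is multiplicative: the path predicts protein
*i* to move in the direction of the product of the first *i* edge signs, and
its cumulative effect on the disease is the product of all signs.  The
implicit biological assumptions are that causal influences compose
multiplicatively along a chain, that a perturbation's transcriptional
footprint reflects the inferred regulation at each step, and that chains
longer than `lmax` are too diluted to matter.  Both are simplifications:
causal edges can act post-transcriptionally (a phosphorylation does not move
mRNA), and binarized fold changes discard magnitude.  The per-check error
budget exists precisely to absorb these mismatches.

A path survives for a drug–disease pair when (i) its cumulative effect on
the disease is inhibitory, (ii) the drug signature matches the predicted
regulations within the error budget, and (iii) the disease signature matches
their negation within its own budget.  An error is a protein whose call is
absent, measured-but-unchanged, or contradictory.  A pair is prioritized iff
at least one path survives; the union of surviving paths, with per-edge
traversal counts, is the proposed mechanism of action.

The target-prioritization variant reverses the traversal: from a disease,
all bounded protein→…→disease paths are enumerated (one shared reverse
depth-first pass rather than one forward pass per protein), and each
starting protein is scored by the number of paths concordant — equal, not
negated — with the disease signature: such a protein is a candidate upstream
regulator that could produce the observed expression state.  The starting
protein itself carries no inferred regulation (it is the perturbation, not a
prediction).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `lmax` | 7 edges | maximum path length considered |
| `max_errors` | 1 per check | tolerated failures within concordance, and independently within anti-correlation |
| `require_disease_inhibition` | on | discard paths whose cumulative effect on the disease is +1 |
| `treat_zero_as_error` | on | a measured 0 provides no supporting direction and counts like a missing value |
| `fc_cutoff` | 1.0 | \|log2 fold change\| threshold for binarization; ties at the cutoff are called dysregulated |
| p-value filter | off | binarization uses the fold-change rule only; a threshold can be supplied |

Design choices where the design was genuinely open:

- **Error budget per check, not shared.**  Concordance and anti-correlation
  are two separate evaluations of the same path; each gets its own budget.
  A shared, stricter reading can be emulated by setting `max_errors=0`.
- **Measured 0 counts as an error by default** because it provides no
  supporting direction; the flag exists because the opposite reading (a 0 is
  merely uninformative, not contradictory) is defensible.
- **Cumulative disease inhibition required by default**: a therapeutic
  mechanism should revert the disease.  Exposed as a flag because the two
  signature checks alone are also a coherent (weaker) criterion.
- **Drug-mode ranking key** is the surviving-path count, with ties broken by
  the surviving fraction of all paths and then pair id — mirroring the
  concordant-path-count ranking used in target mode.
- **Minimum path length is 2 edges** in both modes; direct drug→disease
  edges do not exist in the data model, and a single protein→disease edge is
  not accepted as an upstream-regulator mechanism.

Note a structural consequence of the error budget: a 2-edge path carries
exactly one protein, so with `max_errors ≥ 1` it passes both signature
checks *unconditionally*.  At the default budget, any pair connected by an
inhibitory chemical→protein→disease path is prioritized regardless of the
signatures.  This is faithful to the method; analyses that want the
signatures to bear on short paths should use `max_errors=0`.

## Synthetic benchmark generator

The generator emulates the statistical shape of the real inputs — sparse
typed KG, binarized signatures with noise and missingness, positive-label
list — with exact recorded ground truth.  Defaults (chosen once as a
realistic desk-scale study): 10 chemicals, 60 proteins, 5 diseases; stratum
densities 0.05 (chemical→protein), 0.03 (protein→protein), 0.05
(protein→disease), giving mean out-degrees of ~3 targets per chemical and
~1.8 protein successors per protein; half of edges inhibitory; 5 planted
pairs with one guaranteed mechanism path of 4 edges each, cumulative effect
forced to −1; clean signatures.  Planted on-path proteins receive their
inferred regulation in the drug signature and its negation in the disease
signature; planted values are then degraded by flip/zero noise and
missingness; off-path proteins draw i.i.d. background calls from
{−1, 0, +1} with probabilities (0.15, 0.70, 0.15), loosely emulating the
dysregulation call rate of a unit fold-change cutoff.  Planted paths use
disjoint protein sets so pairs sharing a chemical or disease never receive
contradictory planted values.  Planted edges are inserted after background
sampling and deduplicated against it, which guarantees mechanism existence
without materially distorting degrees at low planting counts.

What the generator does *not* emulate: realistic degree distributions
(hubs), correlated expression between related genes, batch structure, or
fold-change magnitudes (only binarized calls are produced).  Passing tests
on this benchmark therefore demonstrate algorithmic correctness — recovery
of mechanisms that satisfy the model's own assumptions — not performance on
real knowledge graphs, where edge quality and signature coverage dominate.

## Permutation nulls

The null model destroys the graph–signature coupling while preserving
marginals.  KG edges are rewired by XSwap moves within each edge-type
stratum: a move exchanges the targets of two edges (a→b, c→d) → (a→d, c→b),
signs traveling with the source stubs, rejected if it would create a
self-edge or duplicate an existing (source, target, sign) triple.  Every
node's in/out degree and each stratum's edge count are preserved exactly;
the attempt budget is `swap_multiplier × |edges|` per stratum (default 10).
Rejected attempts are simply skipped — the standard rejection scheme keeps
the sampler degree-exact and simple.  Signatures are permuted by shuffling
the value multiset over the measured genes (unmeasured genes stay
unmeasured).  An optional sign-shuffle mode permutes edge signs with the
wiring fixed, for separating wiring effects from sign effects.  Empirical
p-values use the add-one estimator (1 + #{null ≥ observed}) / (1 + n), which
cannot return 0 at small replicate counts.

## Numerical and procedural choices

- Path enumeration is bounded depth-first search with the length cap applied
  during descent and children visited in sorted (node id, sign) order, so
  output order is lexicographic and runs are deterministic; no unbounded
  path set is materialized.
- All randomness (generator, XSwap, signature shuffles) flows through
  numpy's seeded PCG64 generators; permutation replicates derive child seeds
  from a `SeedSequence`, so experiments are reproducible end to end.
- Precision of an empty prioritized set is reported as undefined (`None`),
  never 0: an empty shortlist is "no evidence", not "all wrong".
- The chance baseline divides positives by *connected* candidate pairs only
  — pairs with no path cannot be prioritized by any path-based method and
  would deflate the baseline spuriously.
- The TSV knowledge-graph dialect is an edge list and cannot carry isolated
  nodes; the GraphML dialect round-trips them.
- Degenerate permutation strata (fewer than two edges) are left untouched
  and logged.

## Problem sizes in tests and the acceptance script

The test suite validates path enumeration against an exhaustive
interior-permutation oracle on 200 random graphs of ≤ 10 nodes, concordance
scoring against a brute-force truth table over all sign × state assignments
for 1–3 proteins, and the pipeline properties (planted recovery, budget and
length-bound nesting over 50 seeded benchmarks, XSwap contract over 20
seeds, permutation ablation with 20 replicates and 20 null repetitions) at
the default benchmark scale.  The acceptance script reruns the pipeline at
that same scale.  These sizes were chosen as the smallest at which every
property is non-trivially exercised.

## Known limitations

- Transcript-level signatures are an imperfect proxy for protein activity;
  concordance errors absorb, but do not model, post-transcriptional
  regulation.
- The single-error default makes short paths uninformative (see above) and
  more than one error makes prioritization nearly unconditional for typical
  path lengths; the budget is a blunt instrument.
- Identifier harmonization (gene/compound/disease namespaces) is assumed
  done upstream; the package matches opaque strings.
- The two proximity scores are generic stand-ins that exercise the
  benchmark harness; they are not reimplementations of any published
  benchmark suite.
- Cyclic mechanisms (feedback loops) are outside the model: only node-simple
  paths are considered.
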