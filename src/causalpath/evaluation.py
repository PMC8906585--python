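"""Validation harness: precision against positive labels, the chance
baseline, simple network-proximity baselines, and permutation nulls.

Evaluation follows the early-retrieval setting: only the small set of
prioritized pairs matters, so the metric is precision (fraction of
prioritized pairs that are positive labels) against the chance baseline (the
fraction of positives among all candidate pairs connected by at least one
bounded path).  Ranked-list metrics such as ROC are deliberately not
implemented — they assess a full ranking, which is not what a prioritization
shortlist produces.

The permutation null destroys the coupling between graph structure and
signatures while preserving their marginal structure: KG edges are rewired
with degree-preserving XSwap moves inside each edge-type stratum, and each
signature's value multiset is shuffled over its measured genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional

import networkx as nx
import numpy as np

from .kg import CausalKG, KGError, NodeKind
from .reasoning import ReasoningConfig, prioritize_pairs
from .signatures import Signature

logger = logging.getLogger(__name__)

__all__ = [
    "LabelSet",
    "PermutationSpec",
    "PermutationReport",
    "precision",
    "expected_precision_by_chance",
    "proximity_baselines",
    "xswap_permute_kg",
    "shuffle_edge_signs",
    "permute_signature",
    "permutation_experiment",
    "load_labels",
]

Pair = tuple[str, str]


@dataclass
class LabelSet:
    """Positive (drug, disease) pairs, e.g. clinically investigated ones."""

    positives: set[Pair]
    provenance: str = ""

    def __post_init__(self):
        self.positives = {(str(a), str(b)) for a, b in self.positives}


def load_labels(path, provenance: str = "") -> LabelSet:
    """Read a two-column ``drug_id  disease_id`` TSV of positive pairs."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"drug_id", "disease_id"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns drug_id, disease_id")
    return LabelSet(
        {(r.drug_id, r.disease_id) for r in df.itertuples(index=False)},
        provenance or str(path),
    )


def precision(prioritized: Iterable[Pair], labels: LabelSet) -> Optional[float]:
    """|prioritized ∩ positives| / |prioritized|; None when nothing was
    prioritized (precision is undefined, not zero)."""
    pairs = set(prioritized)
    if not pairs:
        return None
    return len(pairs & labels.positives) / len(pairs)


def expected_precision_by_chance(candidates: Iterable[Pair], labels: LabelSet) -> float:
    """Probability that a uniformly random candidate pair (one connected by at
    least one bounded path) is a positive label."""
    pairs = set(candidates)
    if not pairs:
        raise ValueError("candidate pair set is empty")
    return len(pairs & labels.positives) / len(pairs)


@dataclass(frozen=True)
class ProximityScores:
    """Generic network-proximity scores for one drug-disease pair.

    These are plumbing stand-ins exercising the benchmark harness with the
    two canonical proximity notions (shortest directed path, shared
    interactors); they are not a reimplementation of any published benchmark
    suite.
    """

    shortest_path_length: float  # math.inf when disconnected
    n_shared_interactors: int


def proximity_baselines(kg: CausalKG, drug: str, disease: str) -> ProximityScores:
    """Shortest directed path length (signs ignored) and the count of
    proteins targeted by the drug that also have an edge to the disease."""
    for nid in (drug, disease):
        if nid not in kg:
            raise KGError(f"node {nid!r} not in KG")
    try:
        spl = float(nx.shortest_path_length(kg.graph, drug, disease))
    except nx.NetworkXNoPath:
        spl = math.inf
    drug_targets = {v for v, _ in kg.out_edges(drug)}
    shared = {
        p
        for p in drug_targets
        if kg.kind(p) == NodeKind.PROTEIN
        and any(v == disease for v, _ in kg.out_edges(p))
    }
    return ProximityScores(spl, len(shared))


# ---------------------------------------------------------------------------
# Permutation nulls


@dataclass
class PermutationSpec:
    """Parameters of a permutation-null experiment."""

    n_permutations: int = 20
    swap_multiplier: int = 10
    seed: int = 0
    permute_kg: bool = True
    permute_signatures: bool = True

    def __post_init__(self):
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.swap_multiplier < 1:
            raise ValueError("swap_multiplier must be >= 1")
        if not (self.permute_kg or self.permute_signatures):
            raise ValueError("at least one of permute_kg/permute_signatures required")


def xswap_permute_kg(kg: CausalKG, spec: PermutationSpec) -> CausalKG:
    """Degree-preserving rewiring of the KG (XSwap moves).

    Attempts ``swap_multiplier x |edges|`` swaps per (source-kind,
    target-kind) stratum, so the edge-type constraints can never be violated.
    A swap exchanges the targets of two edges (a→b, c→d) → (a→d, c→b); each
    edge's sign travels with its source stub.  Swaps creating a self-edge or
    duplicating an existing (source, target, sign) triple are rejected, so
    every node's in- and out-degree and each stratum's edge count are
    preserved exactly.  Strata with fewer than two edges are left untouched.
    Reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    out = CausalKG()
    for n in kg.nodes():
        out.add_node(n, kg.kind(n))
    strata: dict[tuple, list[tuple[str, str, int]]] = {}
    for e in sorted(kg.edges(), key=lambda e: (e.source, e.target, e.sign)):
        key = (kg.kind(e.source).value, kg.kind(e.target).value)
        strata.setdefault(key, []).append((e.source, e.target, e.sign))
    for key in sorted(strata):
        edges = strata[key]
        if len(edges) < 2:
            logger.info("stratum %s has <2 edges; left untouched", key)
        else:
            present = set(edges)
            n_attempts = spec.swap_multiplier * len(edges)
            idx = rng.integers(0, len(edges), size=(n_attempts, 2))
            for i, j in idx:
                if i == j:
                    continue
                a, b, s1 = edges[i]
                c, d, s2 = edges[j]
                e1 = (a, d, s1)
                e2 = (c, b, s2)
                if a == d or c == b:
                    continue
                if e1 in present or e2 in present:
                    continue
                present.discard(edges[i])
                present.discard(edges[j])
                if e1 in present or e2 in present or e1 == e2:
                    # restoring; the move collides with itself or a survivor
                    present.add(edges[i])
                    present.add(edges[j])
                    continue
                present.add(e1)
                present.add(e2)
                edges[i] = e1
                edges[j] = e2
        for u, v, s in edges:
            out.add_edge(u, v, s)
    return out


def shuffle_edge_signs(kg: CausalKG, seed: int) -> CausalKG:
    """Alternative null: keep the wiring, shuffle edge signs within each
    (source-kind, target-kind) stratum.  Preserves the per-stratum sign
    distribution exactly.  May drop edges when a shuffled sign duplicates an
    existing parallel edge; such collisions are resampled greedily."""
    rng = np.random.default_rng(seed)
    out = CausalKG()
    for n in kg.nodes():
        out.add_node(n, kg.kind(n))
    strata: dict[tuple, list[tuple[str, str, int]]] = {}
    for e in sorted(kg.edges(), key=lambda e: (e.source, e.target, e.sign)):
        key = (kg.kind(e.source).value, kg.kind(e.target).value)
        strata.setdefault(key, []).append((e.source, e.target, e.sign))
    for key in sorted(strata):
        edges = strata[key]
        signs = np.array([s for _, _, s in edges])
        rng.shuffle(signs)
        for (u, v, _), s in zip(edges, signs):
            out.add_edge(u, v, int(s))
    return out


def permute_signature(sig: Signature, seed: int) -> Signature:
    """Shuffle a signature's values over its measured genes.

    The multiset of {-1, 0, +1} calls is conserved exactly; unmeasured genes
    stay unmeasured.  Destroys gene-level information while preserving the
    overall expression-call distribution."""
    rng = np.random.default_rng(seed)
    genes = sorted(sig.values)
    values = np.array([sig.values[g] for g in genes])
    perm = rng.permutation(len(values))
    return replace(sig, values={g: int(values[p]) for g, p in zip(genes, perm)})


@dataclass
class PermutationReport:
    """Observed prioritization vs. its permutation null."""

    observed_n_prioritized: int
    observed_precision: Optional[float]
    null_n_prioritized: list[int]
    null_precision: list[Optional[float]]
    p_value_n_prioritized: float
    p_value_precision: Optional[float]
    n_permutations: int

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_n_prioritized))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_n_prioritized, ddof=1)) if self.n_permutations > 1 else 0.0


def _empirical_p(observed: float, null: list[float]) -> float:
    """Add-one one-sided empirical p: (1 + #{null >= observed}) / (1 + n)."""
    return (1 + sum(1 for x in null if x >= observed)) / (1 + len(null))


def permutation_experiment(
    kg: CausalKG,
    drug_sigs: Mapping[str, Signature],
    disease_sigs: Mapping[str, Signature],
    labels: LabelSet,
    config: ReasoningConfig = ReasoningConfig(),
    spec: PermutationSpec = PermutationSpec(),
) -> PermutationReport:
    """Compare observed prioritization against permuted replicates.

    Each replicate rewires the KG (XSwap) and/or shuffles every signature,
    with per-replicate seeds derived from ``spec.seed``, then reruns the full
    all-pairs prioritization.  Reports the observed and null counts of
    prioritized pairs and precisions, with add-one empirical one-sided
    p-values.  The precision p-value is None when the observed precision is
    undefined (nothing prioritized); undefined null precisions count as 0 in
    its comparison (an empty null shortlist cannot beat an observed one).
    """
    observed = prioritize_pairs(kg, drug_sigs, disease_sigs, config)
    obs_n = len(observed.prioritized_pairs)
    obs_prec = precision(observed.prioritized_pairs, labels)
    null_n: list[int] = []
    null_prec: list[Optional[float]] = []
    seed_seq = np.random.SeedSequence(spec.seed)
    for child in seed_seq.spawn(spec.n_permutations):
        sub_seeds = [int(s) for s in child.generate_state(3, dtype=np.uint32) % (2**31)]
        kg_i = (
            xswap_permute_kg(kg, replace(spec, seed=sub_seeds[0]))
            if spec.permute_kg
            else kg
        )
        if spec.permute_signatures:
            drug_i = {
                k: permute_signature(s, sub_seeds[1] + i)
                for i, (k, s) in enumerate(sorted(drug_sigs.items()))
            }
            disease_i = {
                k: permute_signature(s, sub_seeds[2] + i)
                for i, (k, s) in enumerate(sorted(disease_sigs.items()))
            }
        else:
            drug_i, disease_i = dict(drug_sigs), dict(disease_sigs)
        rep = prioritize_pairs(kg_i, drug_i, disease_i, config)
        null_n.append(len(rep.prioritized_pairs))
        null_prec.append(precision(rep.prioritized_pairs, labels))
    p_n = _empirical_p(obs_n, [float(x) for x in null_n])
    p_prec = (
        _empirical_p(obs_prec, [x if x is not None else 0.0 for x in null_prec])
        if obs_prec is not None
        else None
    )
    return PermutationReport(
        observed_n_prioritized=obs_n,
        observed_precision=obs_prec,
        null_n_prioritized=null_n,
        null_precision=null_prec,
        p_value_n_prioritized=p_n,
        p_value_precision=p_prec,
        n_permutations=spec.n_permutations,
    )
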