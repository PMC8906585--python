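"""Causal path reasoning: enumerate bounded acyclic paths, propagate signs,
score signature concordance, and prioritize drug-disease pairs or targets.

The core idea: a drug-disease pair is worth prioritizing when at least one
acyclic causal path connects them in the knowledge graph, the regulation signs
that the path *predicts* for its proteins agree with what a drug-perturbation
experiment actually measured (concordance), and the same path's predictions
are opposite to the disease expression signature (anti-correlation), each
check within a small error budget.  A path error is a protein whose measured
call is absent, uninformative, or contradicts the prediction.

Sign propagation is multiplicative: a path predicts protein *i* to move in
the direction given by the product of the first *i* edge signs, and the
product of all edge signs is the path's net (cumulative) effect on its
endpoint.

The target-prioritization variant reverses the traversal: starting from a
disease, every protein with bounded-length paths *into* the disease is scored
by how many of those paths are concordant with the disease signature,
flagging candidate upstream regulators of the phenotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterator, Mapping, Optional

from .kg import CausalKG, KGError, NodeKind
from .signatures import Signature, SignatureContext

logger = logging.getLogger(__name__)

__all__ = [
    "ReasoningConfig",
    "CausalPath",
    "PathVerdict",
    "PrioritizationResult",
    "PrioritizationReport",
    "TargetRanking",
    "enumerate_causal_paths",
    "enumerate_paths_to_disease",
    "infer_regulation",
    "is_concordant",
    "is_anti_correlated",
    "is_drug_prioritized",
    "prioritize_pairs",
    "prioritize_targets",
    "extract_mechanism_subgraph",
]

MIN_PATH_EDGES = 2  # shortest legal path: source -> protein -> target


@dataclass(frozen=True)
class ReasoningConfig:
    """Knobs of the reasoning layer.

    lmax
        Maximum path length in edges; paths longer than this are never
        considered (default 7 — longer chains are assumed biologically
        diluted).
    max_errors
        Error budget applied *per check*: up to this many proteins on a path
        may be unmeasured/uninformative/contradictory within the drug
        concordance check, and independently within the disease
        anti-correlation check (default 1).
    require_disease_inhibition
        When True (default), only paths whose cumulative effect on the
        disease is inhibitory (-1) are considered in drug mode: a therapeutic
        mechanism should revert, not promote, the disease.
    treat_zero_as_error
        When True (default), a measured-but-unchanged gene (call 0) counts as
        a path error, like an unmeasured gene; when False it is a silent pass.
    """

    lmax: int = 7
    max_errors: int = 1
    require_disease_inhibition: bool = True
    treat_zero_as_error: bool = True

    def __post_init__(self):
        if self.lmax < MIN_PATH_EDGES:
            raise ValueError(f"lmax must be >= {MIN_PATH_EDGES}, got {self.lmax}")
        if self.max_errors < 0:
            raise ValueError(f"max_errors must be >= 0, got {self.max_errors}")


@dataclass(frozen=True)
class CausalPath:
    """A node-simple signed path with per-node inferred regulations.

    ``nodes`` runs from the perturbation source (a chemical, or a protein in
    target mode) to the endpoint (a disease).  ``edge_signs[i]`` is the sign
    of the edge nodes[i] -> nodes[i+1]; ``node_kinds`` parallels ``nodes``.
    Inferred regulations are carried by every protein strictly after the
    source (the source itself is the perturbation, not a prediction).
    """

    nodes: tuple[str, ...]
    edge_signs: tuple[int, ...]
    node_kinds: tuple[NodeKind, ...]

    def __post_init__(self):
        if len(self.edge_signs) != len(self.nodes) - 1:
            raise ValueError("edge_signs must have one entry per edge")
        if len(self.node_kinds) != len(self.nodes):
            raise ValueError("node_kinds must parallel nodes")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError(f"path is not node-simple: {self.nodes}")
        if any(s not in (1, -1) for s in self.edge_signs):
            raise ValueError(f"edge signs must be +/-1: {self.edge_signs}")

    @property
    def length(self) -> int:
        return len(self.edge_signs)

    @property
    def protein_positions(self) -> tuple[int, ...]:
        return tuple(
            i
            for i in range(1, len(self.nodes))
            if self.node_kinds[i] == NodeKind.PROTEIN
        )

    @cached_property
    def inferred_regulation(self) -> dict[str, int]:
        """Predicted direction for each protein: product of edge signs up to it."""
        regs: dict[str, int] = {}
        running = 1
        for i, sign in enumerate(self.edge_signs):
            running *= sign
            pos = i + 1
            if pos in self.protein_positions:
                regs[self.nodes[pos]] = running
        return regs

    @cached_property
    def cumulative_effect(self) -> int:
        """Net predicted effect on the path endpoint: product of all edge signs."""
        effect = 1
        for s in self.edge_signs:
            effect *= s
        return effect

    def sort_key(self) -> tuple:
        return (self.nodes, self.edge_signs)


def infer_regulation(path: CausalPath) -> dict[str, int]:
    """Per-protein inferred regulation signs along a path."""
    return dict(path.inferred_regulation)


def _dfs_paths(
    kg: CausalKG,
    source: str,
    target: str,
    lmax: int,
    min_len: int = MIN_PATH_EDGES,
) -> Iterator[tuple[tuple[str, ...], tuple[int, ...]]]:
    """Depth-first bounded enumeration of node-simple signed paths.

    Children are visited in sorted (node id, sign) order, so emission order is
    lexicographic in (node sequence, sign sequence).  Parallel signed edges
    contribute distinct paths.  The length bound prunes during descent; no
    unbounded path set is ever materialized.
    """
    stack_nodes = [source]
    stack_signs: list[int] = []
    on_path = {source}

    def descend() -> Iterator[tuple[tuple[str, ...], tuple[int, ...]]]:
        depth = len(stack_signs)
        if depth >= lmax:
            return
        for succ, sign in kg.out_edges(stack_nodes[-1]):
            if succ == target:
                if depth + 1 >= min_len:
                    yield (tuple(stack_nodes) + (target,), tuple(stack_signs) + (sign,))
                continue
            if succ in on_path:
                continue
            # interior nodes must be able to continue: only proteins have
            # out-edges under the edge-type constraints
            stack_nodes.append(succ)
            stack_signs.append(sign)
            on_path.add(succ)
            yield from descend()
            on_path.discard(succ)
            stack_nodes.pop()
            stack_signs.pop()

    yield from descend()


def enumerate_causal_paths(
    kg: CausalKG,
    source: str,
    target: str,
    lmax: int = 7,
    mode: str = "drug",
) -> list[CausalPath]:
    """Every node-simple directed path source -> ... -> target with
    2..lmax edges, in deterministic lexicographic order.

    ``mode="drug"`` requires a chemical source and disease target;
    ``mode="target"`` requires a protein source and disease target (the
    upstream-regulator orientation).  Interior nodes are proteins, enforced by
    the KG's edge-type constraints.
    """
    for nid in (source, target):
        if nid not in kg:
            raise KGError(f"node {nid!r} not in KG")
    if mode == "drug":
        want_source = NodeKind.CHEMICAL
    elif mode == "target":
        want_source = NodeKind.PROTEIN
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if kg.kind(source) != want_source:
        raise KGError(
            f"source {source!r} has kind {kg.kind(source).value}, "
            f"expected {want_source.value} in {mode} mode"
        )
    if kg.kind(target) != NodeKind.DISEASE:
        raise KGError(f"target {target!r} must be a disease")
    if lmax < MIN_PATH_EDGES:
        raise ValueError(f"lmax must be >= {MIN_PATH_EDGES}")
    paths = [
        _make_path(kg, nodes, signs) for nodes, signs in _dfs_paths(kg, source, target, lmax)
    ]
    paths.sort(key=CausalPath.sort_key)
    return paths


def _make_path(kg: CausalKG, nodes: tuple[str, ...], signs: tuple[int, ...]) -> CausalPath:
    return CausalPath(nodes, signs, tuple(kg.kind(n) for n in nodes))


def enumerate_paths_to_disease(
    kg: CausalKG, disease: str, lmax: int = 7
) -> dict[str, list[CausalPath]]:
    """All bounded node-simple protein -> ... -> disease paths, grouped by the
    starting protein.

    Implemented as a single reverse depth-first traversal from the disease, so
    the cost is shared across all candidate proteins rather than one forward
    enumeration per protein.
    """
    if disease not in kg:
        raise KGError(f"node {disease!r} not in KG")
    if kg.kind(disease) != NodeKind.DISEASE:
        raise KGError(f"{disease!r} is not a disease node")
    out: dict[str, list[CausalPath]] = {}

    stack_nodes = [disease]  # reversed: disease first
    stack_signs: list[int] = []
    on_path = {disease}

    def record() -> None:
        # stack holds disease <- p1 <- ... <- pk ; emit forward orientation
        nodes = tuple(reversed(stack_nodes))
        signs = tuple(reversed(stack_signs))
        out.setdefault(nodes[0], []).append(_make_path(kg, nodes, signs))

    def descend() -> None:
        depth = len(stack_signs)
        if depth >= lmax:
            return
        for pred, sign in kg.in_edges(stack_nodes[-1]):
            if pred in on_path:
                continue
            if kg.kind(pred) != NodeKind.PROTEIN:
                continue  # chemicals cannot head a target-mode path
            stack_nodes.append(pred)
            stack_signs.append(sign)
            on_path.add(pred)
            if depth + 1 >= MIN_PATH_EDGES:
                record()
            descend()
            on_path.discard(pred)
            stack_nodes.pop()
            stack_signs.pop()

    descend()
    for paths in out.values():
        paths.sort(key=CausalPath.sort_key)
    return out


# ---------------------------------------------------------------------------
# Concordance scoring


def _count_path_errors(
    path: CausalPath,
    sig: Signature,
    negate: bool,
    treat_zero_as_error: bool,
) -> int:
    """Errors on a path against a signature.

    For each protein carrying an inferred regulation, an error is counted
    when the gene is unmeasured, measured but 0 (if zeros count as errors), or
    its call differs from the expected sign — the inferred regulation itself,
    or its negation when ``negate`` (the anti-correlation check).
    """
    errors = 0
    for protein, reg in path.inferred_regulation.items():
        call = sig.get(protein)
        expected = -reg if negate else reg
        if call is None:
            errors += 1
        elif call == 0:
            if treat_zero_as_error:
                errors += 1
        elif call != expected:
            errors += 1
    return errors


def is_concordant(
    path: CausalPath, drug_sig: Signature, config: ReasoningConfig = ReasoningConfig()
) -> tuple[bool, int]:
    """Does the drug-perturbation signature agree with the path's predicted
    regulations, within the error budget?  Returns (verdict, error count)."""
    errors = _count_path_errors(path, drug_sig, False, config.treat_zero_as_error)
    return errors <= config.max_errors, errors


def is_anti_correlated(
    path: CausalPath,
    disease_sig: Signature,
    config: ReasoningConfig = ReasoningConfig(),
) -> tuple[bool, int]:
    """Does the disease signature *oppose* the path's predicted regulations,
    within the error budget?  Returns (verdict, error count)."""
    errors = _count_path_errors(path, disease_sig, True, config.treat_zero_as_error)
    return errors <= config.max_errors, errors


@dataclass(frozen=True)
class PathVerdict:
    """Outcome of the two signature checks on one path.

    ``disease_errors`` is None when the anti-correlation check was not
    evaluated (non-concordant paths are filtered first).
    """

    path: CausalPath
    drug_errors: int
    concordant: bool
    disease_errors: Optional[int] = None
    anti_correlated: bool = False

    @property
    def surviving(self) -> bool:
        return self.concordant and self.anti_correlated


@dataclass
class PrioritizationResult:
    """One (source, target) pair with its path funnel."""

    source_id: str
    target_id: str
    n_paths_total: int
    n_considered: int  # after the cumulative-inhibition filter
    n_concordant: int
    n_surviving: int
    surviving_paths: list[PathVerdict] = field(default_factory=list)

    @property
    def prioritized(self) -> bool:
        return self.n_surviving >= 1

    @property
    def surviving_fraction(self) -> float:
        return self.n_surviving / self.n_paths_total if self.n_paths_total else 0.0


def is_drug_prioritized(
    kg: CausalKG,
    drug: str,
    disease: str,
    drug_sig: Signature,
    disease_sig: Signature,
    config: ReasoningConfig = ReasoningConfig(),
) -> PrioritizationResult:
    """Run the three-step check for one drug-disease pair.

    Step 1 enumerates all bounded acyclic paths; step 2 keeps those concordant
    with the drug signature; step 3 keeps, of these, those anti-correlated
    with the disease signature.  When the config requires disease inhibition,
    paths whose cumulative effect on the disease is activating are discarded
    before step 2.  The pair is prioritized iff at least one path survives all
    checks; surviving paths are retained for mechanism interpretation.
    """
    if drug_sig.context != SignatureContext.DRUG:
        raise ValueError(f"drug_sig has context {drug_sig.context.value!r}")
    if disease_sig.context != SignatureContext.DISEASE:
        raise ValueError(f"disease_sig has context {disease_sig.context.value!r}")
    paths = enumerate_causal_paths(kg, drug, disease, config.lmax, mode="drug")
    considered = [
        p
        for p in paths
        if not config.require_disease_inhibition or p.cumulative_effect == -1
    ]
    n_concordant = 0
    surviving: list[PathVerdict] = []
    for path in considered:
        ok_drug, drug_errors = is_concordant(path, drug_sig, config)
        if not ok_drug:
            continue
        n_concordant += 1
        ok_dis, disease_errors = is_anti_correlated(path, disease_sig, config)
        if ok_dis:
            surviving.append(
                PathVerdict(path, drug_errors, True, disease_errors, True)
            )
    return PrioritizationResult(
        source_id=drug,
        target_id=disease,
        n_paths_total=len(paths),
        n_considered=len(considered),
        n_concordant=n_concordant,
        n_surviving=len(surviving),
        surviving_paths=surviving,
    )


@dataclass
class PrioritizationReport:
    """All-pairs prioritization output plus the per-step funnel."""

    results: list[PrioritizationResult]
    funnel: dict[str, int]
    skipped_drugs: list[str] = field(default_factory=list)
    skipped_diseases: list[str] = field(default_factory=list)

    @property
    def prioritized_pairs(self) -> set[tuple[str, str]]:
        return {(r.source_id, r.target_id) for r in self.results if r.prioritized}

    @property
    def candidate_pairs(self) -> set[tuple[str, str]]:
        """Pairs connected by at least one bounded path (the chance-baseline
        denominator)."""
        return {
            (r.source_id, r.target_id) for r in self.results if r.n_paths_total >= 1
        }


def prioritize_pairs(
    kg: CausalKG,
    drug_sigs: Mapping[str, Signature],
    disease_sigs: Mapping[str, Signature],
    config: ReasoningConfig = ReasoningConfig(),
) -> PrioritizationReport:
    """Evaluate every drug x disease combination with signatures and KG nodes.

    Prioritized pairs are ranked by surviving-path count (descending), ties
    broken by surviving fraction of total paths (descending) then pair id;
    non-prioritized pairs follow in id order.  The report's funnel counts how
    many pairs have at least one path, at least one concordant path, and at
    least one surviving path — these are non-increasing by construction.
    """
    if not drug_sigs or not disease_sigs:
        raise ValueError("need at least one drug and one disease signature")
    skipped_drugs = sorted(d for d in drug_sigs if d not in kg)
    skipped_diseases = sorted(d for d in disease_sigs if d not in kg)
    for d in skipped_drugs:
        logger.warning("drug %s not in KG; skipped", d)
    for d in skipped_diseases:
        logger.warning("disease %s not in KG; skipped", d)
    drugs = sorted(d for d in drug_sigs if d in kg)
    diseases = sorted(d for d in disease_sigs if d in kg)
    results = [
        is_drug_prioritized(kg, drug, disease, drug_sigs[drug], disease_sigs[disease], config)
        for drug in drugs
        for disease in diseases
    ]
    results.sort(
        key=lambda r: (
            not r.prioritized,
            -r.n_surviving,
            -r.surviving_fraction,
            (r.source_id, r.target_id),
        )
    )
    funnel = {
        "pairs_evaluated": len(results),
        "pairs_with_path": sum(1 for r in results if r.n_paths_total >= 1),
        "pairs_concordant": sum(1 for r in results if r.n_concordant >= 1),
        "pairs_prioritized": sum(1 for r in results if r.prioritized),
    }
    logger.info("prioritization funnel: %s", funnel)
    return PrioritizationReport(results, funnel, skipped_drugs, skipped_diseases)


@dataclass(frozen=True)
class TargetRanking:
    """A candidate upstream-regulator protein for a disease."""

    protein_id: str
    n_concordant_paths: int
    n_nodes_in_concordant_paths: int


def prioritize_targets(
    kg: CausalKG,
    disease: str,
    disease_sig: Signature,
    config: ReasoningConfig = ReasoningConfig(),
) -> list[TargetRanking]:
    """Rank proteins as candidate upstream regulators of a disease.

    For every protein with at least one bounded path into the disease, counts
    the paths whose inferred regulations are concordant (equal, not negated)
    with the disease signature within the error budget — such a protein could
    drive the observed expression state.  Proteins are ranked by
    concordant-path count descending (ties by id); each entry also reports the
    number of distinct nodes appearing across its concordant paths.  Proteins
    with zero concordant paths are omitted.
    """
    if disease_sig.context != SignatureContext.DISEASE:
        raise ValueError(f"disease_sig has context {disease_sig.context.value!r}")
    by_protein = enumerate_paths_to_disease(kg, disease, config.lmax)
    rankings: list[TargetRanking] = []
    for protein, paths in by_protein.items():
        concordant_paths = [
            p for p in paths if is_concordant(p, disease_sig, config)[0]
        ]
        if not concordant_paths:
            continue
        nodes: set[str] = set()
        for p in concordant_paths:
            nodes.update(p.nodes)
        rankings.append(TargetRanking(protein, len(concordant_paths), len(nodes)))
    rankings.sort(key=lambda r: (-r.n_concordant_paths, r.protein_id))
    return rankings


def extract_mechanism_subgraph(result: PrioritizationResult) -> CausalKG:
    """Union of all surviving paths of a prioritized pair, as a causal KG.

    Each edge carries a ``traversal_count`` attribute: how many surviving
    paths use it.  The subgraph is the pair's proposed mechanism of action.
    """
    if not result.prioritized:
        raise ValueError(
            f"({result.source_id}, {result.target_id}) is not prioritized; "
            "no mechanism to extract"
        )
    sub = CausalKG()
    counts: dict[tuple[str, str, int], int] = {}
    for verdict in result.surviving_paths:
        path = verdict.path
        for node, kind in zip(path.nodes, path.node_kinds):
            sub.add_node(node, kind)
        for i, sign in enumerate(path.edge_signs):
            key = (path.nodes[i], path.nodes[i + 1], sign)
            if key in counts:
                counts[key] += 1
            else:
                sub.add_edge(*key)
                counts[key] = 1
    for (u, v, s), c in counts.items():
        sub.graph.edges[u, v, s]["traversal_count"] = c
    return sub
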