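"""Typed signed causal knowledge graph: data model and I/O.

The graph holds three node kinds (chemical, protein, disease) connected by
signed causal edges (+1 activation, -1 inhibition).  Only three edge strata
exist: chemical→protein, protein→protein and protein→disease, so any directed
walk starting at a chemical passes exclusively through proteins before it can
reach a disease.  Parallel contradictory edges (A activates B *and* A inhibits
B) are retained as two distinct edges: knowledge graphs aggregate conflicting
sources, and collapsing them would silently discard mechanism hypotheses.
"""

from __future__ import annotations

import enum
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "NodeKind",
    "NodeRef",
    "CausalEdge",
    "CausalKG",
    "KGError",
    "KGLoadError",
    "KGStats",
    "load_kg",
    "write_kg",
    "kg_stats",
    "RELATION_TO_SIGN",
    "SIGN_TO_RELATION",
]


class NodeKind(str, enum.Enum):
    """Biological entity classes admitted in the graph."""

    CHEMICAL = "chemical"
    PROTEIN = "protein"
    DISEASE = "disease"


#: Admissible (source kind, target kind) combinations.
ALLOWED_EDGE_KINDS = frozenset(
    {
        (NodeKind.CHEMICAL, NodeKind.PROTEIN),
        (NodeKind.PROTEIN, NodeKind.PROTEIN),
        (NodeKind.PROTEIN, NodeKind.DISEASE),
    }
)

RELATION_TO_SIGN = {"activates": 1, "inhibits": -1}
SIGN_TO_RELATION = {1: "activates", -1: "inhibits"}

TSV_HEADER = ["source_id", "source_kind", "relation", "target_id", "target_kind"]


class KGError(ValueError):
    """Violation of the causal-KG data model."""


class KGLoadError(KGError):
    """Raised in strict mode when a file contains invalid rows.

    Carries the per-row report in :attr:`row_errors` as
    ``(line_number, message)`` tuples.
    """

    def __init__(self, path: str, row_errors: list[tuple[int, str]]):
        self.path = path
        self.row_errors = row_errors
        lines = "; ".join(f"line {n}: {m}" for n, m in row_errors[:20])
        more = "" if len(row_errors) <= 20 else f" (+{len(row_errors) - 20} more)"
        super().__init__(f"{len(row_errors)} invalid row(s) in {path}: {lines}{more}")


@dataclass(frozen=True)
class NodeRef:
    """A graph node: CURIE-style identifier plus its kind."""

    id: str
    kind: NodeKind

    def __post_init__(self):
        if not self.id:
            raise KGError("node id must be non-empty")


@dataclass(frozen=True)
class CausalEdge:
    """A signed causal relation between two node ids."""

    source: str
    target: str
    sign: int
    provenance: Optional[str] = None

    def __post_init__(self):
        if self.sign not in (1, -1):
            raise KGError(f"edge sign must be +1 or -1, got {self.sign!r}")
        if self.source == self.target:
            raise KGError(f"self-edge not allowed: {self.source}")


class CausalKG:
    """Directed multigraph of typed nodes and signed edges.

    Backed by a :class:`networkx.MultiDiGraph` whose edge keys are the edge
    signs, which makes the (source, target, sign) triple unique by
    construction.  Extra per-edge attributes (``provenance``, and the
    ``traversal_count`` annotation added by mechanism extraction) live in the
    edge data dict.
    """

    def __init__(self) -> None:
        self.graph = nx.MultiDiGraph()

    # -- construction -----------------------------------------------------

    def add_node(self, node_id: str, kind: NodeKind | str) -> None:
        kind = NodeKind(kind)
        if node_id in self.graph:
            existing = self.graph.nodes[node_id]["kind"]
            if existing != kind:
                raise KGError(
                    f"node {node_id!r} already registered as {existing.value}, "
                    f"cannot re-register as {kind.value}"
                )
            return
        if not node_id:
            raise KGError("node id must be non-empty")
        self.graph.add_node(node_id, kind=kind)

    def add_edge(
        self,
        source: str,
        target: str,
        sign: int,
        provenance: Optional[str] = None,
    ) -> bool:
        """Add a signed edge; returns False if the triple already exists."""
        if sign not in (1, -1):
            raise KGError(f"edge sign must be +1 or -1, got {sign!r}")
        if source == target:
            raise KGError(f"self-edge not allowed: {source}")
        for nid in (source, target):
            if nid not in self.graph:
                raise KGError(f"edge endpoint {nid!r} is not a registered node")
        stratum = (self.kind(source), self.kind(target))
        if stratum not in ALLOWED_EDGE_KINDS:
            raise KGError(
                f"edge {source}->{target} between kinds "
                f"{stratum[0].value}->{stratum[1].value} is not allowed"
            )
        if self.graph.has_edge(source, target, key=sign):
            return False
        self.graph.add_edge(source, target, key=sign, sign=sign, provenance=provenance)
        return True

    # -- queries -----------------------------------------------------------

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def kind(self, node_id: str) -> NodeKind:
        try:
            return self.graph.nodes[node_id]["kind"]
        except KeyError:
            raise KGError(f"unknown node {node_id!r}") from None

    def nodes(self, kind: Optional[NodeKind | str] = None) -> list[str]:
        """Sorted node ids, optionally restricted to one kind."""
        if kind is None:
            return sorted(self.graph.nodes)
        kind = NodeKind(kind)
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == kind)

    def node_refs(self) -> list[NodeRef]:
        return [NodeRef(n, self.graph.nodes[n]["kind"]) for n in self.nodes()]

    def edges(self) -> Iterator[CausalEdge]:
        for u, v, k, d in self.graph.edges(keys=True, data=True):
            yield CausalEdge(u, v, k, d.get("provenance"))

    def out_edges(self, node_id: str) -> list[tuple[str, int]]:
        """Deterministically ordered (successor, sign) pairs."""
        return sorted((v, k) for _, v, k in self.graph.out_edges(node_id, keys=True))

    def in_edges(self, node_id: str) -> list[tuple[str, int]]:
        """Deterministically ordered (predecessor, sign) pairs."""
        return sorted((u, k) for u, _, k in self.graph.in_edges(node_id, keys=True))

    def copy(self) -> "CausalKG":
        out = CausalKG()
        out.graph = self.graph.copy()
        return out

    def edge_multiset(self) -> frozenset[tuple[str, str, int]]:
        return frozenset((u, v, k) for u, v, k in self.graph.edges(keys=True))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CausalKG):
            return NotImplemented
        self_nodes = {(n, d["kind"]) for n, d in self.graph.nodes(data=True)}
        other_nodes = {(n, d["kind"]) for n, d in other.graph.nodes(data=True)}
        return self_nodes == other_nodes and self.edge_multiset() == other.edge_multiset()


@dataclass
class KGStats:
    """Descriptive breakdown of a causal KG."""

    nodes_per_kind: dict[str, int]
    edges_per_stratum: dict[tuple[str, str, int], int]
    n_negative_edges: int
    n_positive_edges: int
    in_degree: dict[str, int] = field(repr=False, default_factory=dict)
    out_degree: dict[str, int] = field(repr=False, default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return sum(self.nodes_per_kind.values())

    @property
    def n_edges(self) -> int:
        return sum(self.edges_per_stratum.values())


def kg_stats(kg: CausalKG) -> KGStats:
    """Counts of nodes per kind, edges per (source-kind, target-kind, sign)
    stratum, and the in/out degree sequences."""
    nodes_per_kind = Counter(k.value for k in (kg.kind(n) for n in kg.graph.nodes))
    strata: Counter = Counter()
    neg = pos = 0
    for e in kg.edges():
        strata[(kg.kind(e.source).value, kg.kind(e.target).value, e.sign)] += 1
        if e.sign < 0:
            neg += 1
        else:
            pos += 1
    return KGStats(
        nodes_per_kind={k.value: nodes_per_kind.get(k.value, 0) for k in NodeKind},
        edges_per_stratum=dict(strata),
        n_negative_edges=neg,
        n_positive_edges=pos,
        in_degree=dict(kg.graph.in_degree()),
        out_degree=dict(kg.graph.out_degree()),
    )


# ---------------------------------------------------------------------------
# I/O


def _parse_tsv(path: Path, strict: bool) -> CausalKG:
    kg = CausalKG()
    row_errors: list[tuple[int, str]] = []
    n_rows = 0
    n_dup = 0
    with open(path, encoding="utf-8") as fh:
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if [f.strip() for f in fields] != TSV_HEADER:
                    raise KGLoadError(
                        str(path),
                        [(lineno, f"bad header {fields!r}, expected {TSV_HEADER!r}")],
                    )
                header_seen = True
                continue
            if len(fields) != 5:
                row_errors.append((lineno, f"expected 5 columns, got {len(fields)}"))
                continue
            src, src_kind, relation, tgt, tgt_kind = (f.strip() for f in fields)
            try:
                sk = NodeKind(src_kind)
                tk = NodeKind(tgt_kind)
            except ValueError:
                row_errors.append(
                    (lineno, f"unknown node kind in {src_kind!r}/{tgt_kind!r}")
                )
                continue
            if relation not in RELATION_TO_SIGN:
                row_errors.append((lineno, f"unknown relation {relation!r}"))
                continue
            sign = RELATION_TO_SIGN[relation]
            n_rows += 1
            try:
                kg.add_node(src, sk)
                kg.add_node(tgt, tk)
                added = kg.add_edge(src, tgt, sign)
            except KGError as exc:
                row_errors.append((lineno, str(exc)))
                continue
            if not added:
                n_dup += 1
    if row_errors:
        if strict:
            raise KGLoadError(str(path), row_errors)
        for lineno, msg in row_errors:
            logger.warning("%s line %d skipped: %s", path, lineno, msg)
    if n_dup:
        logger.info("%s: collapsed %d duplicate edge row(s)", path, n_dup)
    return kg


def _parse_graphml(path: Path, strict: bool) -> CausalKG:
    g = nx.read_graphml(path, force_multigraph=True)
    kg = CausalKG()
    errors: list[tuple[int, str]] = []
    for n, d in g.nodes(data=True):
        try:
            kg.add_node(str(n), NodeKind(d.get("kind")))
        except (KGError, ValueError) as exc:
            errors.append((0, f"node {n}: {exc}"))
    for u, v, d in g.edges(data=True):
        try:
            kg.add_edge(str(u), str(v), int(d["sign"]), d.get("provenance"))
        except (KGError, KeyError, TypeError) as exc:
            errors.append((0, f"edge {u}->{v}: {exc}"))
    if errors:
        if strict:
            raise KGLoadError(str(path), errors)
        for _, msg in errors:
            logger.warning("%s skipped: %s", path, msg)
    return kg


def load_kg(path: str | Path, dialect: str = "tsv", strict: bool = True) -> CausalKG:
    """Load a causal KG from disk.

    Parameters
    ----------
    path
        Edge-list file.  The ``tsv`` dialect is a tab-separated table with
        header ``source_id source_kind relation target_id target_kind``
        (relation ``activates`` or ``inhibits``; ``#`` starts a comment line).
        The ``graphml`` dialect expects node attribute ``kind`` and edge
        attribute ``sign``.
    dialect
        ``"tsv"`` or ``"graphml"``.
    strict
        When True (default) any invalid row raises :class:`KGLoadError` with a
        per-row report; when False invalid rows are skipped with a warning.

    Duplicate (source, target, sign) rows are collapsed.  A load summary is
    emitted to the module logger.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        kg = _parse_tsv(path, strict)
    elif dialect == "graphml":
        kg = _parse_graphml(path, strict)
    else:
        raise ValueError(f"unknown dialect {dialect!r} (expected 'tsv' or 'graphml')")
    stats = kg_stats(kg)
    logger.info(
        "loaded %s: %s nodes %r, %d edges (%d activating, %d inhibiting)",
        path,
        stats.n_nodes,
        stats.nodes_per_kind,
        stats.n_edges,
        stats.n_positive_edges,
        stats.n_negative_edges,
    )
    return kg


def write_kg(kg: CausalKG, path: str | Path, dialect: str = "tsv") -> None:
    """Serialize a KG; reloading reproduces the exact edge multiset with
    identical ids, kinds and signs.

    The tsv dialect is an edge list and therefore cannot carry nodes with no
    incident edges; use graphml when isolated nodes must survive the round
    trip.
    """
    path = Path(path)
    if dialect == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(TSV_HEADER) + "\n")
            for e in sorted(kg.edges(), key=lambda e: (e.source, e.target, -e.sign)):
                fh.write(
                    "\t".join(
                        [
                            e.source,
                            kg.kind(e.source).value,
                            SIGN_TO_RELATION[e.sign],
                            e.target,
                            kg.kind(e.target).value,
                        ]
                    )
                    + "\n"
                )
    elif dialect == "graphml":
        g = nx.MultiDiGraph()
        for n in kg.nodes():
            g.add_node(n, kind=kg.kind(n).value)
        for u, v, k, d in kg.graph.edges(keys=True, data=True):
            attrs = {a: w for a, w in d.items() if w is not None}
            attrs["sign"] = k
            g.add_edge(u, v, key=k, **attrs)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r} (expected 'tsv' or 'graphml')")
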