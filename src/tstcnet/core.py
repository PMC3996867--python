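"""Core graph model: rooted DAGs, leaf labelings, node/arc taxonomy, validation.

The objects here follow the standard definitions for explicit (rooted,
directed, acyclic) phylogenetic networks:

* a *rDAG* is a nonempty rooted DAG — exactly one node of in-degree 0, and
  every node reachable from it by a directed path;
* an *S-rDAG* is a rDAG whose leaves are injectively labeled by a taxon set S;
* a *phylogenetic network* is an S-rDAG in which no tree node is elementary
  and every hybrid node has out-degree 1 with a tree-type child.

Node identifiers are opaque strings; only leaves carry taxon identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Tuple

import networkx as nx

__all__ = [
    "Diagnostic",
    "InvalidGraphError",
    "RootedDAG",
    "SRDAG",
    "NodeClassification",
    "Classification",
    "TREE_ARC",
    "HYBRIDIZATION_ARC",
    "validate_rdag",
    "classify",
    "validate_network",
    "label_sort_key",
    "rank_labels",
]

Arc = Tuple[str, str]

#: Arc kinds, named by the type of the arc's head.
TREE_ARC = "tree"
HYBRIDIZATION_ARC = "hybridization"


@dataclass(frozen=True)
class Diagnostic:
    """A single validation failure: a machine code plus the offending items."""

    code: str
    message: str
    nodes: Tuple[str, ...] = ()
    arcs: Tuple[Arc, ...] = ()
    line: Optional[int] = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        loc = f" (line {self.line})" if self.line is not None else ""
        return f"{self.code}: {self.message}{loc}"


class InvalidGraphError(ValueError):
    """Raised when a candidate graph violates a structural invariant."""

    def __init__(self, diagnostics: Iterable[Diagnostic]):
        self.diagnostics: Tuple[Diagnostic, ...] = tuple(diagnostics)
        super().__init__("; ".join(str(d) for d in self.diagnostics))

    @property
    def codes(self) -> Tuple[str, ...]:
        return tuple(d.code for d in self.diagnostics)


def _collect_structure_diagnostics(
    nodes: Iterable[str], arcs: Iterable[Arc]
) -> Tuple[Tuple[str, ...], Tuple[Arc, ...], Tuple[Diagnostic, ...]]:
    """Check the rDAG invariants, returning normalized data plus diagnostics."""
    node_list = list(nodes)
    arc_list = list(arcs)
    diags = []

    seen_arcs = set()
    for a in arc_list:
        u, v = a
        if u == v:
            diags.append(
                Diagnostic("self-arc", f"self-arc at node {u!r}", nodes=(u,), arcs=((u, v),))
            )
        if a in seen_arcs:
            diags.append(
                Diagnostic("duplicate arc", f"arc {a!r} repeated", arcs=(a,))
            )
        seen_arcs.add(a)

    node_set = set(node_list)
    for u, v in arc_list:
        node_set.add(u)
        node_set.add(v)

    if not node_set:
        return (), (), (Diagnostic("empty graph", "graph has no nodes"),)
    if diags:
        return tuple(sorted(node_set)), tuple(arc_list), tuple(diags)

    g = nx.DiGraph()
    g.add_nodes_from(node_set)
    g.add_edges_from(arc_list)

    roots = sorted(v for v in g.nodes if g.in_degree(v) == 0)
    if len(roots) != 1:
        if len(roots) == 0:
            diags.append(
                Diagnostic("not rooted", "no node of in-degree 0 (every node has a parent)")
            )
        else:
            diags.append(
                Diagnostic(
                    "not rooted",
                    f"{len(roots)} nodes of in-degree 0: {', '.join(roots)}",
                    nodes=tuple(roots),
                )
            )
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        seq = tuple(u for u, _ in cycle)
        diags.append(
            Diagnostic(
                "not acyclic",
                "cycle found: " + " -> ".join(seq + (seq[0],)),
                nodes=seq,
                arcs=tuple(cycle),
            )
        )
    if len(roots) == 1:
        root = roots[0]
        reachable = set(nx.descendants(g, root)) | {root}
        missing = sorted(node_set - reachable)
        if missing:
            diags.append(
                Diagnostic(
                    "not connected from root",
                    "unreachable from root: " + ", ".join(missing),
                    nodes=tuple(missing),
                )
            )
    return tuple(sorted(node_set)), tuple(arc_list), tuple(diags)


class RootedDAG:
    """A nonempty rooted DAG: unique in-degree-0 node, all nodes reachable from it.

    Immutable once constructed; construction validates every invariant and
    raises :class:`InvalidGraphError` otherwise (inputs are rejected, never
    repaired).
    """

    __slots__ = ("_g", "_root", "_nodes", "_arcs")

    def __init__(self, nodes: Iterable[str] = (), arcs: Iterable[Arc] = ()):  # noqa: D401
        node_tup, arc_tup, diags = _collect_structure_diagnostics(nodes, arcs)
        if diags:
            raise InvalidGraphError(diags)
        g = nx.DiGraph()
        g.add_nodes_from(node_tup)
        g.add_edges_from(arc_tup)
        self._g = g
        self._nodes: FrozenSet[str] = frozenset(node_tup)
        self._arcs: FrozenSet[Arc] = frozenset(arc_tup)
        self._root = next(v for v in node_tup if g.in_degree(v) == 0)

    # -- basic accessors -------------------------------------------------
    @property
    def nx(self) -> nx.DiGraph:
        """The underlying networkx digraph (treat as read-only)."""
        return self._g

    @property
    def nodes(self) -> FrozenSet[str]:
        return self._nodes

    @property
    def arcs(self) -> FrozenSet[Arc]:
        return self._arcs

    @property
    def root(self) -> str:
        return self._root

    def children(self, v: str) -> Tuple[str, ...]:
        return tuple(sorted(self._g.successors(v)))

    def parents(self, v: str) -> Tuple[str, ...]:
        return tuple(sorted(self._g.predecessors(v)))

    def in_degree(self, v: str) -> int:
        return self._g.in_degree(v)

    def out_degree(self, v: str) -> int:
        return self._g.out_degree(v)

    @property
    def leaves(self) -> Tuple[str, ...]:
        return tuple(sorted(v for v in self._nodes if self._g.out_degree(v) == 0))

    def is_leaf(self, v: str) -> bool:
        return self._g.out_degree(v) == 0

    def is_hybrid(self, v: str) -> bool:
        return self._g.in_degree(v) > 1

    def is_tree_node(self, v: str) -> bool:
        return self._g.in_degree(v) <= 1

    def is_elementary(self, v: str) -> bool:
        return self._g.in_degree(v) <= 1 and self._g.out_degree(v) == 1

    def arc_kind(self, u: str, v: str) -> str:
        if (u, v) not in self._arcs:
            raise KeyError((u, v))
        return HYBRIDIZATION_ARC if self.is_hybrid(v) else TREE_ARC

    @property
    def hybridization_arcs(self) -> Tuple[Arc, ...]:
        return tuple(sorted(a for a in self._arcs if self.is_hybrid(a[1])))

    def topological_order(self) -> Tuple[str, ...]:
        return tuple(nx.lexicographical_topological_sort(self._g))

    # -- dunder ----------------------------------------------------------
    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, v: str) -> bool:
        return v in self._nodes

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RootedDAG):
            return NotImplemented
        return self._nodes == other._nodes and self._arcs == other._arcs

    def __hash__(self) -> int:
        return hash((self._nodes, self._arcs))

    def __repr__(self) -> str:
        return f"RootedDAG({len(self._nodes)} nodes, {len(self._arcs)} arcs, root={self._root!r})"


def validate_rdag(nodes: Iterable[str], arcs: Iterable[Arc]) -> RootedDAG:
    """Validate a candidate node/arc set as a rooted DAG.

    Returns the validated :class:`RootedDAG`; raises
    :class:`InvalidGraphError` whose diagnostics name the violated invariant
    ("empty graph", "not rooted", "not acyclic" with the cycle's node
    sequence, "not connected from root" with the unreachable nodes,
    "self-arc", "duplicate arc").
    """
    return RootedDAG(nodes, arcs)


@dataclass(frozen=True)
class NodeClassification:
    """Degree-based taxonomy of one node plus its height and depth.

    ``height`` is the longest directed path down to a leaf, ``depth`` the
    longest directed path from the root.
    """

    node: str
    in_degree: int
    out_degree: int
    is_leaf: bool
    is_tree: bool
    is_hybrid: bool
    is_elementary: bool
    height: int
    depth: int


@dataclass(frozen=True)
class Classification:
    nodes: Mapping[str, NodeClassification]
    arcs: Mapping[Arc, str]

    @property
    def hybrid_nodes(self) -> Tuple[str, ...]:
        return tuple(sorted(v for v, c in self.nodes.items() if c.is_hybrid))

    @property
    def elementary_nodes(self) -> Tuple[str, ...]:
        return tuple(sorted(v for v, c in self.nodes.items() if c.is_elementary))


def classify(G: RootedDAG) -> Classification:
    """Classify every node (leaf/tree/hybrid/elementary, height, depth) and arc.

    Heights and depths are longest-path lengths, computed by dynamic
    programming over a topological order.
    """
    g = G.nx
    order = list(nx.topological_sort(g))
    depth = {G.root: 0}
    for v in order:
        for c in g.successors(v):
            depth[c] = max(depth.get(c, 0), depth[v] + 1)
    height: Dict[str, int] = {}
    for v in reversed(order):
        succ = list(g.successors(v))
        height[v] = 0 if not succ else 1 + max(height[c] for c in succ)

    nodes = {}
    for v in G.nodes:
        ind, outd = g.in_degree(v), g.out_degree(v)
        nodes[v] = NodeClassification(
            node=v,
            in_degree=ind,
            out_degree=outd,
            is_leaf=outd == 0,
            is_tree=ind <= 1,
            is_hybrid=ind > 1,
            is_elementary=ind <= 1 and outd == 1,
            height=height[v],
            depth=depth[v],
        )
    arcs = {(u, v): (HYBRIDIZATION_ARC if nodes[v].is_hybrid else TREE_ARC) for u, v in G.arcs}
    return Classification(nodes=nodes, arcs=arcs)


def label_sort_key(label: str) -> Tuple[int, str]:
    """Total order on labels: by length, then lexicographic.

    On strings of decimal digits this coincides with numeric order, which
    realizes the convention S = {1, ..., n} for free while staying total on
    arbitrary strings.
    """
    return (len(label), label)


def rank_labels(labels: Iterable[str]) -> Dict[str, int]:
    """Rank-order a label set to 1..n under :func:`label_sort_key`."""
    return {lab: i + 1 for i, lab in enumerate(sorted(set(labels), key=label_sort_key))}


class SRDAG:
    """A rooted DAG with its leaves injectively labeled by taxa (an S-rDAG).

    ``labeling`` maps leaf node identifiers to label strings. By default the
    constructor enforces the labeling invariants (defined exactly on the
    leaves, injective); pass ``strict=False`` to build a candidate for
    :func:`validate_network` to report on.
    """

    __slots__ = ("graph", "labeling")

    def __init__(self, graph: RootedDAG, labeling: Mapping[str, str], *, strict: bool = True):
        self.graph = graph
        self.labeling: Dict[str, str] = dict(labeling)
        if strict:
            diags = validate_network(self, level="srdag")
            if diags:
                raise InvalidGraphError(diags)

    @classmethod
    def from_arcs(
        cls,
        arcs: Iterable[Arc],
        labeling: Mapping[str, str],
        nodes: Iterable[str] = (),
        *,
        strict: bool = True,
    ) -> "SRDAG":
        return cls(RootedDAG(nodes, arcs), labeling, strict=strict)

    # -- delegation ------------------------------------------------------
    @property
    def nodes(self) -> FrozenSet[str]:
        return self.graph.nodes

    @property
    def arcs(self) -> FrozenSet[Arc]:
        return self.graph.arcs

    @property
    def root(self) -> str:
        return self.graph.root

    @property
    def leaves(self) -> Tuple[str, ...]:
        return self.graph.leaves

    @property
    def labels(self) -> FrozenSet[str]:
        return frozenset(self.labeling.values())

    def label_of(self, v: str) -> Optional[str]:
        return self.labeling.get(v)

    def leaf_with_label(self, label: str) -> str:
        for v, lab in self.labeling.items():
            if lab == label:
                return v
        raise KeyError(label)

    def relabel_nodes(self, mapping: Mapping[str, str]) -> "SRDAG":
        """Rename node identifiers by a bijection (labels ride along)."""
        m = dict(mapping)
        if len(set(m.values())) != len(m) or set(m) != set(self.nodes):
            raise ValueError("mapping is not a bijection on the node set")
        arcs = [(m[u], m[v]) for u, v in self.arcs]
        nodes = [m[v] for v in self.nodes]
        labeling = {m[v]: lab for v, lab in self.labeling.items()}
        return SRDAG(RootedDAG(nodes, arcs), labeling)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SRDAG):
            return NotImplemented
        return self.graph == other.graph and self.labeling == other.labeling

    def __hash__(self) -> int:
        return hash((self.graph, tuple(sorted(self.labeling.items()))))

    def __repr__(self) -> str:
        return (
            f"SRDAG({len(self.nodes)} nodes, {len(self.arcs)} arcs, "
            f"labels={sorted(self.labels, key=label_sort_key)})"
        )


def validate_network(G: SRDAG, level: str = "srdag") -> Tuple[Diagnostic, ...]:
    """Check the leaf-labeling invariants and, optionally, the network axioms.

    ``level="srdag"`` checks only that the labeling is injective and defined
    on exactly the leaves. ``level="phylogenetic_network"`` additionally
    checks the two network axioms: no tree node is elementary, and every
    hybrid node has out-degree 1 with a tree-type single child. Returns a
    (possibly empty) tuple of diagnostics naming every offending node.
    """
    if level not in ("srdag", "phylogenetic_network"):
        raise ValueError(f"unknown level {level!r}")
    g = G.graph
    diags = []
    leaves = set(g.leaves)
    unlabeled = sorted(leaves - set(G.labeling))
    if unlabeled:
        diags.append(
            Diagnostic("unlabeled leaf", "leaves without labels: " + ", ".join(unlabeled), nodes=tuple(unlabeled))
        )
    nonleaf = sorted(set(G.labeling) - leaves)
    if nonleaf:
        diags.append(
            Diagnostic("non-leaf labeled", "labeled non-leaf nodes: " + ", ".join(nonleaf), nodes=tuple(nonleaf))
        )
    by_label: Dict[str, list] = {}
    for v, lab in G.labeling.items():
        by_label.setdefault(lab, []).append(v)
    for lab, vs in sorted(by_label.items()):
        if len(vs) > 1:
            diags.append(
                Diagnostic(
                    "duplicate label",
                    f"label {lab!r} on nodes " + ", ".join(sorted(vs)),
                    nodes=tuple(sorted(vs)),
                )
            )
    if level == "phylogenetic_network":
        elementary = sorted(v for v in g.nodes if g.is_elementary(v))
        if elementary:
            diags.append(
                Diagnostic(
                    "elementary tree node",
                    "elementary tree nodes: " + ", ".join(elementary),
                    nodes=tuple(elementary),
                )
            )
        bad_outdeg = sorted(v for v in g.nodes if g.is_hybrid(v) and g.out_degree(v) != 1)
        if bad_outdeg:
            diags.append(
                Diagnostic(
                    "hybrid out-degree",
                    "hybrid nodes with out-degree != 1: " + ", ".join(bad_outdeg),
                    nodes=tuple(bad_outdeg),
                )
            )
        bad_child = sorted(
            v
            for v in g.nodes
            if g.is_hybrid(v)
            and g.out_degree(v) == 1
            and g.is_hybrid(g.children(v)[0])
        )
        if bad_child:
            diags.append(
                Diagnostic(
                    "hybrid child of hybrid",
                    "hybrid nodes whose single child is hybrid: " + ", ".join(bad_child),
                    nodes=tuple(bad_child),
                )
            )
    return tuple(diags)
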