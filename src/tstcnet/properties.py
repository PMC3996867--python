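"""Property checkers: tree-sibling, time consistency, TSTC.

A *temporal assignment* on a network N = (V, E) is a map tau: V -> {1, 2, ...}
that is constant across hybridization arcs (the species meeting at a
reticulation must coexist) and strictly increasing along tree arcs
(speciation takes time). N is *time consistent* iff such a map exists, which
happens iff the star graph N* — N plus the reversal of every hybridization
arc — has no cycle through a tree arc. The checker here decides this via
strongly connected components of N* and, when consistent, returns a concrete
witness built by longest-path layering on the condensation.

An independent quotient-graph formulation (`time_consistency_quotient`) is
kept alongside as a cross-check oracle: cluster nodes by the undirected
hybridization arcs, then demand no tree arc inside a cluster and an acyclic
cluster quotient.

The checkers accept any valid S-rDAG, not only phylogenetic networks: the
arguments need only the tree/hybrid arc classification, and the reduction
machinery applies them to intermediate graphs that are not yet networks.
Only `is_tstc` insists on the network axioms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Tuple

import networkx as nx

from .core import (
    HYBRIDIZATION_ARC,
    TREE_ARC,
    Arc,
    Diagnostic,
    SRDAG,
    validate_network,
)

__all__ = [
    "StarGraph",
    "TemporalAssignment",
    "TimeConsistencyVerdict",
    "TreeSiblingResult",
    "TSTCReport",
    "star_graph",
    "is_tree_sibling",
    "time_consistency",
    "time_consistency_quotient",
    "verify_temporal_assignment",
    "is_tstc",
]


@dataclass(frozen=True)
class StarGraph:
    """N* = (V, E ∪ {(v,u) | (u,v) a hybridization arc}), kinds annotated."""

    base: SRDAG
    star_arcs: Tuple[Arc, ...]
    #: kind of each *original* arc of the base network
    arc_kinds: Mapping[Arc, str]

    @property
    def digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.base.nodes)
        g.add_edges_from(self.star_arcs)
        return g


TemporalAssignment = Dict[str, int]


@dataclass(frozen=True)
class TimeConsistencyVerdict:
    """Outcome of the time-consistency decision.

    Exactly one of ``witness`` (a valid temporal assignment) and
    ``violation`` (a directed cycle of N*, as a node sequence, containing at
    least one tree arc) is present.
    """

    consistent: bool
    witness: Optional[TemporalAssignment] = None
    violation: Optional[Tuple[str, ...]] = None

    def __post_init__(self):
        assert (self.witness is None) != (self.violation is None)


@dataclass(frozen=True)
class TreeSiblingResult:
    ok: bool
    violators: Tuple[str, ...] = ()


def star_graph(N: SRDAG) -> StarGraph:
    """Build N*: the network plus the reversal of every hybridization arc."""
    g = N.graph
    kinds = {a: g.arc_kind(*a) for a in g.arcs}
    star = set(g.arcs)
    for (u, v), kind in kinds.items():
        if kind == HYBRIDIZATION_ARC:
            star.add((v, u))
    return StarGraph(base=N, star_arcs=tuple(sorted(star)), arc_kinds=kinds)


def is_tree_sibling(N: SRDAG) -> TreeSiblingResult:
    """Does every hybrid node share a parent with at least one tree node?

    The sibling must be a node other than the hybrid itself and of tree type
    (in-degree <= 1). Hybrid-free graphs pass vacuously.
    """
    g = N.graph
    violators = []
    for h in sorted(g.nodes):
        if not g.is_hybrid(h):
            continue
        has_tree_sibling = any(
            c != h and g.is_tree_node(c)
            for p in g.parents(h)
            for c in g.children(p)
        )
        if not has_tree_sibling:
            violators.append(h)
    return TreeSiblingResult(ok=not violators, violators=tuple(violators))


def _cycle_through_arc(star: nx.DiGraph, scc: frozenset, u: str, v: str) -> Tuple[str, ...]:
    """Shortest cycle of N* through the arc (u, v), found by BFS inside its SCC."""
    sub = star.subgraph(scc)
    path = nx.shortest_path(sub, v, u)  # v -> ... -> u; arc (u, v) closes it
    cycle = tuple([u] + path[:-1])
    # rotate so the lexicographically smallest node starts (determinism)
    i = cycle.index(min(cycle))
    return cycle[i:] + cycle[:i]


def time_consistency(N: SRDAG) -> TimeConsistencyVerdict:
    """Decide time consistency; return a witness or a violating cycle.

    Inconsistent iff some tree arc has both endpoints in one strongly
    connected component of N*. When consistent, the witness assigns each
    component 1 + the maximum over its tree-arc predecessors (source
    components get 1); every node inherits its component's value. The
    witness is re-verified before being returned.
    """
    sg = star_graph(N)
    star = sg.digraph
    comp_of: Dict[str, int] = {}
    comps: List[frozenset] = []
    for i, comp in enumerate(nx.strongly_connected_components(star)):
        comps.append(frozenset(comp))
        for v in comp:
            comp_of[v] = i

    tree_arcs = sorted(a for a, k in sg.arc_kinds.items() if k == TREE_ARC)
    for u, v in tree_arcs:
        if comp_of[u] == comp_of[v]:
            cycle = _cycle_through_arc(star, comps[comp_of[u]], u, v)
            return TimeConsistencyVerdict(consistent=False, violation=cycle)

    # condensation DAG; all inter-component arcs are tree arcs here
    cond = nx.DiGraph()
    cond.add_nodes_from(range(len(comps)))
    for u, v in tree_arcs:
        if comp_of[u] != comp_of[v]:
            cond.add_edge(comp_of[u], comp_of[v])
    level: Dict[int, int] = {}
    for c in nx.topological_sort(cond):
        preds = list(cond.predecessors(c))
        level[c] = 1 if not preds else 1 + max(level[p] for p in preds)
    tau = {v: level[comp_of[v]] for v in N.nodes}
    ok, violated = verify_temporal_assignment(N, tau)
    assert ok, f"internal error: witness invalid on arcs {violated}"
    return TimeConsistencyVerdict(consistent=True, witness=tau)


def time_consistency_quotient(N: SRDAG) -> bool:
    """Independent time-consistency oracle via hybridization clusters.

    Cluster the nodes by the connected components of the *undirected* graph
    whose edges are the hybridization arcs. N is time consistent iff no tree
    arc joins two nodes of one cluster and the cluster quotient under tree
    arcs is acyclic.
    """
    g = N.graph
    und = nx.Graph()
    und.add_nodes_from(g.nodes)
    tree_arcs = []
    for u, v in g.arcs:
        if g.arc_kind(u, v) == HYBRIDIZATION_ARC:
            und.add_edge(u, v)
        else:
            tree_arcs.append((u, v))
    cluster_of: Dict[str, int] = {}
    for i, comp in enumerate(nx.connected_components(und)):
        for v in comp:
            cluster_of[v] = i
    quotient = nx.DiGraph()
    quotient.add_nodes_from(set(cluster_of.values()))
    for u, v in tree_arcs:
        if cluster_of[u] == cluster_of[v]:
            return False
        quotient.add_edge(cluster_of[u], cluster_of[v])
    return nx.is_directed_acyclic_graph(quotient)


def verify_temporal_assignment(
    N: SRDAG, tau: Mapping[str, int]
) -> Tuple[bool, Tuple[Tuple[Arc, str], ...]]:
    """Check tau against both arc conditions; list every violated arc.

    Returns ``(ok, violations)`` where each violation pairs the arc with the
    failing inequality. Raises ``ValueError`` if tau is not total on the
    nodes or not positive-integer valued.
    """
    missing = sorted(set(N.nodes) - set(tau))
    if missing:
        raise ValueError("partial assignment: missing nodes " + ", ".join(missing))
    bad_vals = sorted(v for v in N.nodes if not (isinstance(tau[v], int) and tau[v] >= 1))
    if bad_vals:
        raise ValueError("non-positive-integer times at " + ", ".join(bad_vals))
    g = N.graph
    violations = []
    for u, v in sorted(g.arcs):
        if g.arc_kind(u, v) == HYBRIDIZATION_ARC:
            if tau[u] != tau[v]:
                violations.append(((u, v), f"tau({u})={tau[u]} != tau({v})={tau[v]}"))
        else:
            if not tau[u] < tau[v]:
                violations.append(((u, v), f"tau({u})={tau[u]} !< tau({v})={tau[v]}"))
    return (not violations, tuple(violations))


@dataclass(frozen=True)
class TSTCReport:
    """Conjunction of the three TSTC requirements, with sub-reports."""

    ok: bool
    network_diagnostics: Tuple[Diagnostic, ...]
    tree_sibling: TreeSiblingResult
    time_consistency: TimeConsistencyVerdict


def is_tstc(N: SRDAG) -> TSTCReport:
    """Is N a tree-sibling time-consistent phylogenetic network?

    Checks, in order: the network axioms (via
    :func:`~tstcnet.core.validate_network` at level ``phylogenetic_network``),
    the tree-sibling property, and time consistency. All three sub-reports
    are returned regardless of the verdict.
    """
    diags = validate_network(N, level="phylogenetic_network")
    ts = is_tree_sibling(N)
    tc = time_consistency(N)
    return TSTCReport(
        ok=not diags and ts.ok and tc.consistent,
        network_diagnostics=diags,
        tree_sibling=ts,
        time_consistency=tc,
    )
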