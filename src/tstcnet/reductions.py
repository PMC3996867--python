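"""Constructive polynomial reductions between graph classes, with inverses.

Three reductions chain general rooted-DAG isomorphism down to isomorphism of
tree-sibling time-consistent (TSTC) phylogenetic networks:

* ``srdag_to_rdag``  — leaf-labeled to unlabeled: a leaf whose label has
  rank k (labels rank-ordered to 1..n) receives k fresh leaf children and
  loses its label, so label identity is encoded in pure structure.
* ``rdag_to_srdag``  — unlabeled to leaf-labeled: a single fresh sink below
  every leaf, labeled "1".
* ``srdag_to_tstc``  — leaf-labeled rDAG to TSTC network over two extra
  labels, via the six-step construction (detach hybrid children behind a
  fresh tree node u_h, subdivide hybridization arcs with v_e nodes, give
  every elementary node of the intermediate graph a pendant child v', hang
  two fresh hybrid nodes a and b below all the v' and below a subdivision
  point w_m above the largest-labeled leaf, and finish with two fresh
  labeled leaves under a and b).

Each forward map records a :class:`ConstructionTrace` — the roles assigned
to every created node — so that inversion is exact and auditable rather than
pattern-guessed. All reductions preserve isomorphism in both directions and
each inverse composed with its forward map is the identity on construction
images.

``injective_to_bijective`` lifts injectively-labeled networks to bijectively
labeled ones by padding the root with leaf children for the unused labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, Tuple

from .core import (
    Arc,
    RootedDAG,
    SRDAG,
    classify,
    label_sort_key,
    rank_labels,
)
from .properties import is_tstc

__all__ = [
    "ConstructionTrace",
    "NotConstructionImage",
    "srdag_to_rdag",
    "invert_srdag_to_rdag",
    "rdag_to_srdag",
    "invert_rdag_to_srdag",
    "srdag_to_tstc",
    "invert_srdag_to_tstc",
    "injective_to_bijective",
]

ROLE_U_H = "u_h"
ROLE_V_E = "v_e"
ROLE_V_PRIME = "v_prime"
ROLE_W_M = "w_m"
ROLE_A = "a"
ROLE_B = "b"
ROLE_PAD_LEAF = "pad_leaf"
ROLE_RANK_LEAF = "rank_leaf"
ROLE_SINK = "sink"


class NotConstructionImage(ValueError):
    """The supplied graph/trace pair is not an image of the claimed reduction."""


@dataclass
class ConstructionTrace:
    """Audit record of a reduction: which fresh node plays which role.

    ``role_map`` covers exactly the nodes present in the output but absent
    from the input; ``source_of`` ties each fresh node back to the original
    node or arc it was created for; ``new_labels`` and ``m_label`` record the
    label bookkeeping of the TSTC construction so inversion never guesses.
    """

    kind: str
    role_map: Dict[str, str] = field(default_factory=dict)
    source_of: Dict[str, str] = field(default_factory=dict)
    new_labels: Tuple[str, ...] = ()
    m_label: Optional[str] = None
    data: Dict[str, object] = field(default_factory=dict)

    def nodes_with_role(self, role: str) -> Tuple[str, ...]:
        return tuple(sorted(v for v, r in self.role_map.items() if r == role))

    # -- JSON round trip (used by the CLI) -------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "role_map": self.role_map,
                "source_of": self.source_of,
                "new_labels": list(self.new_labels),
                "m_label": self.m_label,
                "data": self.data,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "ConstructionTrace":
        d = json.loads(text)
        return cls(
            kind=d["kind"],
            role_map=dict(d["role_map"]),
            source_of=dict(d["source_of"]),
            new_labels=tuple(d["new_labels"]),
            m_label=d["m_label"],
            data=dict(d.get("data", {})),
        )


def _fresh(base: str, used: Set[str]) -> str:
    cand = base
    k = 1
    while cand in used:
        k += 1
        cand = f"{base}~{k}"
    used.add(cand)
    return cand


def _two_fresh_labels(existing: Iterable[str]) -> Tuple[str, str]:
    """The two smallest decimal strings (under the label order) not in use."""
    existing = set(existing)
    out: List[str] = []
    i = 1
    while len(out) < 2:
        if str(i) not in existing:
            out.append(str(i))
        i += 1
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Leaf-labeled -> unlabeled (rank-k leaf gets k pendant leaves)
# ---------------------------------------------------------------------------

def srdag_to_rdag(G: SRDAG) -> Tuple[RootedDAG, ConstructionTrace]:
    """Encode leaf labels structurally: the rank-k leaf gets k fresh leaf children."""
    ranks = rank_labels(G.labels)
    used = set(G.nodes)
    arcs = set(G.arcs)
    trace = ConstructionTrace(kind="srdag_to_rdag", data={"former_labels": dict(G.labeling)})
    for leaf in sorted(G.labeling):
        k = ranks[G.labeling[leaf]]
        for i in range(1, k + 1):
            child = _fresh(f"rank:{leaf}:{i}", used)
            arcs.add((leaf, child))
            trace.role_map[child] = ROLE_RANK_LEAF
            trace.source_of[child] = leaf
    return RootedDAG(used, arcs), trace


def invert_srdag_to_rdag(Gp: RootedDAG, trace: ConstructionTrace) -> SRDAG:
    """Strip the pendant rank-encoding leaves and restore the recorded labels."""
    if trace.kind != "srdag_to_rdag":
        raise NotConstructionImage(f"trace kind {trace.kind!r} does not match")
    added = set(trace.role_map)
    former_labels = dict(trace.data.get("former_labels", {}))  # type: ignore[arg-type]
    for v, role in trace.role_map.items():
        if role != ROLE_RANK_LEAF:
            raise NotConstructionImage(f"unexpected role {role!r} for node {v!r}")
        if v not in Gp.nodes:
            raise NotConstructionImage(f"traced node {v!r} absent from graph")
        if Gp.out_degree(v) != 0 or Gp.parents(v) != (trace.source_of[v],):
            raise NotConstructionImage(f"node {v!r} is not a pendant child of its source")
    ranks = rank_labels(former_labels.values())
    for leaf, lab in former_labels.items():
        kids = [c for c in Gp.children(leaf) if c in added]
        if len(kids) != ranks[lab] or set(Gp.children(leaf)) != set(kids):
            raise NotConstructionImage(f"node {leaf!r} does not carry rank {ranks[lab]}")
    nodes = set(Gp.nodes) - added
    arcs = {(u, v) for u, v in Gp.arcs if v not in added}
    return SRDAG(RootedDAG(nodes, arcs), former_labels)


# ---------------------------------------------------------------------------
# Unlabeled -> leaf-labeled (single labeled sink below every leaf)
# ---------------------------------------------------------------------------

def rdag_to_srdag(G: RootedDAG) -> Tuple[SRDAG, ConstructionTrace]:
    """Add one fresh node below every leaf and label it "1"."""
    used = set(G.nodes)
    sink = _fresh("sink:a", used)
    arcs = set(G.arcs) | {(leaf, sink) for leaf in G.leaves}
    trace = ConstructionTrace(kind="rdag_to_srdag")
    trace.role_map[sink] = ROLE_SINK
    trace.source_of[sink] = G.root
    return SRDAG(RootedDAG(used, arcs), {sink: "1"}), trace


def invert_rdag_to_srdag(Gpp: SRDAG) -> RootedDAG:
    """Remove the unique leaf (and arcs into it) of a single-sink image."""
    leaves = Gpp.leaves
    if len(leaves) != 1:
        raise NotConstructionImage(f"expected exactly one leaf, found {len(leaves)}")
    sink = leaves[0]
    nodes = set(Gpp.nodes) - {sink}
    if not nodes:
        raise NotConstructionImage("removing the leaf would empty the graph")
    arcs = {(u, v) for u, v in Gpp.arcs if v != sink}
    return RootedDAG(nodes, arcs)


# ---------------------------------------------------------------------------
# Leaf-labeled rDAG -> TSTC network (the six-step construction)
# ---------------------------------------------------------------------------

class _Mut:
    """Tiny mutable digraph for the constructions."""

    def __init__(self, G: SRDAG):
        self.nodes: Set[str] = set(G.nodes)
        self.succ: Dict[str, Set[str]] = {v: set() for v in self.nodes}
        self.pred: Dict[str, Set[str]] = {v: set() for v in self.nodes}
        for u, v in G.arcs:
            self.succ[u].add(v)
            self.pred[v].add(u)
        self.labeling: Dict[str, str] = dict(G.labeling)

    def add_node(self, v: str) -> None:
        self.nodes.add(v)
        self.succ.setdefault(v, set())
        self.pred.setdefault(v, set())

    def add_arc(self, u: str, v: str) -> None:
        self.succ[u].add(v)
        self.pred[v].add(u)

    def remove_arc(self, u: str, v: str) -> None:
        self.succ[u].discard(v)
        self.pred[v].discard(u)

    def remove_node(self, v: str) -> None:
        for u in list(self.pred[v]):
            self.remove_arc(u, v)
        for w in list(self.succ[v]):
            self.remove_arc(v, w)
        self.nodes.discard(v)
        del self.succ[v], self.pred[v]
        self.labeling.pop(v, None)

    def hybrids(self) -> List[str]:
        return sorted(v for v in self.nodes if len(self.pred[v]) > 1)

    def elementary(self) -> List[str]:
        return sorted(
            v for v in self.nodes if len(self.pred[v]) <= 1 and len(self.succ[v]) == 1
        )

    def arcs(self) -> Set[Arc]:
        return {(u, v) for u in self.nodes for v in self.succ[u]}

    def to_srdag(self, *, strict: bool = True) -> SRDAG:
        return SRDAG(RootedDAG(self.nodes, self.arcs()), self.labeling, strict=strict)


def srdag_to_tstc(N: SRDAG) -> Tuple[SRDAG, ConstructionTrace]:
    """Turn any S-rDAG into a TSTC network over S plus two extra labels.

    A phylogenetic tree (no hybrid and no elementary node) is already TSTC
    and passes through unchanged with an empty trace. Otherwise the six
    steps run in order; the output is asserted to satisfy ``is_tstc`` and to
    carry exactly labels(N) plus the two fresh labels recorded in the trace.
    """
    cls = classify(N.graph)
    has_hybrid = any(c.is_hybrid for c in cls.nodes.values())
    has_elem = any(c.is_elementary for c in cls.nodes.values())
    if not has_hybrid and not has_elem:
        return N, ConstructionTrace(kind="srdag_to_tstc")

    g = _Mut(N)
    used = set(g.nodes)
    trace = ConstructionTrace(kind="srdag_to_tstc")

    # (1) detach each hybrid's children behind a fresh tree node u_h,
    #     which inherits the label when the hybrid was a labeled leaf
    for h in g.hybrids():
        children = sorted(g.succ[h])
        u_h = _fresh(f"uh:{h}", used)
        g.add_node(u_h)
        for c in children:
            g.remove_arc(h, c)
            g.add_arc(u_h, c)
        g.add_arc(h, u_h)
        if h in g.labeling:
            g.labeling[u_h] = g.labeling.pop(h)
        trace.role_map[u_h] = ROLE_U_H
        trace.source_of[u_h] = h

    # (2) subdivide every hybridization arc with a fresh tree node v_e
    hyb_arcs = sorted(
        (u, v) for v in g.hybrids() for u in g.pred[v]
    )
    for u, h in hyb_arcs:
        v_e = _fresh(f"ve:{u}:{h}", used)
        g.add_node(v_e)
        g.remove_arc(u, h)
        g.add_arc(u, v_e)
        g.add_arc(v_e, h)
        trace.role_map[v_e] = ROLE_V_E
        trace.source_of[v_e] = f"{u}->{h}"

    # (3) pendant child v' for every elementary node of the intermediate graph
    #     (this includes every v_e, and any u_h whose hybrid had one child)
    for v in g.elementary():
        v_p = _fresh(f"vp:{v}", used)
        g.add_node(v_p)
        g.add_arc(v, v_p)
        trace.role_map[v_p] = ROLE_V_PRIME
        trace.source_of[v_p] = v

    # (4) subdivide the arc into the largest-labeled leaf m
    m_label = max(g.labeling.values(), key=label_sort_key)
    leaf_m = next(v for v, lab in g.labeling.items() if lab == m_label)
    parents_m = sorted(g.pred[leaf_m])
    assert len(parents_m) == 1, "leaf m must have a unique parent after step (1)"
    w = parents_m[0]
    w_m = _fresh(f"wm:{leaf_m}", used)
    g.add_node(w_m)
    g.remove_arc(w, leaf_m)
    g.add_arc(w, w_m)
    g.add_arc(w_m, leaf_m)
    trace.role_map[w_m] = ROLE_W_M
    trace.source_of[w_m] = leaf_m
    trace.m_label = m_label

    # (5) fresh hybrid nodes a, b below every v' and below w_m
    a = _fresh("a", used)
    b = _fresh("b", used)
    g.add_node(a)
    g.add_node(b)
    for v_p in trace.nodes_with_role(ROLE_V_PRIME):
        g.add_arc(v_p, a)
        g.add_arc(v_p, b)
    g.add_arc(w_m, a)
    g.add_arc(w_m, b)
    trace.role_map[a] = ROLE_A
    trace.role_map[b] = ROLE_B
    trace.source_of[a] = trace.source_of[b] = w_m

    # (6) fresh labeled leaves under a and b
    lab1, lab2 = _two_fresh_labels(N.labels)
    leaf_a = _fresh(f"leaf:{lab1}", used)
    leaf_b = _fresh(f"leaf:{lab2}", used)
    g.add_node(leaf_a)
    g.add_node(leaf_b)
    g.add_arc(a, leaf_a)
    g.add_arc(b, leaf_b)
    g.labeling[leaf_a] = lab1
    g.labeling[leaf_b] = lab2
    trace.role_map[leaf_a] = trace.role_map[leaf_b] = ROLE_PAD_LEAF
    trace.source_of[leaf_a] = a
    trace.source_of[leaf_b] = b
    trace.new_labels = (lab1, lab2)

    out = g.to_srdag()
    report = is_tstc(out)
    assert report.ok, f"construction output is not TSTC: {report}"
    assert out.labels == N.labels | {lab1, lab2}, "label-set growth must be the two fresh labels"
    return out, trace


def invert_srdag_to_tstc(M: SRDAG, trace: ConstructionTrace) -> SRDAG:
    """Undo the six-step construction on a traced image (five inverse steps)."""
    if trace.kind != "srdag_to_tstc":
        raise NotConstructionImage(f"trace kind {trace.kind!r} does not match")
    if not trace.role_map:  # phylogenetic tree: passed through unchanged
        return M
    missing = sorted(set(trace.role_map) - set(M.nodes))
    if missing:
        raise NotConstructionImage("traced nodes absent from graph: " + ", ".join(missing))

    g = _Mut(M)

    # (i) drop the two fresh leaves and their hybrid parents a, b
    for role in (ROLE_PAD_LEAF, ROLE_A, ROLE_B):
        for v in trace.nodes_with_role(role):
            g.remove_node(v)

    # (ii) contract the elementary parent w_m of the largest-labeled leaf
    (w_m,) = trace.nodes_with_role(ROLE_W_M)
    if len(g.succ[w_m]) != 1 or len(g.pred[w_m]) != 1:
        raise NotConstructionImage(f"{w_m!r} is not an elementary subdivision point")
    (leaf_m,) = g.succ[w_m]
    if g.labeling.get(leaf_m) != trace.m_label:
        raise NotConstructionImage(f"child of {w_m!r} does not carry label {trace.m_label!r}")
    (parent,) = g.pred[w_m]
    g.remove_node(w_m)
    g.add_arc(parent, leaf_m)

    # (iii) remove all unlabeled leaves (single pass: the v' nodes)
    v_primes = set(trace.nodes_with_role(ROLE_V_PRIME))
    unlabeled = {v for v in g.nodes if not g.succ[v] and v not in g.labeling}
    if unlabeled != v_primes:
        raise NotConstructionImage("unlabeled leaves do not match the traced v' nodes")
    for v in sorted(unlabeled):
        g.remove_node(v)
    assert all(g.succ[v] or v in g.labeling for v in g.nodes), "unlabeled leaf survived"

    # (iv) contract every v_e parent of a hybrid node
    v_es = set(trace.nodes_with_role(ROLE_V_E))
    for h in g.hybrids():
        for v_e in sorted(g.pred[h]):
            if v_e not in v_es:
                raise NotConstructionImage(f"hybrid parent {v_e!r} is not a traced v_e")
            (p,) = g.pred[v_e]
            g.remove_node(v_e)
            g.add_arc(p, h)

    # (v) remove each hybrid's single tree child u_h, reattaching its
    #     children and transferring a leaf label back onto the hybrid
    u_hs = set(trace.nodes_with_role(ROLE_U_H))
    for h in g.hybrids():
        if len(g.succ[h]) != 1:
            raise NotConstructionImage(f"hybrid {h!r} has out-degree != 1")
        (u_h,) = g.succ[h]
        if u_h not in u_hs:
            raise NotConstructionImage(f"child {u_h!r} of hybrid {h!r} is not a traced u_h")
        children = sorted(g.succ[u_h])
        label = g.labeling.get(u_h)
        g.remove_node(u_h)
        for c in children:
            g.add_arc(h, c)
        if label is not None:
            g.labeling[h] = label
    return g.to_srdag()


# ---------------------------------------------------------------------------
# Injective -> bijective labeling lift
# ---------------------------------------------------------------------------

def injective_to_bijective(N: SRDAG, S: Iterable[str]) -> SRDAG:
    """Pad the root with leaf children for the labels of S not used by N.

    Leaves end up bijectively labeled on S. The padding leaves are tree
    children of the root, so tree-sibling and time consistency are
    unaffected; if the whole network is a single labeled leaf, its label
    moves onto a pendant child as well so no label is lost.
    """
    S = set(S)
    outside = sorted(N.labels - S, key=label_sort_key)
    if outside:
        raise ValueError("label outside target set: " + ", ".join(outside))
    missing = sorted(S - N.labels, key=label_sort_key)
    if not missing:
        return N
    g = _Mut(N)
    used = set(g.nodes)
    root = N.root
    if root in g.labeling:  # single-node network: keep its label on a leaf
        missing.append(g.labeling.pop(root))
        missing.sort(key=label_sort_key)
    for lab in missing:
        leaf = _fresh(f"pad:{lab}", used)
        g.add_node(leaf)
        g.add_arc(root, leaf)
        g.labeling[leaf] = lab
    return g.to_srdag()
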