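"""Exact isomorphism for leaf-labeled rooted DAGs.

An isomorphism of S-rDAGs is a digraph isomorphism that preserves and
reflects the leaf labeling: each labeled leaf must map to the leaf carrying
the same label. Internal nodes are unlabeled and interchangeable; their
tree/hybrid type needs no explicit color because in/out-degrees already
refine it.

The decision is exact (no heuristic false answers):

1. fast rejection on isomorphism-invariant multisets (node and arc counts,
   label sets, and the multiset of (label, in-degree, out-degree, height,
   depth) node invariants);
2. iterative partition refinement seeded by those invariants (1-dimensional
   Weisfeiler-Leman on the ordered partition);
3. backtracking individualization over the refined cells, producing a
   *canonical form* — the minimum adjacency certificate over all
   refinement-consistent orderings. Two graphs are isomorphic iff their
   canonical certificates coincide, and the two canonical orderings compose
   into a witness bijection, which is re-verified arc by arc before return.

The same search yields :func:`canonical_key`, a byte string equal for two
graphs iff they are isomorphic (used to deduplicate enumeration). The search
is exponential in the worst case but fast on the near-rigid graphs this
package manipulates; interchangeable "false twin" vertices (equal parent and
child sets) are collapsed to a single branch, which keeps the constructions'
bundles of identical leaves linear instead of factorial.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .core import RootedDAG, SRDAG, classify

__all__ = ["IsomorphismResult", "isomorphic", "canonical_key", "verify_witness"]


@dataclass(frozen=True)
class IsomorphismResult:
    isomorphic: bool
    #: node(G1) -> node(G2) bijection, present iff isomorphic
    witness: Optional[Dict[str, str]]
    reason: str = ""

    def __bool__(self) -> bool:
        return self.isomorphic


GraphLike = Union[SRDAG, RootedDAG]


def _coerce(G: GraphLike) -> SRDAG:
    if isinstance(G, RootedDAG):
        return SRDAG(G, {}, strict=False)
    return G


class _Structure:
    """Index-based view of an SRDAG with invariant initial colors."""

    __slots__ = ("nodes", "n", "preds", "succs", "init_raw", "init_rank")

    def __init__(self, G: SRDAG):
        self.nodes: List[str] = sorted(G.nodes)
        idx = {v: i for i, v in enumerate(self.nodes)}
        self.n = len(self.nodes)
        self.preds: List[Tuple[int, ...]] = [()] * self.n
        self.succs: List[Tuple[int, ...]] = [()] * self.n
        pre: List[List[int]] = [[] for _ in range(self.n)]
        suc: List[List[int]] = [[] for _ in range(self.n)]
        for u, v in G.arcs:
            suc[idx[u]].append(idx[v])
            pre[idx[v]].append(idx[u])
        self.preds = [tuple(sorted(p)) for p in pre]
        self.succs = [tuple(sorted(s)) for s in suc]
        cls = classify(G.graph)
        self.init_raw: List[tuple] = []
        for v in self.nodes:
            c = cls.nodes[v]
            lab = G.label_of(v)
            self.init_raw.append(
                ("" if lab is None else lab, c.in_degree, c.out_degree, c.height, c.depth)
            )
        rank = {t: i for i, t in enumerate(sorted(set(self.init_raw)))}
        self.init_rank: List[int] = [rank[t] for t in self.init_raw]


def _refine(st: _Structure, colors: Sequence[int]) -> List[int]:
    """Iterate neighborhood-signature splitting until the partition is stable.

    New colors are ranks of sorted signatures whose first component is the
    old color, so refinement only ever splits cells and keeps their relative
    order — the resulting cell order is isomorphism-invariant.
    """
    colors = list(colors)
    n_colors = len(set(colors))
    while True:
        sigs = [
            (
                colors[v],
                tuple(sorted(colors[u] for u in st.preds[v])),
                tuple(sorted(colors[w] for w in st.succs[v])),
            )
            for v in range(st.n)
        ]
        rank = {s: i for i, s in enumerate(sorted(set(sigs)))}
        new = [rank[s] for s in sigs]
        if len(rank) == n_colors:
            return new
        colors, n_colors = new, len(rank)


def _adjacency_cert(st: _Structure, order: Sequence[int]) -> Tuple[int, ...]:
    pos = {v: i for i, v in enumerate(order)}
    rows = []
    for v in order:
        row = 0
        for w in st.succs[v]:
            row |= 1 << pos[w]
        rows.append(row)
    return tuple(rows)


def _canonical(st: _Structure) -> Tuple[tuple, List[int]]:
    """Canonical certificate and ordering by individualization-refinement."""
    best: List[Optional[Tuple[Tuple[int, ...], List[int]]]] = [None]

    def search(colors: List[int]) -> None:
        cells: Dict[int, List[int]] = {}
        for v in range(st.n):
            cells.setdefault(colors[v], []).append(v)
        target = None
        for c in sorted(cells):
            if len(cells[c]) > 1:
                target = cells[c]
                break
        if target is None:
            order = sorted(range(st.n), key=lambda v: colors[v])
            cert = _adjacency_cert(st, order)
            if best[0] is None or cert < best[0][0]:
                best[0] = (cert, order)
            return
        # false twins (equal parent/child sets) are automorphic: branch once
        seen = set()
        for v in sorted(target):
            key = (st.preds[v], st.succs[v])
            if key in seen:
                continue
            seen.add(key)
            indiv = [(colors[u], 0 if u == v else 1) for u in range(st.n)]
            rank = {t: i for i, t in enumerate(sorted(set(indiv)))}
            search(_refine(st, [rank[t] for t in indiv]))

    search(_refine(st, st.init_rank))
    assert best[0] is not None
    cert_adj, order = best[0]
    full_cert = (st.n, tuple(st.init_raw[v] for v in order), cert_adj)
    return full_cert, order


@lru_cache(maxsize=8192)
def _canonical_cached(G: SRDAG) -> Tuple[tuple, Tuple[str, ...]]:
    st = _Structure(G)
    cert, order = _canonical(st)
    return cert, tuple(st.nodes[i] for i in order)


def canonical_key(G: GraphLike) -> bytes:
    """A byte string with ``key(G1) == key(G2)`` iff G1 and G2 are isomorphic."""
    cert, _ = _canonical_cached(_coerce(G))
    return repr(cert).encode()


def verify_witness(G1: GraphLike, G2: GraphLike, mapping: Dict[str, str]) -> bool:
    """Independent arc-by-arc check that ``mapping`` is a label-preserving isomorphism."""
    G1, G2 = _coerce(G1), _coerce(G2)
    if set(mapping) != set(G1.nodes) or set(mapping.values()) != set(G2.nodes):
        return False
    if len(set(mapping.values())) != len(mapping):
        return False
    mapped = {(mapping[u], mapping[v]) for u, v in G1.arcs}
    if mapped != set(G2.arcs):
        return False
    if {mapping[v]: lab for v, lab in G1.labeling.items()} != G2.labeling:
        return False
    return True


def isomorphic(G1: GraphLike, G2: GraphLike) -> IsomorphismResult:
    """Exact isomorphism decision with a verified witness when true."""
    G1, G2 = _coerce(G1), _coerce(G2)
    if len(G1.nodes) != len(G2.nodes):
        return IsomorphismResult(False, None, "node counts differ")
    if len(G1.arcs) != len(G2.arcs):
        return IsomorphismResult(False, None, "arc counts differ")
    if G1.labels != G2.labels:
        return IsomorphismResult(False, None, "label sets differ")
    st1, st2 = _Structure(G1), _Structure(G2)
    if sorted(st1.init_raw) != sorted(st2.init_raw):
        return IsomorphismResult(False, None, "node invariant multisets differ")
    cert1, order1 = _canonical_cached(G1)
    cert2, order2 = _canonical_cached(G2)
    if cert1 != cert2:
        return IsomorphismResult(False, None, "canonical certificates differ")
    witness = dict(zip(order1, order2))
    assert verify_witness(G1, G2, witness), "internal error: unverified witness"
    return IsomorphismResult(True, witness, "canonical certificates agree")
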