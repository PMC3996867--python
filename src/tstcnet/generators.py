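"""Synthetic instance generation: seeded random S-rDAGs, isomorphic and
non-isomorphic variant pairs, and bounded exhaustive enumeration of
isomorphism classes.

The enumeration walks all binary strictly-upper-triangular adjacency
matrices on k ordered nodes (every DAG admits such a representation under
some topological order, so every isomorphism class is covered), keeps the
rooted ones, attaches every injective assignment of the requested labels
onto the leaves, applies the property filter, and deduplicates with
:func:`~tstcnet.isomorphism.canonical_key`. With node 0 forced to be the
unique root, a matrix is a valid rDAG exactly when every other column is
nonzero, so only those are generated; the property filters run on cheap
bit-level degree data before any graph object is built.

Everything is explicitly seeded; there is no global random state.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from itertools import permutations, product
from typing import Dict, Iterator, List, Sequence, Tuple

from .core import RootedDAG, SRDAG, InvalidGraphError
from .isomorphism import canonical_key, isomorphic
from .properties import time_consistency

__all__ = [
    "GeneratorConfig",
    "random_srdag",
    "variant_pair",
    "enumerate_classes",
    "enumerate_rdags",
]

MAX_ENUM_NODES = 7


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the random S-rDAG generator.

    ``n_nodes`` nodes are laid out in a random topological order; every
    non-root node gets one parent among its predecessors (guaranteeing
    rootedness and reachability) plus independent extra arcs with
    probability ``extra_arc_prob``; the graph is regenerated until it has
    exactly ``n_labels`` leaves, which are then labeled injectively with
    "1".."n_labels".
    """

    n_nodes: int
    n_labels: int
    extra_arc_prob: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 1 or self.n_labels < 1:
            raise ValueError("n_nodes and n_labels must be positive")
        if not 0.0 <= self.extra_arc_prob <= 1.0:
            raise ValueError("extra_arc_prob must lie in [0, 1]")
        if self.n_labels > self.n_nodes:
            raise ValueError("more labels than possible leaves")


_MAX_RETRIES = 1000


def random_srdag(cfg: GeneratorConfig) -> SRDAG:
    """Draw a seeded random S-rDAG; identical config implies identical output."""
    rng = random.Random(cfg.seed)
    names = [f"v{i}" for i in range(cfg.n_nodes)]
    for _ in range(_MAX_RETRIES):
        order = names[:]
        rng.shuffle(order)
        arcs = set()
        for i in range(1, cfg.n_nodes):
            arcs.add((order[rng.randrange(i)], order[i]))
        for i in range(cfg.n_nodes):
            for j in range(i + 1, cfg.n_nodes):
                if rng.random() < cfg.extra_arc_prob:
                    arcs.add((order[i], order[j]))
        g = RootedDAG(names, arcs)
        leaves = list(g.leaves)
        if len(leaves) != cfg.n_labels:
            continue
        labels = [str(r) for r in range(1, cfg.n_labels + 1)]
        rng.shuffle(labels)
        return SRDAG(g, dict(zip(leaves, labels)))
    raise ValueError(
        f"cannot realize leaf count {cfg.n_labels} with {cfg.n_nodes} nodes "
        f"(extra_arc_prob={cfg.extra_arc_prob}, seed={cfg.seed})"
    )


def variant_pair(G: SRDAG, mode: str, seed: int) -> SRDAG:
    """A companion graph for G: a renamed isomorphic copy, or a certified
    non-isomorphic perturbation (arc rewires / leaf-label swaps, rejected
    until ``isomorphic(G, candidate)`` is false)."""
    rng = random.Random(seed)
    if mode == "isomorphic":
        old = sorted(G.nodes)
        new = [f"w{i}" for i in range(len(old))]
        rng.shuffle(new)
        return G.relabel_nodes(dict(zip(old, new)))
    if mode != "nonisomorphic":
        raise ValueError(f"unknown mode {mode!r}")
    if len(G.arcs) < 2:
        raise ValueError("nonisomorphic mode needs a graph with at least 2 arcs")
    nodes = sorted(G.nodes)
    for attempt in range(500):
        arcs = set(G.arcs)
        labeling = dict(G.labeling)
        # size-preserving rewires first; for rigid graphs where none exists
        # (e.g. a fully labeled star), fall back to subdividing an arc
        op = rng.randrange(3) if attempt < 100 else rng.randrange(4)
        if op == 3:
            u, v = rng.choice(sorted(arcs))
            mid = f"sub{attempt}"
            arcs.discard((u, v))
            arcs.update([(u, mid), (mid, v)])
            try:
                cand = SRDAG.from_arcs(arcs, labeling, nodes=nodes + [mid])
            except InvalidGraphError:
                continue
            return cand  # node counts differ: never isomorphic
        if op == 0 and len(labeling) >= 2:  # swap two leaf labels
            a, bnode = rng.sample(sorted(labeling), 2)
            labeling[a], labeling[bnode] = labeling[bnode], labeling[a]
        elif op == 1:  # redirect an arc to a new parent
            u, v = rng.choice(sorted(arcs))
            u2 = rng.choice(nodes)
            arcs.discard((u, v))
            arcs.add((u2, v))
        else:  # add an extra arc
            u2, v2 = rng.sample(nodes, 2)
            arcs.add((u2, v2))
        try:
            cand = SRDAG.from_arcs(arcs, labeling, nodes=nodes)
        except InvalidGraphError:
            continue
        if not isomorphic(G, cand):
            return cand
    raise ValueError("no variant found")


# ---------------------------------------------------------------------------
# Exhaustive enumeration
# ---------------------------------------------------------------------------

def _structures(k: int) -> Iterator[Tuple[int, ...]]:
    """All rooted-DAG parent masks: cols[i-1] = parent set of node i (bits < i)."""
    if k == 1:
        yield ()
        return
    yield from product(*[range(1, 1 << i) for i in range(1, k)])


def _cols_to_rdag(k: int, cols: Sequence[int]) -> RootedDAG:
    arcs = []
    for i, mask in enumerate(cols, start=1):
        m = mask
        while m:
            p = (m & -m).bit_length() - 1
            arcs.append((f"n{p}", f"n{i}"))
            m &= m - 1
    return RootedDAG([f"n{j}" for j in range(k)], arcs)


def enumerate_rdags(max_nodes: int) -> Iterator[RootedDAG]:
    """Every rooted DAG on up to ``max_nodes`` nodes, one topological layout each.

    Not deduplicated by isomorphism; intended as raw material for oracle
    cross-checks and for :func:`enumerate_classes`.
    """
    if max_nodes > MAX_ENUM_NODES:
        raise ValueError(f"enumeration limited to {MAX_ENUM_NODES} nodes")
    for k in range(1, max_nodes + 1):
        for cols in _structures(k):
            yield _cols_to_rdag(k, cols)


def _passes_network_axioms(k: int, cols: Sequence[int]) -> bool:
    """Bit-level check of the two phylogenetic-network axioms."""
    child_mask = [0] * k
    indeg = [0] * k
    for i, mask in enumerate(cols, start=1):
        indeg[i] = mask.bit_count()
        m = mask
        while m:
            p = (m & -m).bit_length() - 1
            child_mask[p] |= 1 << i
            m &= m - 1
    for v in range(k):
        outd = child_mask[v].bit_count()
        if indeg[v] <= 1:
            if outd == 1:  # elementary tree node
                return False
        else:
            if outd != 1:
                return False
            c = child_mask[v].bit_length() - 1
            if indeg[c] > 1:  # hybrid child of hybrid
                return False
    return True


def _is_tree_sibling_cols(k: int, cols: Sequence[int]) -> bool:
    child_mask = [0] * k
    indeg = [0] * k
    parent_mask = [0] * k
    for i, mask in enumerate(cols, start=1):
        indeg[i] = mask.bit_count()
        parent_mask[i] = mask
        m = mask
        while m:
            p = (m & -m).bit_length() - 1
            child_mask[p] |= 1 << i
            m &= m - 1
    for h in range(k):
        if indeg[h] <= 1:
            continue
        found = False
        pm = parent_mask[h]
        while pm and not found:
            p = (pm & -pm).bit_length() - 1
            cm = child_mask[p] & ~(1 << h)
            while cm:
                c = (cm & -cm).bit_length() - 1
                if indeg[c] <= 1:
                    found = True
                    break
                cm &= cm - 1
            pm &= pm - 1
        if not found:
            return False
    return True


_FILTERS = ("srdag", "phylogenetic_network", "tstc")


def enumerate_classes(max_nodes: int, labels: Sequence[str], filter: str = "srdag") -> List[SRDAG]:
    """All isomorphism classes of leaf-labeled rooted DAGs up to ``max_nodes``
    nodes whose leaves are injectively labeled by exactly ``labels``, subject
    to a property filter, one canonical representative per class.

    ``filter``: "srdag" (no extra condition), "phylogenetic_network" (the two
    network axioms), or "tstc" (network axioms + tree-sibling + time
    consistency). Representatives are sorted by (node count, canonical key).
    """
    if max_nodes > MAX_ENUM_NODES:
        raise ValueError(f"enumeration limited to {MAX_ENUM_NODES} nodes")
    if filter not in _FILTERS:
        raise ValueError(f"filter must be one of {_FILTERS}")
    label_list = sorted(set(labels))
    if len(label_list) != len(list(labels)):
        raise ValueError("labels must be distinct")
    L = len(label_list)
    reps: Dict[bytes, SRDAG] = {}
    for k in range(1, max_nodes + 1):
        for cols in _structures(k):
            # leaf count from bit data, before building any graph object
            cm = [0] * k
            for i, mask in enumerate(cols, start=1):
                m = mask
                while m:
                    p = (m & -m).bit_length() - 1
                    cm[p] |= 1 << i
                    m &= m - 1
            leaves = [v for v in range(k) if cm[v] == 0]
            if len(leaves) != L:
                continue
            if filter in ("phylogenetic_network", "tstc"):
                if not _passes_network_axioms(k, cols):
                    continue
            if filter == "tstc" and not _is_tree_sibling_cols(k, cols):
                continue
            g = _cols_to_rdag(k, cols)
            if filter == "tstc":
                # time consistency ignores the labeling: check once
                probe = SRDAG(g, {}, strict=False)
                if not time_consistency(probe).consistent:
                    continue
            leaf_names = [f"n{v}" for v in leaves]
            for perm in permutations(label_list):
                cand = SRDAG(g, dict(zip(leaf_names, perm)))
                key = canonical_key(cand)
                if key not in reps:
                    reps[key] = cand
    return sorted(reps.values(), key=lambda s: (len(s.nodes), canonical_key(s)))
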