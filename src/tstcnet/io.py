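"""Readers and writers: the edge-list dialect and extended Newick.

The edge-list dialect covers every graph this package manipulates,
including mid-construction S-rDAGs with elementary nodes and unlabeled
leaves, which no Newick dialect can express::

    # comment
    r -> u
    r -> w
    u -> h
    w -> h
    label h = 1

One arc per line (``PARENT -> CHILD``), label lines (``label NODE =
LABEL``), ``#`` comments, blank lines ignored. A label line may introduce a
node only when the document has no arc lines (a single labeled node);
otherwise labeling an unknown node is an error. The writer is bit-exact:
arcs sorted lexicographically, label lines last, so read∘write is the
identity.

Extended Newick (eNewick) is offered for valid phylogenetic networks only:
each hybrid node is printed once in full, tagged ``#Hk``, and elsewhere as
the bare tag; children are ordered by a canonical subtree key so the writer
is deterministic, and read∘write yields an isomorphic network.
"""

from __future__ import annotations

import re
from typing import Dict, List, Tuple

from .core import (
    Diagnostic,
    InvalidGraphError,
    RootedDAG,
    SRDAG,
    validate_network,
)

__all__ = ["ParseError", "read_edgelist", "write_edgelist", "read_enewick", "write_enewick"]


class ParseError(ValueError):
    """A syntax or consistency error in an input document, with its line."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"{message} at line {line}")


_ARC_RE = re.compile(r"^(\S+)\s*->\s*(\S+)$")
_LABEL_RE = re.compile(r"^label\s+(\S+)\s*=\s*(\S+)$")


def read_edgelist(text: str) -> SRDAG:
    """Parse the edge-list dialect into a validated S-rDAG."""
    arcs: List[Tuple[str, str]] = []
    arc_set = set()
    labels: Dict[str, str] = {}
    label_lines: List[Tuple[str, str, int]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _LABEL_RE.match(line)
        if m:
            node, lab = m.groups()
            if node in labels:
                raise ParseError(f"node {node!r} labeled twice", lineno)
            if lab in labels.values():
                raise ParseError(f"duplicate label {lab!r}", lineno)
            labels[node] = lab
            label_lines.append((node, lab, lineno))
            continue
        m = _ARC_RE.match(line)
        if m:
            u, v = m.groups()
            if u == v:
                raise ParseError("self-arc", lineno)
            if (u, v) in arc_set:
                raise ParseError(f"duplicate arc {u} -> {v}", lineno)
            arc_set.add((u, v))
            arcs.append((u, v))
            continue
        raise ParseError(f"malformed line {line!r}", lineno)

    nodes = {u for a in arcs for u in a}
    if arcs:
        for node, _, lineno in label_lines:
            if node not in nodes:
                raise ParseError(f"unknown node {node!r} in label line", lineno)
    else:
        nodes = set(labels)  # a label line may declare a single-node graph
    if not nodes:
        raise InvalidGraphError([Diagnostic("empty graph", "document defines no nodes")])
    return SRDAG(RootedDAG(nodes, arcs), labels)


def write_edgelist(G: SRDAG) -> str:
    """Deterministic edge-list serialization (read∘write is the identity)."""
    lines = [f"{u} -> {v}" for u, v in sorted(G.arcs)]
    lines += [f"label {v} = {lab}" for v, lab in sorted(G.labeling.items())]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Extended Newick
# ---------------------------------------------------------------------------

def write_enewick(N: SRDAG) -> str:
    """Serialize a valid phylogenetic network as extended Newick."""
    diags = validate_network(N, level="phylogenetic_network")
    if diags:
        raise InvalidGraphError(diags)
    g = N.graph

    skey_memo: Dict[str, str] = {}

    def skey(v: str) -> str:
        if v not in skey_memo:
            kids = g.children(v)
            if not kids:
                skey_memo[v] = "L:" + (N.label_of(v) or "")
            else:
                skey_memo[v] = "(" + ",".join(sorted(skey(c) for c in kids)) + ")"
        return skey_memo[v]

    hybrid_tag: Dict[str, int] = {}

    def render(v: str) -> str:
        if g.is_hybrid(v):
            if v in hybrid_tag:
                return f"#H{hybrid_tag[v]}"
            hybrid_tag[v] = len(hybrid_tag) + 1
            tag = f"#H{hybrid_tag[v]}"
        else:
            tag = ""
        kids = sorted(g.children(v), key=lambda c: (skey(c), c))
        if not kids:
            return (N.label_of(v) or "") + tag
        return "(" + ",".join(render(c) for c in kids) + ")" + tag

    return render(g.root) + ";"


_ENEWICK_TOKEN = re.compile(r"\s*([(),;]|[^\s(),;]+)")


def read_enewick(text: str) -> SRDAG:
    """Parse extended Newick (with #Hk hybrid tags) into a phylogenetic network."""
    tokens = _ENEWICK_TOKEN.findall(text)
    if not tokens:
        raise ParseError("empty document")
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        if pos >= len(tokens):
            raise ParseError("unexpected end of input")
        pos += 1
        return tokens[pos - 1]

    def parse_node() -> Tuple[str, list]:
        children = []
        if peek() == "(":
            take()
            children.append(parse_node())
            while peek() == ",":
                take()
                children.append(parse_node())
            if peek() != ")":
                raise ParseError("unbalanced parentheses")
            take()
        name = ""
        if peek() not in ("(", ")", ",", ";", None):
            name = take()
        return (name, children)

    tree = parse_node()
    if take() != ";":
        raise ParseError("expected ';' at end")
    if pos != len(tokens):
        raise ParseError("trailing content after ';'")

    arcs: List[Tuple[str, str]] = []
    labeling: Dict[str, str] = {}
    tag_node: Dict[str, str] = {}
    tag_defined: Dict[str, bool] = {}
    counter = [0]

    def build(node: Tuple[str, list], parent: str | None) -> None:
        name, children = node
        label, tag = name, None
        if "#" in name:
            label, _, tagpart = name.partition("#")
            tag = tagpart
            if not tag:
                raise ParseError(f"malformed hybrid tag in {name!r}")
        if tag is not None:
            if tag not in tag_node:
                counter[0] += 1
                tag_node[tag] = f"e{counter[0]}"
                tag_defined[tag] = False
            vid = tag_node[tag]
            if children:
                tag_defined[tag] = True
        else:
            counter[0] += 1
            vid = f"e{counter[0]}"
        if parent is not None:
            arcs.append((parent, vid))
        if label:
            if vid in labeling and labeling[vid] != label:
                raise ParseError(f"conflicting labels for hybrid {name!r}")
            labeling[vid] = label
        for c in children:
            build(c, vid)

    build(tree, None)
    dangling = sorted(t for t, ok in tag_defined.items() if not ok)
    if dangling:
        raise ParseError("dangling hybrid tag(s): " + ", ".join("#" + t for t in dangling))
    nodes = {u for a in arcs for u in a} or {"e1"}
    net = SRDAG(RootedDAG(nodes, arcs), labeling)
    diags = validate_network(net, level="phylogenetic_network")
    if diags:
        raise InvalidGraphError(diags)
    return net
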