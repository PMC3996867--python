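# Methods

## Objects and conventions

A rooted DAG (`RootedDAG`) is required to have exactly one in-degree-0 node
*and* every node reachable from it. The second condition is what makes
heights and depths total and is implied by the first whenever the arc
relation is acyclic; we still check and report it separately so that inputs
with a disconnected cycle get both diagnostics. Inputs violating any
invariant are rejected with named diagnostics, never repaired.

Labels are arbitrary strings ordered by `(length, lexicographic)`. On
decimal strings this coincides with numeric order, so the conventional
taxon sets {1, …, n} behave as expected, while the order stays total on
any alphabet. "The largest label", "rank k", and "two fresh labels" are
all resolved through this order; the fresh labels are the two smallest
decimal strings not colliding with the input's labels and are recorded in
the construction trace, so inversion never guesses.

Node identifiers are opaque strings. Constructions mint fresh identifiers
with role-based prefixes (`uh:<hybrid>`, `ve:<tail>:<head>`, `vp:<node>`,
`wm:<leaf>`, `rank:<leaf>:<i>`, …), suffixed with `~k` on collision, which
makes traces readable and runs byte-for-byte reproducible.

## Time consistency

A temporal assignment must be constant across hybridization arcs and
strictly increasing along tree arcs; its existence is decided on the star
graph N* (the network plus the reversal of every hybridization arc). The
decision computes strongly connected components of N*: the network is
inconsistent iff some tree arc has both endpoints in one component, and the
reported violation is a concrete cycle (BFS-shortest path closing the
offending tree arc, rotated to start at its lexicographically smallest
node; the offending arc itself is the lexicographically smallest one). When
consistent, each component receives 1 + the maximum over its tree-arc
predecessors (sources get 1) — the smallest ranks achievable by longest-path
layering on the condensation. The witness is canonical but not unique; τ
starts at 1 (whether 0 is admissible is a matter of convention and nothing
downstream depends on it). Every witness is re-verified against both arc
conditions before being returned.

Two independent oracles guard this decision in the tests: a quotient
formulation (cluster nodes by undirected hybridization arcs; demand no
intra-cluster tree arc and an acyclic cluster quotient), and exhaustive
search over all assignments V → {1..|V|} on small graphs — complete because
any assignment can be rank-compressed into that range.

The property checkers deliberately accept any valid S-rDAG, not only
phylogenetic networks: the arguments need only the tree/hybrid arc
classification, and the TSTC construction wants them on intermediate
graphs. Only `is_tstc` insists on the network axioms.

## The TSTC construction

A phylogenetic tree (no hybrid and no elementary node) is already TSTC and
passes through unchanged. Otherwise the six steps run in order: (1) each
hybrid's children move behind a fresh tree node u_h, which inherits the
label when the hybrid was a labeled leaf; (2) every hybridization arc is
subdivided by a fresh tree node v_e; (3) every elementary node **of the
intermediate graph** gets a pendant child v′; (4) the unique arc into the
largest-labeled leaf m is subdivided by w_m; (5) two fresh nodes a and b
receive arcs from every v′ and from w_m, making them hybrid; (6) fresh
leaves labeled with the two extra labels hang under a and b.

Step (3) is applied to the elementary nodes of the *intermediate* graph —
which includes every v_e and any u_h whose hybrid had exactly one child —
rather than only to nodes elementary in the input: that is the only scope
under which the output provably has no elementary node, which the
implementation asserts (the full `is_tstc` report is checked before every
return). The uniqueness of the parent of leaf m needed by step (4) holds
because step (1) makes every leaf a tree node; it is asserted, not assumed.

Size accounting, verified on every test input:
|V(out)| = |V| + H + |E_H| + Elem(N′) + 5, where H is the number of hybrid
nodes, E_H the hybridization arcs, and Elem(N′) = Elem(N) + |E_H| + #{hybrids
with out-degree exactly 1}.

Inversion applies the five inverse steps (drop the two fresh leaves and
their hybrid parents; contract w_m; remove unlabeled leaves in a single
pass; contract every v_e; remove each hybrid's tree child, reattaching its
children). Two points the inverse description leaves open are resolved by
the trace: the removed tree child of a hybrid returns its leaf label to the
hybrid (the round trip forces this), and the unlabeled-leaf sweep is
non-cascading, with an assertion that none survive — on construction images
no cascade can occur because every surviving internal node keeps a
non-removed child. Inversion is offered **only** for traced images:
pattern-recognition on arbitrary graphs that merely look like images is
ambiguous, and any mismatch between trace and graph raises
`NotConstructionImage`.

The bijective-labeling lift pads the root with leaf children for the unused
labels. Degenerate case: if the network is a single labeled node, the root
stops being a leaf, so its label moves onto a pendant child as well —
otherwise a label would be lost and the output would not be bijectively
labeled. Padding leaves are tree children of the root, so the network
axioms, tree-sibling, and time consistency are all preserved (the witness
extends by giving each new leaf a time above the root's).

## Isomorphism and canonical keys

Only leaves carry identity; internal nodes are interchangeable. The decision
pipeline is: invariant-multiset rejection (counts, label sets, per-node
(label, in-degree, out-degree, height, depth) profiles); iterative partition
refinement seeded by those profiles, with new cells ordered by their
signatures so the refined partition is isomorphism-invariant; then
individualization-refinement backtracking that minimizes the adjacency
certificate over all refinement-consistent orderings. Equal canonical
certificates yield the witness by composing the two canonical orderings,
and every witness is independently re-verified arc by arc. `canonical_key`
serializes the certificate; keys are equal iff the graphs are isomorphic,
which is what the enumeration uses for deduplication.

The search is exponential in the worst case — acceptable at the sizes this
package manipulates — with one important mitigation: vertices of a
branching cell with identical parent and child sets ("false twins") are
automorphic, so only one representative is explored. The constructions
routinely create bundles of k interchangeable leaves, which would otherwise
cost k! branches. Ties inside cells break lexicographically; the whole
procedure is deterministic.

## Generators and enumeration

`random_srdag` draws a random topological order over n_nodes named nodes,
gives every non-root node one uniformly chosen predecessor parent
(guaranteeing rootedness and reachability), adds each remaining
forward pair as an arc independently with probability `extra_arc_prob`, and
resamples (up to 1000 times) until the leaf count equals `n_labels`, then
labels the leaves with a shuffled "1".."n_labels". Defaults used across the
test batches: 3–12 nodes, extra-arc probability drawn from
{0, 0.1, 0.25, 0.4}, label counts up to half the node count — small enough
that thousands of cases run in seconds, large enough that hybrid-rich,
multi-hybrid, and tree-shaped inputs all occur. Everything is explicitly
seeded; there is no global random state.

`enumerate_classes` walks all strictly-upper-triangular adjacency matrices
on k ≤ 7 ordered nodes. With node 0 forced to be the unique root, a matrix
is a valid rooted DAG exactly when every other column is nonempty, so only
those columns are generated (615 195 layouts at k = 7 instead of 2^21
matrices), and every DAG admits such a layout under some topological order,
so every isomorphism class is covered. Degree-based filters (leaf count,
network axioms, tree-sibling) run on bit-level column data before any graph
object is built; time consistency, which ignores the labeling, is checked
once per surviving structure; label assignments are then attached in all
injective ways and classes deduplicated by canonical key. The 7-node bound
is a guard against combinatorial blowup, chosen so a full enumeration runs
in a couple of seconds.

## What the synthetic data does and does not show

The random generator produces uniformly-seeded DAG topologies, not
realistic evolutionary histories: it has no model of reticulation rate,
taxon sampling, branch lengths, or the biases of network-reconstruction
methods, and its label sets are small. Passing property suites therefore
establish the *combinatorial* guarantees — validity, round-trip exactness,
isomorphism preservation, oracle agreement — on a broad sample of
structures, not statistical performance on biological data. The uniqueness
of one- and two-leaf TSTC networks is an unbounded mathematical claim; the
enumeration verifies it exhaustively only up to 7 nodes and is reported as
a bounded check.

## Numerical and degenerate-input choices

There is no floating-point arithmetic anywhere; all quantities are exact
integers and strings, so determinism reduces to fixed iteration orders
(everything is sorted) and explicit seeds. Degenerate inputs are handled
explicitly: the single-node graph is a valid rDAG (root = leaf), a
single labeled node is a valid phylogenetic tree that passes through the
TSTC construction unchanged, label lines may declare a single-node graph in
the edge-list dialect (with arc lines present, labeling an unknown node is
an error), and `invert_rdag_to_srdag` refuses inputs whose leaf removal
would empty the graph. Extended Newick is offered only for valid
phylogenetic networks — mid-construction S-rDAGs with elementary nodes or
unlabeled leaves are exactly what the edge-list dialect exists for — and
the eNewick writer orders children by a canonical subtree key so repeated
writes are byte-identical.
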