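# tstcnet

Rooted leaf-labeled DAGs, tree-sibling time-consistent (TSTC) phylogenetic
networks, and the constructive reductions that make comparing such networks
exactly as hard as the general graph-isomorphism problem.

## The problem

Phylogenetic networks generalize phylogenetic trees with *hybrid* nodes of
in-degree > 1, modelling reticulate evolution (hybridization,
recombination, lateral gene transfer). A network is an S-rDAG — a rooted
DAG whose leaves are injectively labeled by a taxon set S — satisfying two
axioms: no tree node (in-degree ≤ 1) is *elementary* (out-degree 1), and
every hybrid node has out-degree 1 with a tree-type child. Two biologically
motivated restrictions matter for comparison methods:

* **tree-sibling** — every hybrid node shares a parent with a tree node
  (some species involved in each reticulation also leaves descendants by
  mutation);
* **time consistency** — there is a *temporal assignment*
  τ : V → {1, 2, …} with τ(u) = τ(v) for every hybridization arc (u, v)
  (the interacting species coexist) and τ(u) < τ(v) for every tree arc
  (speciation takes time). Equivalently, the *star graph* N* — N plus the
  reversal of every hybridization arc — has no cycle through a tree arc.

Polynomial-time metrics exist for *semibinary* TSTC networks (hybrid
in-degree 2). For general TSTC networks they cannot exist unless graph
isomorphism is in P: isomorphism of S-rDAGs reduces, constructively and in
polynomial time, to isomorphism of TSTC networks on S plus two extra
labels, and S-rDAG isomorphism is itself GI-complete. This package
implements those reductions — with exact inverses, audit traces, and
checkers for every property the constructions must preserve — so the
chain of equivalences can be executed and verified rather than only read.

What it provides:

* `core` — validated rooted DAGs (`RootedDAG`), leaf labelings (`SRDAG`),
  node/arc taxonomy (`classify`), network-axiom checking
  (`validate_network`);
* `properties` — `is_tree_sibling`, `time_consistency` (SCC decision on N*
  with a verified τ witness or a concrete violating cycle), an independent
  quotient-graph oracle, `is_tstc`;
* `reductions` — `srdag_to_rdag` / `rdag_to_srdag` (labeled ↔ unlabeled),
  the six-step `srdag_to_tstc` construction, `injective_to_bijective`, each
  with a `ConstructionTrace` and an exact inverse;
* `isomorphism` — exact `isomorphic` with verified witnesses and a
  `canonical_key` (partition refinement + canonical backtracking search);
* `generators` — seeded `random_srdag`, `variant_pair`, and
  `enumerate_classes`, an exhaustive bounded enumeration of isomorphism
  classes;
* `io` / CLI — a plain-text edge-list dialect for arbitrary S-rDAGs,
  extended Newick (`#Hk` hybrid tags) for valid networks, and a `tstcnet`
  command with `validate`, `check`, `reduce`, `invert`, `iso`, `gen` and
  `enumerate` subcommands.

## Worked example

The smallest interesting S-rDAG is the "diamond": root `r`, two paths
through `u` and `w` meeting in a hybrid leaf `h` labeled 1.

```sh
$ cat diamond.txt
r -> u
r -> w
u -> h
w -> h
label h = 1

$ tstcnet check diamond.txt --property tstc
network axiom: elementary tree node: elementary tree nodes: u, w
network axiom: hybrid out-degree: hybrid nodes with out-degree != 1: h
not tree-sibling: h
```

Not a TSTC network (exit code 1): `u` and `w` are elementary, the hybrid
`h` has no child and no tree sibling. The six-step construction repairs all
of this while preserving isomorphism:

```sh
$ tstcnet reduce diamond.txt --from srdag --to tstc --trace trace.json > tstc.txt
$ tstcnet validate tstc.txt --level phylogenetic_network
ok: 16 nodes, 24 arcs, 3 labels
$ tstcnet check tstc.txt --property time-consistent | head -4
time-consistent: true
tau a = 4
tau b = 4
tau h = 3
```

The 4-node diamond becomes a 16-node, 24-arc TSTC network on labels
{1, 2, 3} (the two extra labels 2 and 3 are the price of the construction),
and the printed τ is a verified temporal assignment. The trace makes the
reduction exactly invertible:

```sh
$ tstcnet invert tstc.txt --trace trace.json
r -> u
r -> w
u -> h
w -> h
label h = 1
```

The two extra labels are also necessary: exhaustive enumeration shows TSTC
networks with fewer than three leaves are unique up to relabeling —

```sh
$ tstcnet enumerate --max-nodes 5 --labels 1,2 --filter tstc
classes: 1
# class 0 (3 nodes)
n0 -> n1
n0 -> n2
label n1 = 1
label n2 = 2
```

— the cherry `(1,2);`, and likewise the single labeled node for one leaf.

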