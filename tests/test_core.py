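import pytest

from tstcnet import (
    InvalidGraphError,
    RootedDAG,
    SRDAG,
    classify,
    rank_labels,
    validate_network,
    validate_rdag,
)

from conftest import srdag_batch


class TestValidateRdag:
    def test_minimal_single_node(self):
        g = validate_rdag(["a"], [])
        assert g.root == "a" and g.leaves == ("a",)

    def test_diamond_is_valid(self):
        g = validate_rdag([], [("r", "u"), ("r", "w"), ("u", "h"), ("w", "h")])
        assert g.root == "r" and len(g) == 4

    @pytest.mark.parametrize(
        "nodes,arcs,code",
        [
            ([], [], "empty graph"),
            (["a", "b"], [("a", "b"), ("b", "a")], "not acyclic"),
            (["a", "b", "c"], [("a", "c"), ("b", "c")], "not rooted"),
            (["a"], [("a", "a")], "self-arc"),
            ([], [("a", "b"), ("a", "b")], "duplicate arc"),
        ],
    )
    def test_rejections_name_the_violated_invariant(self, nodes, arcs, code):
        with pytest.raises(InvalidGraphError) as exc:
            validate_rdag(nodes, arcs)
        assert code in exc.value.codes

    def test_cycle_diagnostic_carries_node_sequence(self):
        with pytest.raises(InvalidGraphError) as exc:
            validate_rdag([], [("r", "a"), ("a", "b"), ("b", "a")])
        diag = next(d for d in exc.value.diagnostics if d.code == "not acyclic")
        assert set(diag.nodes) == {"a", "b"}

    def test_unreachable_nodes_listed(self):
        # a side cycle hanging off nothing: unique root, but b and c cannot
        # be reached from it — both the cycle and the disconnection surface
        with pytest.raises(InvalidGraphError) as exc:
            validate_rdag([], [("r", "x"), ("b", "c"), ("c", "b")])
        codes = set(exc.value.codes)
        assert "not connected from root" in codes and "not acyclic" in codes
        unreach = next(d for d in exc.value.diagnostics if d.code == "not connected from root")
        assert set(unreach.nodes) == {"b", "c"}


class TestClassify:
    def test_diamond_taxonomy(self, diamond):
        cls = classify(diamond.graph)
        assert cls.nodes["h"].is_hybrid and cls.nodes["h"].is_leaf
        assert cls.nodes["u"].is_elementary and cls.nodes["w"].is_elementary
        assert cls.arcs[("u", "h")] == "hybridization"
        assert cls.arcs[("w", "h")] == "hybridization"
        assert cls.arcs[("r", "u")] == "tree"

    def test_heights_and_depths(self, tree12):
        cls = classify(tree12.graph)
        root = tree12.root
        assert cls.nodes[root].height == 1 and cls.nodes[root].depth == 0
        for leaf in tree12.leaves:
            assert cls.nodes[leaf].height == 0 and cls.nodes[leaf].depth == 1

    def test_longest_path_semantics_on_diamond(self, diamond):
        cls = classify(diamond.graph)
        # r -> u -> h is longer than any direct arc would be
        assert cls.nodes["h"].depth == 2
        assert cls.nodes["r"].height == 2

    def test_leaves_are_never_elementary(self):
        for g in srdag_batch(20, seed0=11):
            cls = classify(g.graph)
            for v, c in cls.nodes.items():
                assert not (c.is_leaf and c.is_elementary)
                assert c.is_tree != c.is_hybrid
                assert (c.height == 0) == c.is_leaf

    def test_tree_plus_hybrid_partitions_nodes(self):
        for g in srdag_batch(20, seed0=12):
            cls = classify(g.graph)
            n_tree = sum(c.is_tree for c in cls.nodes.values())
            n_hyb = sum(c.is_hybrid for c in cls.nodes.values())
            assert n_tree + n_hyb == len(g.nodes)
            n_hyb_arcs = sum(1 for k in cls.arcs.values() if k == "hybridization")
            assert n_hyb_arcs == sum(
                c.in_degree for c in cls.nodes.values() if c.is_hybrid
            )

    def test_invariant_under_renaming(self):
        for g in srdag_batch(10, seed0=13):
            renamed = g.relabel_nodes({v: f"x{i}" for i, v in enumerate(sorted(g.nodes))})
            def profile(s):
                cls = classify(s.graph)
                return sorted(
                    (c.in_degree, c.out_degree, c.height, c.depth, c.is_hybrid)
                    for c in cls.nodes.values()
                )
            assert profile(g) == profile(renamed)


class TestValidateNetwork:
    def test_tree12_is_a_phylogenetic_network(self, tree12):
        assert validate_network(tree12, level="phylogenetic_network") == ()

    def test_diamond_fails_network_axioms_but_is_a_valid_srdag(self, diamond):
        assert validate_network(diamond, level="srdag") == ()
        codes = {d.code for d in validate_network(diamond, level="phylogenetic_network")}
        assert "elementary tree node" in codes
        elem = next(
            d for d in validate_network(diamond, level="phylogenetic_network")
            if d.code == "elementary tree node"
        )
        assert set(elem.nodes) == {"u", "w"}

    def test_labeling_violations_reported_distinctly(self):
        g = RootedDAG([], [("r", "a"), ("r", "b")])
        codes = {d.code for d in validate_network(SRDAG(g, {"a": "1"}, strict=False))}
        assert codes == {"unlabeled leaf"}
        codes = {d.code for d in validate_network(SRDAG(g, {"a": "1", "b": "1"}, strict=False))}
        assert codes == {"duplicate label"}
        codes = {d.code for d in validate_network(
            SRDAG(g, {"a": "1", "b": "2", "r": "3"}, strict=False))}
        assert codes == {"non-leaf labeled"}

    def test_hybrid_child_of_hybrid_reported(self):
        arcs = [("r", "u"), ("r", "w"), ("u", "h"), ("w", "h"),
                ("u", "k"), ("h", "k"), ("k", "l"), ("r", "t")]
        g = SRDAG.from_arcs(arcs, {"l": "1", "t": "2"}, strict=False)
        codes = {d.code for d in validate_network(g, level="phylogenetic_network")}
        assert "hybrid child of hybrid" in codes


def test_rank_labels_orders_numeric_strings_numerically():
    assert rank_labels(["10", "2", "1"]) == {"1": 1, "2": 2, "10": 3}
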