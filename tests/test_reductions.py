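import pytest

from tstcnet import (
    ConstructionTrace,
    NotConstructionImage,
    RootedDAG,
    SRDAG,
    classify,
    injective_to_bijective,
    invert_rdag_to_srdag,
    invert_srdag_to_rdag,
    invert_srdag_to_tstc,
    is_tstc,
    rdag_to_srdag,
    srdag_to_rdag,
    srdag_to_tstc,
)

from conftest import non_tree_batch, srdag_batch


class TestLeafRankEncoding:
    """Leaf-labeled -> unlabeled: rank-k leaves sprout k pendant leaves."""

    def test_single_labeled_node_becomes_two_node_path(self):
        g = SRDAG.from_arcs([], {"v": "1"}, nodes=["v"])
        out, trace = srdag_to_rdag(g)
        assert len(out.nodes) == 2 and out.root == "v"
        assert invert_srdag_to_rdag(out, trace) == g

    def test_two_leaf_tree_grows_to_six_nodes(self, tree12):
        out, trace = srdag_to_rdag(tree12)
        assert len(out.nodes) == 6  # 3 original + 1 + 2 pendant leaves
        # the height-1 nodes over fresh leaves encode the former ranks
        added = set(trace.role_map)
        kcounts = sorted(
            len([c for c in out.children(v) if c in added])
            for v in out.nodes
            if any(c in added for c in out.children(v))
        )
        assert kcounts == [1, 2]

    def test_output_carries_no_labels_and_node_growth_is_rank_sum(self):
        for g in srdag_batch(30, seed0=31):
            out, trace = srdag_to_rdag(g)
            n_labels = len(g.labels)
            assert len(out.nodes) == len(g.nodes) + n_labels * (n_labels + 1) // 2

    def test_round_trip_is_identity(self):
        for g in srdag_batch(50, seed0=32):
            out, trace = srdag_to_rdag(g)
            assert invert_srdag_to_rdag(out, trace) == g

    def test_tampered_trace_rejected(self, tree12):
        out, trace = srdag_to_rdag(tree12)
        missing = next(iter(trace.role_map))
        bad = ConstructionTrace(
            kind=trace.kind,
            role_map={k: v for k, v in trace.role_map.items() if k != missing},
            source_of=trace.source_of,
            data=trace.data,
        )
        with pytest.raises(NotConstructionImage):
            invert_srdag_to_rdag(out, bad)


class TestSingleSink:
    """Unlabeled -> leaf-labeled: one labeled sink below every leaf."""

    def test_single_node(self):
        g = RootedDAG(["a"], [])
        out, _ = rdag_to_srdag(g)
        assert len(out.nodes) == 2 and len(out.leaves) == 1
        assert out.labeling[out.leaves[0]] == "1"
        assert invert_rdag_to_srdag(out) == g

    def test_node_delta_is_always_one(self):
        for g in srdag_batch(40, seed0=33):
            out, _ = rdag_to_srdag(g.graph)
            assert len(out.nodes) == len(g.graph.nodes) + 1
            assert len(out.arcs) == len(g.graph.arcs) + len(g.graph.leaves)
            assert len(out.leaves) == 1

    def test_new_sink_parents_are_exactly_the_former_leaves(self, diamond):
        out, trace = rdag_to_srdag(diamond.graph)
        assert len(out.nodes) == 5
        sink = out.leaves[0]
        assert set(out.graph.parents(sink)) == set(diamond.graph.leaves)

    def test_round_trip_is_identity(self):
        for g in srdag_batch(50, seed0=34):
            out, _ = rdag_to_srdag(g.graph)
            assert invert_rdag_to_srdag(out) == g.graph

    def test_two_leaf_input_rejected(self, tree12):
        with pytest.raises(NotConstructionImage):
            invert_rdag_to_srdag(tree12)


class TestTSTCConstruction:
    def test_worked_example_diamond(self, diamond):
        out, trace = srdag_to_tstc(diamond)
        assert len(out.nodes) == 16
        assert len(out.arcs) == 24
        assert sorted(out.labels) == ["1", "2", "3"]
        assert len(out.leaves) == 3
        assert is_tstc(out).ok
        assert invert_srdag_to_tstc(out, trace) == diamond

    def test_worked_example_roles(self, diamond):
        _, trace = srdag_to_tstc(diamond)
        counts = {}
        for role in trace.role_map.values():
            counts[role] = counts.get(role, 0) + 1
        assert counts == {
            "u_h": 1, "v_e": 2, "v_prime": 4, "w_m": 1, "a": 1, "b": 1, "pad_leaf": 2,
        }

    def test_phylogenetic_trees_pass_through(self, tree12):
        out, trace = srdag_to_tstc(tree12)
        assert out is tree12 and trace.role_map == {}

    def test_tree_with_elementary_node_does_not_pass_through(self):
        # a chain r -> e -> leaf is a tree but not a phylogenetic tree
        g = SRDAG.from_arcs([("r", "e"), ("e", "l")], {"l": "1"})
        out, trace = srdag_to_tstc(g)
        assert trace.role_map and is_tstc(out).ok

    def test_label_growth_is_exactly_two_on_non_tree_inputs(self):
        for g in non_tree_batch(40, seed0=35):
            out, trace = srdag_to_tstc(g)
            assert out.labels == g.labels | set(trace.new_labels)
            assert len(out.labels) == len(g.labels) + 2

    def test_size_accounting(self):
        for g in non_tree_batch(40, seed0=36):
            out, trace = srdag_to_tstc(g)
            cls = classify(g.graph)
            H = sum(c.is_hybrid for c in cls.nodes.values())
            EH = sum(c.in_degree for c in cls.nodes.values() if c.is_hybrid)
            elem = sum(c.is_elementary for c in cls.nodes.values())
            hyb_out1 = sum(
                1 for c in cls.nodes.values() if c.is_hybrid and c.out_degree == 1
            )
            elem_nprime = elem + EH + hyb_out1
            assert len(out.nodes) == len(g.nodes) + H + EH + elem_nprime + 5
            assert len(trace.nodes_with_role("u_h")) == H
            assert len(trace.nodes_with_role("v_e")) == EH
            assert len(trace.nodes_with_role("v_prime")) == elem_nprime

    def test_round_trip_is_identity(self):
        for g in non_tree_batch(50, seed0=37):
            out, trace = srdag_to_tstc(g)
            assert invert_srdag_to_tstc(out, trace) == g

    def test_deterministic_traces(self):
        for g in non_tree_batch(10, seed0=38):
            out1, t1 = srdag_to_tstc(g)
            out2, t2 = srdag_to_tstc(g)
            assert out1 == out2 and t1.to_json() == t2.to_json()

    def test_trace_round_trips_through_json(self, diamond):
        _, trace = srdag_to_tstc(diamond)
        again = ConstructionTrace.from_json(trace.to_json())
        assert again.role_map == trace.role_map
        assert again.new_labels == trace.new_labels
        assert again.m_label == trace.m_label

    def test_mismatched_trace_rejected(self, diamond):
        out, trace = srdag_to_tstc(diamond)
        other = SRDAG.from_arcs(
            [("r", "u"), ("r", "w"), ("u", "h"), ("w", "h"), ("r", "t")],
            {"h": "1", "t": "2"},
        )
        out2, _ = srdag_to_tstc(other)
        with pytest.raises(NotConstructionImage):
            invert_srdag_to_tstc(out2, trace)


class TestBijectiveLift:
    def test_missing_labels_become_root_children(self):
        g = SRDAG.from_arcs([], {"v": "1"}, nodes=["v"])
        out = injective_to_bijective(g, {"1", "2", "3"})
        assert sorted(out.labels) == ["1", "2", "3"]
        assert len(out.nodes) == 4  # the root's own label moves onto a leaf too
        assert all(p == ("v",) for p in (out.graph.parents(l) for l in out.leaves))

    def test_identity_when_labels_match(self, tree12):
        assert injective_to_bijective(tree12, {"1", "2"}) is tree12

    def test_label_outside_target_set(self, tree12):
        with pytest.raises(ValueError, match="label outside target set"):
            injective_to_bijective(tree12, {"1", "3"})

    def test_node_growth_counts(self, tree12):
        out = injective_to_bijective(tree12, {"1", "2", "3", "4"})
        assert len(out.nodes) == len(tree12.nodes) + 2

    def test_tstc_preserved(self):
        for g in srdag_batch(30, seed0=39):
            net, _ = srdag_to_tstc(g)
            target = set(net.labels) | {"x1", "x2"}
            lifted = injective_to_bijective(net, target)
            assert is_tstc(lifted).ok
            assert lifted.labels == frozenset(target)
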