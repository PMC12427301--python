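import itertools

import numpy as np
import pytest

from oracles import enumerate_parsimony

from karyoevol.events import (
    Event,
    EventScenario,
    fitch_changes,
    infer_edge_events,
    infer_scenario,
    node_name,
)
from karyoevol.karyo_io import SHAPE_LABELS, parse_tree


class TestEvent:
    def test_inversion_requires_position_and_change(self):
        with pytest.raises(ValueError, match="position"):
            Event("inversion", ("p", "c"), position=None, from_state="M", to_state="sM")
        with pytest.raises(ValueError, match="change"):
            Event("inversion", ("p", "c"), position=3, from_state="M", to_state="M")

    def test_translocation_decrement(self):
        with pytest.raises(ValueError, match="exactly one pair"):
            Event("translocation", ("p", "c"), from_state=26, to_state=23)
        e = Event("translocation", ("p", "c"), from_state=26, to_state=25)
        assert e.kind == "translocation"

    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="kind"):
            Event("fission", ("p", "c"), position=1, from_state="M", to_state="T")


class TestFitchChanges:
    def test_two_leaf_disagreement(self):
        count, labeling = fitch_changes(parse_tree("(A,B);"), {"A": "sT", "B": "M"})
        assert count == 1
        assert labeling["A"] == "sT" and labeling["B"] == "M"
        # tie at the root resolves toward M
        assert labeling["N1"] == "M"

    def test_identical_leaves(self):
        tree = parse_tree("((A,B),(C,D));")
        count, labeling = fitch_changes(tree, {x: "sM" for x in "ABCD"})
        assert count == 0
        assert set(labeling.values()) == {"sM"}

    def test_unlabeled_leaf(self):
        with pytest.raises(ValueError, match="no state"):
            fitch_changes(parse_tree("(A,B);"), {"A": "M"})

    def test_polytomy_exact(self):
        # star tree: 3 leaves M, 2 leaves sM -> 2 changes from an M root
        tree = parse_tree("(A,B,C,D,E);")
        states = {"A": "M", "B": "M", "C": "M", "D": "sM", "E": "sM"}
        count, labeling = fitch_changes(tree, states)
        assert count == 2
        assert labeling["N1"] == "M"

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(2000 + seed)
        n_leaves = int(rng.integers(3, 7))
        labels = [f"L{i}" for i in range(n_leaves)]
        newick = _random_newick(labels, rng)
        tree = parse_tree(newick)
        states = {lab: SHAPE_LABELS[i] for lab, i in
                  zip(labels, rng.integers(0, 4, n_leaves))}
        count, labeling = fitch_changes(tree, states)

        edges = [
            (node_name(n), node_name(c))
            for n in tree.preorder_node_iter()
            for c in n.child_nodes()
        ]
        expected = enumerate_parsimony(edges, states, SHAPE_LABELS)
        assert count == expected
        # the returned labeling achieves the minimum
        achieved = sum(1 for p, c in edges if labeling[p] != labeling[c])
        assert achieved == expected


def _random_newick(labels, rng):
    items = list(labels)
    rng.shuffle(items)
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False), reverse=True)
        a, b = items.pop(int(i)), items.pop(int(j))
        items.append(f"({a},{b})")
    return items[0] + ";"


class TestRootMajority:
    def test_single_taxon(self):
        from karyoevol.events import reconstruct_root_majority

        assert reconstruct_root_majority([("M", "sM")]) == ("M", "sM")

    def test_strict_majority(self):
        from karyoevol.events import reconstruct_root_majority

        assert reconstruct_root_majority([("M",), ("M",), ("sM",)]) == ("M",)

    def test_tie_breaks_toward_metacentric(self):
        from karyoevol.events import reconstruct_root_majority

        assert reconstruct_root_majority([("sM",), ("M",)]) == ("M",)
        assert reconstruct_root_majority([("sT",), ("T",)]) == ("sT",)

    def test_unequal_lengths(self):
        from karyoevol.events import reconstruct_root_majority

        with pytest.raises(ValueError, match="unequal"):
            reconstruct_root_majority([("M",), ("M", "sM")])


class TestInferEdgeEvents:
    def test_study_populations(self, capri, palermo):
        events = infer_edge_events(capri.shape_labels, palermo.shape_labels)
        assert len(events) == 2
        assert all(e.kind == "inversion" for e in events)
        assert [(e.position, e.from_state, e.to_state) for e in events] == [
            (8, "sT", "M"),
            (17, "M", "sM"),
        ]

    def test_primitive_to_derived_translocations(self):
        parent = ("M",) * 26
        child = ("M",) * 20 + ("sM",) * 4  # a 24-pair descendant
        events = infer_edge_events(parent, child)
        kinds = [e.kind for e in events]
        assert kinds.count("translocation") == 2

    def test_identical_states_empty(self, capri):
        assert infer_edge_events(capri.shape_labels, capri.shape_labels) == []

    def test_translocation_count_is_half_diploid_difference(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            np_count = int(rng.integers(4, 12))
            d = int(rng.integers(0, 3))
            parent = tuple(SHAPE_LABELS[i] for i in rng.integers(0, 4, np_count))
            child = tuple(SHAPE_LABELS[i] for i in rng.integers(0, 4, np_count - d))
            events = infer_edge_events(parent, child)
            n_t = sum(1 for e in events if e.kind == "translocation")
            diploid_diff = 2 * np_count - 2 * (np_count - d)
            assert n_t == diploid_diff // 2 == d

    def test_fusion_positions_minimize_inversions(self):
        # dropping the lone sM leaves a perfect match (0 inversions)
        parent = ("M", "sM", "M")
        child = ("M", "M")
        events = infer_edge_events(parent, child)
        assert [e.kind for e in events] == ["translocation"]
        assert events[0].position == 2

    def test_exhaustive_fusion_choice_matches_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n = int(rng.integers(4, 9))
            d = int(rng.integers(1, 3))
            parent = tuple(SHAPE_LABELS[i] for i in rng.integers(0, 4, n))
            child = tuple(SHAPE_LABELS[i] for i in rng.integers(0, 4, n - d))
            events = infer_edge_events(parent, child)
            inv = sum(1 for e in events if e.kind == "inversion")
            best = min(
                sum(
                    1
                    for k, c in zip([x for x in range(n) if x not in lost], range(n - d))
                    if parent[k] != child[c]
                )
                for lost in itertools.combinations(range(n), d)
            )
            assert inv == best

    def test_fission_unsupported(self):
        with pytest.raises(ValueError, match="fission"):
            infer_edge_events(("M",), ("M", "sM"))

    def test_deep_fusion_not_implemented(self):
        with pytest.raises(NotImplementedError):
            infer_edge_events(("M",) * 8, ("M",) * 5)


class TestInferScenario:
    def test_study_two_leaf_totals(self, capri, palermo):
        scenario = infer_scenario("(Capri,Palermo);", {"Capri": capri, "Palermo": palermo})
        assert scenario.totals == {"inversion": 2, "translocation": 0}
        positions = sorted(e.position for e in scenario.events)
        assert positions == [8, 17]

    def test_star_tree_identical_leaves(self, capri):
        scenario = infer_scenario(
            "(a,b,c);", {name: capri for name in ("a", "b", "c")}
        )
        assert scenario.events == ()
        assert scenario.totals == {"inversion": 0, "translocation": 0}

    def test_totals_invariant_to_leaf_order(self, capri, palermo):
        s1 = infer_scenario("(Capri,Palermo);", {"Capri": capri, "Palermo": palermo})
        s2 = infer_scenario("(Palermo,Capri);", {"Palermo": palermo, "Capri": capri})
        assert s1.totals == s2.totals

    def test_missing_leaf(self, capri):
        with pytest.raises(ValueError, match="no karyotype"):
            infer_scenario("(Capri,Palermo);", {"Capri": capri})

    def test_unequal_pair_counts(self, capri):
        from conftest import make_karyotype

        small = make_karyotype("x", [60.0, 40.0], [40.0, 40.0])
        with pytest.raises(ValueError, match="unequal pair counts"):
            infer_scenario("(Capri,x);", {"Capri": capri, "x": small})

    def test_label_vectors_accepted(self):
        scenario = infer_scenario(
            "(a,b);", {"a": ("M", "sM"), "b": ("M", "M")}
        )
        assert scenario.totals["inversion"] == 1

    def test_deterministic(self, capri, palermo):
        s1 = infer_scenario("(Capri,Palermo);", {"Capri": capri, "Palermo": palermo})
        s2 = infer_scenario("(Capri,Palermo);", {"Capri": capri, "Palermo": palermo})
        assert s1.to_dict() == s2.to_dict()


class TestScenarioConsistency:
    def test_edge_events_replay(self, capri, palermo):
        scenario = infer_scenario(
            "((Capri,Palermo),(Capri2,Palermo2));",
            {
                "Capri": capri,
                "Palermo": palermo,
                "Capri2": capri.with_shapes(capri.shape_labels),
                "Palermo2": palermo.with_shapes(palermo.shape_labels),
            },
        )
        tree = parse_tree(scenario.tree_newick)
        for node in tree.preorder_node_iter():
            for child in node.child_nodes():
                parent_states = scenario.node_states[node_name(node)]
                child_states = scenario.node_states[node_name(child)]
                edge_events = scenario.events_on_edge(node_name(node), node_name(child))
                mismatches = {
                    i + 1
                    for i, (p, c) in enumerate(zip(parent_states, child_states))
                    if p != c
                }
                assert {e.position for e in edge_events} == mismatches

    def test_totals_match_event_list(self, capri, palermo):
        scenario = infer_scenario("(Capri,Palermo);", {"Capri": capri, "Palermo": palermo})
        assert scenario.totals["inversion"] == sum(
            1 for e in scenario.events if e.kind == "inversion"
        )
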