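import random

import pytest

from netweaver import (
    NETWORK_CSV_HEADER,
    InteractionRecord,
    NodeRecord,
    UnknownSymbolError,
    build_wheel,
    integrate_interactions,
    merge_networks,
    read_network_csv,
    write_network_csv,
)
from conftest import ORGANISM, make_dataset


class TestBuildWheel:
    def test_wheel_shape(self, identity_backend):
        net = build_wheel(make_dataset("A", ["t1", "t2"]), identity_backend)
        assert net.n_nodes == 3 and net.n_edges == 2
        assert {e.key for e in net.edges} == {("A", "t1", "DamID"), ("A", "t2", "DamID")}
        assert [c.primary_identifier for c in net.cores] == ["A"]

    def test_empty_target_list(self, identity_backend):
        net = build_wheel(make_dataset("A", []), identity_backend)
        assert net.n_nodes == 1 and net.n_edges == 0

    def test_duplicate_targets_collapse(self, identity_backend):
        net = build_wheel(make_dataset("A", ["t1", "t1"]), identity_backend)
        assert net.n_edges == 1

    def test_self_loop_dropped_by_default(self, identity_backend):
        net = build_wheel(make_dataset("A", ["A", "t1"]), identity_backend)
        assert net.edge_keys() == {("A", "t1", "DamID")}
        looped = build_wheel(
            make_dataset("A", ["A"]), identity_backend, allow_self_loops=True
        )
        assert looped.edge_keys() == {("A", "A", "DamID")}

    def test_invalid_core_is_fatal(self, identity_backend):
        with pytest.raises(UnknownSymbolError):
            build_wheel(make_dataset("nope", ["t1"]), identity_backend)


class TestMergeNetworks:
    def wheels(self, backend):
        return [
            build_wheel(make_dataset("A", ["t1", "t2"]), backend),
            build_wheel(make_dataset("B", ["t2", "t3"], technique="RNAseq"), backend),
        ]

    def test_shared_target_connects_hubs(self, identity_backend):
        net = merge_networks(self.wheels(identity_backend))
        assert net.n_nodes == 5 and net.n_edges == 4
        in_degree_t2 = sum(e.target.primary_identifier == "t2" for e in net.edges)
        assert in_degree_t2 == 2

    def test_idempotent_self_merge(self, identity_backend):
        wheel = self.wheels(identity_backend)[0]
        twice = merge_networks([wheel, wheel])
        assert twice.edge_keys() == wheel.edge_keys()
        assert set(twice.nodes) == set(wheel.nodes)

    def test_core_targeting_another_core(self, identity_backend):
        a = build_wheel(make_dataset("A", ["B"]), identity_backend)
        b = build_wheel(make_dataset("B", ["t1"]), identity_backend)
        net = merge_networks([a, b])
        assert ("A", "B", "DamID") in net.edge_keys()
        assert len(net.cores) == 2

    def test_order_invariance_up_to_canonical_sort(self, identity_backend):
        wheels = self.wheels(identity_backend) + [
            build_wheel(make_dataset("C", ["t1", "t3"], technique="ChIP"), identity_backend)
        ]
        ref = merge_networks(wheels)
        rng = random.Random(7)
        for _ in range(5):
            shuffled = wheels[:]
            rng.shuffle(shuffled)
            net = merge_networks(shuffled)
            assert net.edge_keys() == ref.edge_keys()
            assert set(net.nodes) == set(ref.nodes)
            assert {c.primary_identifier for c in net.cores} == {
                c.primary_identifier for c in ref.cores
            }

    def test_node_count_equals_identifier_union(self, identity_backend):
        lists = {"A": ["t1", "t2"], "B": ["t2", "t3"], "C": ["t1", "t4", "B"]}
        wheels = [build_wheel(make_dataset(c, ts), identity_backend) for c, ts in lists.items()]
        net = merge_networks(wheels)
        brute = set(lists) | {t for ts in lists.values() for t in ts}
        assert set(net.nodes) == brute

    def test_technique_collision_keeps_both_edges(self, identity_backend):
        a1 = build_wheel(make_dataset("A", ["t1"], name="d1", technique="DamID"), identity_backend)
        a2 = build_wheel(make_dataset("A", ["t1"], name="d2", technique="RNAseq"), identity_backend)
        net = merge_networks([a1, a2])
        assert net.n_edges == 2

    def test_organism_mismatch_rejected(self, identity_backend):
        wheel = self.wheels(identity_backend)[0]
        alien = wheel.copy()
        alien.organism = "Alius organismi"
        with pytest.raises(ValueError, match="organism"):
            merge_networks([wheel, alien])


class TestIntegrateInteractions:
    def test_feedback_loop_onto_core(self, identity_backend):
        net = build_wheel(make_dataset("A", ["t1"]), identity_backend)
        rec = InteractionRecord(
            NodeRecord("t1", "t1", "", ORGANISM), NodeRecord("A", "A", "", ORGANISM), "genetic"
        )
        out = integrate_interactions(net, [rec])
        assert ("t1", "A", "genetic") in out.edge_keys()
        assert ("A", "t1", "DamID") in out.edge_keys()  # never removes edges

    def test_new_partner_added(self, identity_backend):
        net = build_wheel(make_dataset("A", ["t1"]), identity_backend)
        rec = InteractionRecord(
            NodeRecord("t1", "t1", "", ORGANISM), NodeRecord("x9", "x9", "", ORGANISM), "physical"
        )
        out = integrate_interactions(net, [rec])
        assert out.n_nodes == net.n_nodes + 1
        assert ("t1", "x9", "physical") in out.edge_keys()

    def test_duplicate_record_is_noop_and_monotone(self, identity_backend):
        net = build_wheel(make_dataset("A", ["t1"]), identity_backend)
        rec = InteractionRecord(
            NodeRecord("t1", "t1", "", ORGANISM), NodeRecord("A", "A", "", ORGANISM), "genetic"
        )
        once = integrate_interactions(net, [rec])
        twice = integrate_interactions(once, [rec])
        assert twice.edge_keys() == once.edge_keys()
        assert set(net.nodes) <= set(once.nodes) <= set(twice.nodes)

    def test_foreign_organism_rejected(self, identity_backend):
        net = build_wheel(make_dataset("A", ["t1"]), identity_backend)
        rec = InteractionRecord(
            NodeRecord("t1", "t1", "", "Alius organismi"),
            NodeRecord("A", "A", "", "Alius organismi"),
            "genetic",
        )
        out = integrate_interactions(net, [rec])
        assert out.edge_keys() == net.edge_keys()


class TestNetworkCsv:
    def test_header_is_the_cytoscape_column_set(self, identity_backend, tmp_path):
        net = build_wheel(make_dataset("A", ["t1"]), identity_backend)
        path = tmp_path / "net.csv"
        write_network_csv(net, str(path))
        first_line = path.read_text(encoding="utf-8").splitlines()[0]
        assert first_line == (
            "Source Symbol,Source Primary Identifier,Source Secondary Identifier,"
            "Interaction Type,Target Symbol,Target Primary Identifier,"
            "Target Secondary Identifier"
        )
        assert first_line == ",".join(NETWORK_CSV_HEADER)

    def test_row_count_is_edge_count(self, identity_backend, tmp_path):
        net = build_wheel(make_dataset("A", ["t1", "t2"]), identity_backend)
        path = tmp_path / "net.csv"
        write_network_csv(net, str(path))
        assert len(path.read_text(encoding="utf-8").splitlines()) == 3

    def test_empty_network_writes_header_only(self, identity_backend, tmp_path):
        net = build_wheel(make_dataset("A", []), identity_backend)
        path = tmp_path / "net.csv"
        write_network_csv(net, str(path))
        assert len(path.read_text(encoding="utf-8").splitlines()) == 1

    def test_round_trip_preserves_edge_multiset(self, identity_backend, tmp_path):
        wheels = [
            build_wheel(make_dataset("A", ["t1", "t2"]), identity_backend),
            build_wheel(make_dataset("B", ["t2", "t3"], technique="RNAseq"), identity_backend),
        ]
        net = merge_networks(wheels)
        path = tmp_path / "net.csv"
        write_network_csv(net, str(path))
        back = read_network_csv(str(path), organism=ORGANISM, cores=["A", "B"])
        assert sorted(e.key for e in back.edges) == sorted(e.key for e in net.edges)
        assert set(back.nodes) == set(net.nodes)
        assert {c.primary_identifier for c in back.cores} == {"A", "B"}

    def test_cores_inferred_from_technique_edges(self, identity_backend, tmp_path):
        net = merge_networks([
            build_wheel(make_dataset("A", ["t1"]), identity_backend),
            build_wheel(make_dataset("B", ["t1"]), identity_backend),
        ])
        path = tmp_path / "net.csv"
        write_network_csv(net, str(path))
        back = read_network_csv(str(path))
        assert {c.primary_identifier for c in back.cores} == {"A", "B"}
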