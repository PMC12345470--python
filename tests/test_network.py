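import datetime
from collections import defaultdict

import numpy as np
import pytest

from keystonenet import (
    BipartiteNetwork,
    NestRecord,
    SampleMeta,
    build_network,
    export_graph,
    filter_otus,
    import_graphml,
    node_degree,
    node_wmd,
    rank_keystones,
)
from keystonenet.network import AnimalAggregation, node_importance
from keystonenet.simulate import SimConfig, generate_dataset
from keystonenet.ingest import Lineage, assign_hosts

from conftest import PLANT, make_otu_table, random_network


class TestBuildNetwork:
    def test_edge_filter_drops_weak_edge_and_isolated_node(
        self, plant_table, assigned_samples
    ):
        net = build_network(
            "diet_plant", samples=assigned_samples, otu=plant_table, edge_min=100
        )
        assert sorted(net.edges) == [
            ("Host one", "GenA", 150.0),
            ("Host two", "GenA", 4000.0),
        ]
        assert "GenB" not in net.resource_nodes  # 90-read edge filtered, node isolated
        assert "GenC" not in net.resource_nodes  # never exceeded the threshold

    def test_zero_samples_gives_empty_network(self, plant_table):
        net = build_network("diet_plant", samples=[], otu=plant_table)
        assert not net.bird_nodes and not net.resource_nodes and not net.edges

    def test_node_abundance_is_total_observed(self, plant_table, assigned_samples):
        net = build_network("diet_plant", samples=assigned_samples, otu=plant_table)
        # GenA abundance counts all reads, including those behind filtered edges
        assert net.resource_nodes["GenA"] == 4150
        assert net.bird_nodes["Host one"] == 150 + 90 + 20

    def test_edge_weight_exactly_at_threshold_excluded(self, assigned_samples):
        table = make_otu_table(
            "rbcL",
            [("o1", PLANT.format(g="GenA"), [100, 101])],
            ["s1", "s2"],
        )
        net = build_network("diet_plant", samples=assigned_samples, otu=table, edge_min=100)
        assert net.edges == [("Host two", "GenA", 101.0)]

    def test_matches_brute_force_accumulation_on_simulated_data(self):
        """Edge weights equal a per-cell accumulation over (host, genus) pairs."""
        cfg = SimConfig(seed=11, n_samples=10)
        coi, rbcl, samples, *_ = generate_dataset(cfg)
        assigned = assign_hosts(filter_otus(coi), samples)
        rbcl_f = filter_otus(rbcl)
        net = build_network("diet_plant", samples=assigned, otu=rbcl_f, edge_min=100)

        expected = defaultdict(float)
        host_of = {s.sample_id: s.host_species for s in assigned if s.host_species != "UNASSIGNED"}
        for otu_id in rbcl_f.counts.index:
            genus = rbcl_f.lineages[otu_id].label_at("genus")
            for sid, host in host_of.items():
                expected[(host, genus)] += int(rbcl_f.counts.loc[otu_id, sid])
        expected_edges = sorted(
            (h, g, w) for (h, g), w in expected.items() if w > 100
        )
        assert net.edges == expected_edges

    def test_monotone_in_edge_min(self, plant_table, assigned_samples):
        nets = [
            build_network("diet_plant", samples=assigned_samples, otu=plant_table, edge_min=m)
            for m in (0, 50, 100, 1000, 10**6)
        ]
        for weaker, stronger in zip(nets, nets[1:]):
            assert stronger.n_edges <= weaker.n_edges
            for node in stronger.resource_nodes:
                assert node_degree(stronger, node) <= node_degree(weaker, node)

    def test_nest_network_counts_nests_without_read_filter(self):
        nests = [
            NestRecord("n1", "Pica pica", "Robinia pseudoacacia", "deciduous_tree"),
            NestRecord("n2", "Pica pica", "Robinia pseudoacacia", "deciduous_tree"),
            NestRecord("n3", "Parus minor", "Robinia pseudoacacia", "deciduous_tree"),
            NestRecord("n4", "Parus minor", "ARTIFICIAL", "non_plant"),
            NestRecord("n5", "UNIDENTIFIED", "Vitex negundo", "shrub"),
        ]
        net = build_network("nest_plant", nests=nests)
        assert net.edges == [
            ("Parus minor", "Robinia pseudoacacia", 1.0),
            ("Pica pica", "Robinia pseudoacacia", 2.0),
        ]
        assert net.resource_nodes["Robinia pseudoacacia"] == 3

    def test_hominidae_excluded_from_animal_network_by_default(self):
        rows = [
            ("o1", "k__Animalia;p__Chordata;c__Mammalia;o__Primates;f__Hominidae;g__Homo;s__Homo sapiens", [500]),
            ("o2", "k__Animalia;p__Annelida;c__Clitellata;o__;f__;g__;s__Amynthas sp.", [800]),
        ]
        table = make_otu_table("COI", rows, ["s1"])
        samples = [SampleMeta("s1", datetime.date(2024, 6, 5), host_species="Pica pica")]
        net = build_network("diet_animal", samples=samples, otu=table, edge_min=100)
        assert list(net.resource_nodes) == ["Annelida"]
        kept = build_network(
            "diet_animal", samples=samples, otu=table, edge_min=100, exclude_families=()
        )
        assert set(kept.resource_nodes) == {"Annelida", "Hominidae"}


class TestAnimalAggregation:
    @pytest.mark.parametrize(
        "lineage,label",
        [
            ("k__Animalia;p__Arthropoda;c__Insecta;o__Coleoptera;f__;g__;s__", "Coleoptera"),
            ("k__Animalia;p__Arthropoda;c__Insecta;o__Blattodea;f__;g__;s__", "other insects"),
            ("k__Animalia;p__Annelida;c__Clitellata;o__;f__;g__;s__", "Annelida"),
            ("k__Animalia;p__Chordata;c__Aves;o__;f__Corvidae;g__;s__", "Aves"),
            ("k__Animalia;p__Chordata;c__Mammalia;o__Rodentia;f__Muridae;g__;s__", "Rodentia"),
            ("k__Animalia;p__Chordata;c__Mammalia;o__Primates;f__Hominidae;g__;s__", "Hominidae"),
            ("k__Animalia;p__Arthropoda;c__Malacostraca;o__Isopoda;f__;g__;s__", "other Arthropoda"),
            ("k__Animalia;p__Chordata;c__Reptilia;o__;f__;g__;s__", "other vertebrates"),
            ("k__Animalia;p__Nematoda;c__;o__;f__;g__;s__", "other invertebrates"),
        ],
    )
    def test_default_scheme(self, lineage, label):
        agg = AnimalAggregation.default()
        assert agg.label(Lineage.from_string(lineage)) == label


class TestNodeStatistics:
    def test_degree_counts_incident_edges(self, toy_network):
        assert node_degree(toy_network, "GenA") == 2
        assert node_degree(toy_network, "Host one") == 1

    def test_single_edge_wmd_is_its_weight_either_variant(self):
        net = BipartiteNetwork(
            kind="diet_plant",
            bird_nodes={"b": 1000},
            resource_nodes={"r": 500},
            edges=[("b", "r", 500.0)],
        )
        assert node_wmd(net, "r", "literal") == 500
        assert node_wmd(net, "r", "partner_weighted") == 500

    def test_literal_wmd_of_three_edges(self):
        net = BipartiteNetwork(
            kind="diet_plant",
            bird_nodes={"b1": 10, "b2": 20, "b3": 30},
            resource_nodes={"r": 900},
            edges=[("b1", "r", 150.0), ("b2", "r", 300.0), ("b3", "r", 450.0)],
        )
        assert node_wmd(net, "r", "literal") == pytest.approx(300.0)

    def test_partner_weighted_wmd(self):
        net = BipartiteNetwork(
            kind="diet_plant",
            bird_nodes={"b1": 1000, "b2": 3000},
            resource_nodes={"r": 600},
            edges=[("b1", "r", 100.0), ("b2", "r", 500.0)],
        )
        assert node_wmd(net, "r", "partner_weighted") == pytest.approx(400.0)

    def test_literal_wmd_equals_mean_incident_weight_on_random_networks(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            net = random_network(rng)
            for node in list(net.bird_nodes) + list(net.resource_nodes):
                weights = [w for _, w in net.incident(node)]
                assert node_wmd(net, node, "literal") == pytest.approx(
                    sum(weights) / len(weights)
                )

    def test_bipartite_handshake(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            net = random_network(rng)
            bird_sum = sum(node_degree(net, b) for b in net.bird_nodes)
            res_sum = sum(node_degree(net, r) for r in net.resource_nodes)
            assert bird_sum == res_sum == net.n_edges


class TestRankKeystones:
    def test_output_is_permutation_of_resource_nodes(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            net = random_network(rng)
            for by in ("degree", "wmd"):
                ranked = rank_keystones(net, by=by)
                assert sorted(s.node for s in ranked) == sorted(net.resource_nodes)

    def test_identical_statistics_fall_back_to_alphabetical(self):
        net = BipartiteNetwork(
            kind="diet_plant",
            bird_nodes={"b": 100},
            resource_nodes={"Zeta": 10, "Alpha": 10, "Mid": 10},
            edges=[("b", "Zeta", 50.0), ("b", "Alpha", 50.0), ("b", "Mid", 50.0)],
        )
        ranked = rank_keystones(net, by="degree")
        assert [s.node for s in ranked] == ["Alpha", "Mid", "Zeta"]

    def test_single_resource_ranks_first(self, toy_network):
        ranked = rank_keystones(toy_network, by="wmd")
        assert ranked[0].node == "GenA"

    def test_both_reports_top_k_intersection(self):
        # res_hi tops wMD, res_deg tops degree; only res_both is in both top-2
        net = BipartiteNetwork(
            kind="diet_plant",
            bird_nodes={"b1": 1, "b2": 1, "b3": 1},
            resource_nodes={"res_deg": 5, "res_hi": 5, "res_both": 5, "res_low": 5},
            edges=[
                ("b1", "res_deg", 10.0), ("b2", "res_deg", 10.0), ("b3", "res_deg", 10.0),
                ("b1", "res_hi", 900.0),
                ("b1", "res_both", 500.0), ("b2", "res_both", 500.0),
                ("b1", "res_low", 5.0),
            ],
        )
        both = rank_keystones(net, by="both", top_k=2)
        assert [s.node for s in both] == ["res_both"]

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            rank_keystones(BipartiteNetwork(kind="diet_plant"))

    def test_planted_dominant_genus_ranks_first_by_both(self, plant_table, assigned_samples):
        net = build_network("diet_plant", samples=assigned_samples, otu=plant_table, edge_min=0)
        for by in ("degree", "wmd"):
            assert rank_keystones(net, by=by)[0].node == "GenA"


class TestExport:
    def test_graphml_round_trip_identity(self, toy_network, tmp_path):
        p = tmp_path / "net.graphml"
        export_graph(toy_network, p, "graphml")
        back = import_graphml(p, kind="diet_plant")
        assert back.bird_nodes == toy_network.bird_nodes
        assert back.resource_nodes == toy_network.resource_nodes
        assert sorted(back.edges) == sorted(toy_network.edges)

    def test_empty_network_exports_valid_file(self, tmp_path):
        p = tmp_path / "empty.graphml"
        export_graph(BipartiteNetwork(kind="diet_plant"), p, "graphml")
        back = import_graphml(p, kind="diet_plant")
        assert not back.bird_nodes and not back.edges

    def test_edge_tsv_row_count_matches_edges(self, toy_network, tmp_path):
        p = tmp_path / "net.tsv"
        export_graph(toy_network, p, "edge_tsv")
        lines = p.read_text().strip().splitlines()
        assert lines[0] == "bird\tresource\tweight"
        assert len(lines) - 1 == toy_network.n_edges

    def test_random_network_graphml_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        net = random_network(rng)
        p = tmp_path / "r.graphml"
        export_graph(net, p, "graphml")
        back = import_graphml(p, kind="diet_plant")
        assert back.bird_nodes == net.bird_nodes
        assert back.resource_nodes == net.resource_nodes
        assert sorted(back.edges) == sorted(net.edges)
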