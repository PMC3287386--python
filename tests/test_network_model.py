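import pytest

from abmotif import (
    ConfigurationError,
    FunctionalAssociationNetwork,
    InputError,
    OrganismAnnotation,
    ParameterError,
    Phenotype,
    Vertex,
    build_divided_network,
    project_proteins_to_cogs,
    type_count,
)
from abmotif.synthetic_data import CohortParams, generate_cohort

from conftest import toy_networks


def two_org_networks(score_b: int):
    nets = [
        FunctionalAssociationNetwork.from_edge_list("A", [("c1", "c2", 900)]),
        FunctionalAssociationNetwork.from_edge_list("B", [("c1", "c2", score_b)]),
    ]
    anns = [OrganismAnnotation(o, Phenotype.POSITIVE) for o in "AB"]
    return nets, anns


class TestBuildDividedNetwork:
    def test_conserved_association_requires_edge_in_both(self):
        nets, anns = two_org_networks(900)
        net = build_divided_network(nets, anns, 800)
        assert net.summary()["vertices"] == 4
        assert len(net.intra_edges) == 2
        assert len(net.orthology_edges) == 2
        assert len(net.conserved_edges) == 2
        # the four vertices form a complete graph
        verts = net.vertices()
        assert all(
            u in net.adjacency[v] for v in verts for u in verts if u != v
        )

    def test_subthreshold_edge_kills_conservation(self):
        nets, anns = two_org_networks(700)
        net = build_divided_network(nets, anns, 800)
        assert net.summary()["vertices"] == 4
        assert len(net.intra_edges) == 1
        assert len(net.orthology_edges) == 2
        assert len(net.conserved_edges) == 0

    def test_single_organism_has_no_inter_edges(self):
        net = build_divided_network(
            [FunctionalAssociationNetwork.from_edge_list("A", [("c1", "c2", 900)])],
            [OrganismAnnotation("A", Phenotype.POSITIVE)],
            0,
        )
        assert not net.inter_edges

    def test_partition_property(self):
        nets, anns = toy_networks()
        net = build_divided_network(nets, anns, 800)
        assert sum(len(d) for d in net.divisions.values()) == len(net.vertices())
        assert len({v for d in net.divisions.values() for v in d}) == len(
            net.vertices()
        )

    def test_edge_side_invariants(self):
        nets, anns = toy_networks()
        net = build_divided_network(nets, anns, 800)
        assert all(a.organism_id == b.organism_id for a, b in net.intra_edges)
        assert all(
            a.organism_id != b.organism_id for a, b in net.inter_edges
        )
        assert all(a.cog_id == b.cog_id for a, b in net.orthology_edges)
        assert all(a.cog_id != b.cog_id for a, b in net.conserved_edges)

    def test_conservation_criteria_exhaustive(self):
        """(A,c1)-(B,c2) exists iff the c1-c2 association holds in both."""
        nets, anns = toy_networks()
        net = build_divided_network(nets, anns, 800)
        assoc = {
            org: {
                frozenset((a.cog_id, b.cog_id))
                for a, b in net.intra_edges
                if a.organism_id == org
            }
            for org in net.divisions
        }
        for a in net.divisions:
            for b in net.divisions:
                if a >= b:
                    continue
                for va in net.divisions[a]:
                    for vb in net.divisions[b]:
                        if va.cog_id == vb.cog_id:
                            continue
                        pair = frozenset((va.cog_id, vb.cog_id))
                        expected = pair in assoc[a] and pair in assoc[b]
                        edge = tuple(sorted((va, vb)))
                        assert (edge in net.conserved_edges) == expected

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_threshold_monotone_shrinkage(self, seed):
        cohort = generate_cohort(
            CohortParams(n_pos=3, n_neg=2, universe_size=8,
                         background_edge_prob=0.4, seed=seed)
        )
        prev = None
        for threshold in (300, 600, 900):
            net = build_divided_network(
                cohort.networks, cohort.annotations, threshold
            )
            if prev is not None:
                assert net.intra_edges <= prev.intra_edges
                assert net.conserved_edges <= prev.conserved_edges
                assert net.orthology_edges == prev.orthology_edges
            prev = net

    def test_inter_edge_count_bound(self):
        cohort = generate_cohort(
            CohortParams(n_pos=4, n_neg=3, universe_size=10,
                         background_edge_prob=0.5, seed=3)
        )
        net = build_divided_network(cohort.networks, cohort.annotations, 0)
        k = len(net.divisions)
        n_max = max(len(d) for d in net.divisions.values())
        assert len(net.inter_edges) <= k * (k - 1) // 2 * n_max**2

    def test_unknown_organism_is_configuration_error(self):
        nets, anns = toy_networks()
        with pytest.raises(ConfigurationError):
            build_divided_network(nets, anns[:2], 800)

    def test_duplicate_organism_is_configuration_error(self):
        nets, anns = toy_networks()
        with pytest.raises(ConfigurationError):
            build_divided_network(nets, anns + [anns[0]], 800)

    def test_bad_threshold_is_parameter_error(self):
        nets, anns = toy_networks()
        with pytest.raises(ParameterError):
            build_divided_network(nets, anns, 1000)


class TestTypeCount:
    def test_empty_set(self, toy_network):
        assert type_count(toy_network, set(), Phenotype.POSITIVE) == 0
        assert type_count(toy_network, set(), Phenotype.NEGATIVE) == 0

    def test_counts_organisms_not_vertices(self, toy_network):
        s = {Vertex("A", "c1"), Vertex("A", "c2")}
        assert type_count(toy_network, s, Phenotype.POSITIVE) == 1

    def test_mixed_types(self, toy_network):
        s = {Vertex("A", "c1"), Vertex("B", "c2"), Vertex("C", "c1")}
        assert type_count(toy_network, s, Phenotype.POSITIVE) == 2
        assert type_count(toy_network, s, Phenotype.NEGATIVE) == 1

    def test_foreign_vertex_is_input_error(self, toy_network):
        with pytest.raises(InputError):
            type_count(toy_network, {Vertex("Z", "c1")}, Phenotype.POSITIVE)
        with pytest.raises(InputError):
            type_count(toy_network, {Vertex("C", "c2")}, Phenotype.POSITIVE)


class TestProjection:
    def test_max_aggregation_over_protein_pairs(self):
        net, report = project_proteins_to_cogs(
            [("pA", "pB", 650), ("pC", "pD", 820)],
            {"pA": "c1", "pB": "c2", "pC": "c1", "pD": "c2"},
            organism_id="X",
        )
        assert net.edges == {("c1", "c2"): 820}
        assert not report.unmapped_proteins

    def test_all_unmapped_yields_empty_network_with_report(self):
        net, report = project_proteins_to_cogs(
            [("pA", "pB", 500)], {}, organism_id="X"
        )
        assert not net.cogs and not net.edges
        assert report.unmapped_proteins == {"pA", "pB"}
        assert report.n_dropped_unmapped_edges == 1

    def test_same_cog_pair_dropped_as_self_loop(self):
        net, report = project_proteins_to_cogs(
            [("pA", "pB", 500)], {"pA": "c1", "pB": "c1"}, organism_id="X"
        )
        assert not net.edges
        assert net.cogs == {"c1"}
        assert report.n_dropped_self_pairs == 1

    def test_malformed_score_is_parse_error(self):
        from abmotif import ParseError

        with pytest.raises(ParseError):
            project_proteins_to_cogs(
                [("pA", "pB", "high")], {"pA": "c1", "pB": "c2"}
            )


class TestFunctionalAssociationNetwork:
    def test_reversed_duplicates_merge_with_max(self):
        net = FunctionalAssociationNetwork.from_edge_list(
            "X", [("b", "a", 300), ("a", "b", 700)]
        )
        assert net.edges == {("a", "b"): 700}

    def test_score_out_of_range_rejected(self):
        with pytest.raises(InputError):
            FunctionalAssociationNetwork.from_edge_list("X", [("a", "b", 1000)])

    def test_isolated_cogs_are_kept(self):
        net = FunctionalAssociationNetwork.from_edge_list(
            "X", [("a", "b", 500)], extra_cogs=["lonely"]
        )
        assert "lonely" in net.cogs
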