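import pytest

from abmotif import (
    BoundMode,
    ParameterError,
    SizeGuardError,
    benchmark_bounds,
    build_divided_network,
    enumerate_ab_cliques,
    oracle_ab_cliques,
    scan_parameter_grid,
)
from abmotif.network_model import Vertex

from conftest import nonproduct_network, random_small_network, tripartite_network

MODES = [BoundMode.NONE, BoundMode.BETA_ONLY, BoundMode.ALPHA_BETA]


def as_sets(modules):
    return {m.vertices for m in modules}


class TestToyCohort:
    def test_strict_criterion_finds_conserved_pair(self, toy_network):
        mods = enumerate_ab_cliques(toy_network, 2, 0)
        assert [(sorted(m.cog_set), sorted(m.organisms)) for m in mods] == [
            (["c1", "c2"], ["A", "B"])
        ]

    def test_relaxed_beta_admits_shared_cog(self, toy_network):
        mods = enumerate_ab_cliques(toy_network, 2, 1)
        assert [(sorted(m.cog_set), sorted(m.organisms)) for m in mods] == [
            (["c1", "c2"], ["A", "B"]),
            (["c1"], ["A", "B", "C"]),
        ]

    @pytest.mark.parametrize("beta", [0, 1])
    def test_unreachable_alpha_yields_empty(self, toy_network, beta):
        assert enumerate_ab_cliques(toy_network, 3, beta) == []

    def test_type_counts_on_output(self, toy_network):
        (mod,) = enumerate_ab_cliques(toy_network, 2, 0)
        assert mod.alpha_count == 2 and mod.beta_count == 0
        assert mod.is_product

    def test_negative_parameters_rejected(self, toy_network):
        with pytest.raises(ParameterError):
            enumerate_ab_cliques(toy_network, -1, 0)
        with pytest.raises(ParameterError):
            enumerate_ab_cliques(toy_network, 0, -1)


class TestWorstCaseFamily:
    @pytest.mark.parametrize("k,expected", [(2, 9), (3, 27), (4, 81)])
    def test_complete_multipartite_clique_count(self, k, expected):
        net = tripartite_network(k_parts=k)
        assert len(enumerate_ab_cliques(net, 0, 0)) == expected

    def test_oracle_agrees_on_tripartite(self):
        net = tripartite_network()
        assert len(oracle_ab_cliques(net, 0, 0)) == 27


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(30))
    def test_all_modes_match_oracle(self, seed):
        net = random_small_network(seed)
        n_pos, n_neg = net.n_positive, net.n_negative
        full = oracle_ab_cliques(net, 0, n_neg)
        for alpha in range(n_pos + 1):
            for beta in range(n_neg + 1):
                expected = {
                    m.vertices
                    for m in full
                    if m.alpha_count >= alpha and m.beta_count <= beta
                }
                for mode in MODES:
                    got = enumerate_ab_cliques(net, alpha, beta, mode)
                    assert as_sets(got) == expected, (seed, alpha, beta, mode)

    @pytest.mark.parametrize("seed", range(10))
    def test_anti_monotonicity(self, seed):
        net = random_small_network(seed + 500)
        n_neg = net.n_negative
        for alpha in range(net.n_positive):
            assert as_sets(enumerate_ab_cliques(net, alpha + 1, n_neg)) <= as_sets(
                enumerate_ab_cliques(net, alpha, n_neg)
            )
        for beta in range(n_neg):
            assert as_sets(enumerate_ab_cliques(net, 0, beta)) <= as_sets(
                enumerate_ab_cliques(net, 0, beta + 1)
            )

    @pytest.mark.parametrize("seed", range(10))
    def test_outputs_are_maximal_and_unique(self, seed):
        net = random_small_network(seed + 900)
        mods = enumerate_ab_cliques(net, 0, net.n_negative)
        seen = set()
        all_vertices = set(net.vertices())
        for m in mods:
            assert m.vertices not in seen
            seen.add(m.vertices)
            for extra in all_vertices - m.vertices:
                assert not all(
                    extra in net.adjacency[v] or extra == v for v in m.vertices
                ), f"clique {m.vertices} extendable by {extra}"

    def test_oracle_size_guard(self):
        net = random_small_network(0)
        with pytest.raises(SizeGuardError):
            oracle_ab_cliques(net, 0, net.n_negative, max_vertices=1)

    def test_empty_network(self):
        from abmotif import OrganismAnnotation, Phenotype
        from abmotif.network_model import FunctionalAssociationNetwork

        net = build_divided_network(
            [FunctionalAssociationNetwork("A", frozenset(), {})],
            [OrganismAnnotation("A", Phenotype.POSITIVE)],
            0,
        )
        assert enumerate_ab_cliques(net, 0, 0) == []
        assert oracle_ab_cliques(net, 0, 0) == []


class TestNonProductCliques:
    def test_chained_conserved_associations_break_product_structure(self):
        """Three organisms can each contribute one non-orthologous vertex."""
        net = nonproduct_network()
        mods = enumerate_ab_cliques(net, 0, 0)
        assert as_sets(mods) == as_sets(oracle_ab_cliques(net, 0, 0))
        target = frozenset(
            {Vertex("A", "x"), Vertex("B", "y"), Vertex("C", "z")}
        )
        (found,) = [m for m in mods if m.vertices == target]
        assert not found.is_product
        assert found.alpha_count == 3
        # product cliques coexist in the same output
        assert any(m.is_product and len(m.cog_set) == 2 for m in mods)


class TestParameterGrid:
    def test_toy_grid_cells(self, toy_network):
        grid = scan_parameter_grid(toy_network)
        assert grid.loc[2, 1] == 2
        assert grid.loc[2, 0] == 1
        assert grid.loc[0, 1] == len(oracle_ab_cliques(toy_network, 0, 1))

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_grid_monotone_with_max_at_loosest(self, seed):
        net = random_small_network(seed)
        grid = scan_parameter_grid(net)
        total = len(enumerate_ab_cliques(net, 0, net.n_negative))
        assert grid.loc[0, net.n_negative] == total
        assert grid.values.max() == grid.loc[0, net.n_negative]
        # non-increasing in alpha (down each column)
        assert (grid.diff(axis=0).fillna(0) <= 0).all().all()
        # non-decreasing in beta (across each row)
        assert (grid.diff(axis=1).fillna(0) >= 0).all().all()


class TestBounds:
    @pytest.mark.parametrize("seed", [21, 22, 23, 24])
    def test_node_counts_ordered_and_outputs_identical(self, seed):
        net = random_small_network(seed)
        alpha = max(1, net.n_positive - 1)
        bench = benchmark_bounds(net, alpha, 0)
        assert (
            bench.nodes["alpha_beta"]
            <= bench.nodes["beta_only"]
            <= bench.nodes["none"]
        )

    def test_bounds_never_trigger_in_all_cliques_mode(self):
        net = random_small_network(42)
        bench = benchmark_bounds(net, 0, net.n_negative)
        assert len(set(bench.nodes.values())) == 1

    def test_bounds_actually_prune_somewhere(self):
        # a strict criterion on a noisy cohort must cut the search tree
        pruned = False
        for seed in range(40):
            net = random_small_network(seed)
            if net.n_positive < 2 or net.n_negative < 1:
                continue
            bench = benchmark_bounds(net, net.n_positive, 0)
            if bench.nodes["alpha_beta"] < bench.nodes["none"]:
                pruned = True
                break
        assert pruned
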