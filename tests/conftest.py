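import pytest

from abmotif import (
    CohortParams,
    FunctionalAssociationNetwork,
    OrganismAnnotation,
    Phenotype,
    build_divided_network,
    generate_cohort,
)


def toy_networks():
    """A(+), B(+) each with association c1-c2 (score 900); C(-) has only c1."""
    nets = [
        FunctionalAssociationNetwork.from_edge_list(o, [("c1", "c2", 900)])
        for o in "AB"
    ]
    nets.append(FunctionalAssociationNetwork("C", frozenset({"c1"}), {}))
    anns = [
        OrganismAnnotation("A", Phenotype.POSITIVE),
        OrganismAnnotation("B", Phenotype.POSITIVE),
        OrganismAnnotation("C", Phenotype.NEGATIVE),
    ]
    return nets, anns


@pytest.fixture
def toy_network():
    nets, anns = toy_networks()
    return build_divided_network(nets, anns, 800)


def tripartite_network(k_parts: int = 3, part_size: int = 3):
    """Single positive organism, complete multipartite association network.

    The classic worst-case family: part_size^k_parts maximal cliques.
    """
    parts = [
        [f"p{i}c{j}" for j in range(part_size)] for i in range(k_parts)
    ]
    edges = []
    for i in range(k_parts):
        for j in range(i + 1, k_parts):
            for x in parts[i]:
                for y in parts[j]:
                    edges.append((x, y, 900))
    net = FunctionalAssociationNetwork.from_edge_list("X", edges)
    ann = OrganismAnnotation("X", Phenotype.POSITIVE)
    return build_divided_network([net], [ann], 700)


def random_small_network(seed: int, edge_threshold: int = 500):
    """Random cohort small enough for the exhaustive oracle.

    Sizes are drawn from the seed itself: up to 6 organisms over up to 8
    COGs, dense enough that maximal cliques of every shape appear.
    """
    import numpy as np

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(99,)))
    n_pos = int(rng.integers(1, 4))
    n_neg = int(rng.integers(0, 4))
    params = CohortParams(
        n_pos=n_pos,
        n_neg=n_neg,
        universe_size=int(rng.integers(4, 9)),
        presence_prob=0.7,
        background_edge_prob=0.4,
        background_score_range=(1, 999),
        seed=seed,
    )
    cohort = generate_cohort(params)
    return build_divided_network(
        cohort.networks, cohort.annotations, edge_threshold
    )


def nonproduct_network():
    """Smallest known divided network with a non-product maximal clique.

    Three organisms share COGs {x, y, z}; their association edges are the
    three distinct 2-subsets, so {(A,x), (B,y), (C,z)} is a maximal clique
    chained purely through conserved-association edges.
    """
    intra = {"A": [("x", "y"), ("x", "z")],
             "B": [("x", "y"), ("y", "z")],
             "C": [("x", "z"), ("y", "z")]}
    nets = [
        FunctionalAssociationNetwork.from_edge_list(
            org, [(a, b, 900) for a, b in pairs], extra_cogs=["x", "y", "z"]
        )
        for org, pairs in intra.items()
    ]
    anns = [OrganismAnnotation(o, Phenotype.POSITIVE) for o in "ABC"]
    return build_divided_network(nets, anns, 700)
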