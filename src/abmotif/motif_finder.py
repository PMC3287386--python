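"""(alpha, beta)-clique enumeration.

A maximal clique S of the two-typed, divided network is an *(alpha,
beta)-clique* when it touches at least ``alpha`` phenotype-positive organisms
and at most ``beta`` phenotype-negative organisms (type counts c(S, p) and
c(S, n)). The enumerator is a pivotless Bron--Kerbosch recursion over the
whole network with two optional pruning bounds:

* **beta bound** — if adding the current candidate already pushes the
  negative type-count above ``beta``, the subtree is cut: type counts only
  grow along a branch, so no descendant can recover.
* **alpha bound** — if the positive organisms reachable from the extended
  clique plus its surviving candidates number fewer than ``alpha``, the
  subtree is cut: that union upper-bounds c(., p) for every descendant.

Both bounds are pure pruning: for any ``bound_mode`` the output is exactly
the set of maximal cliques of the network satisfying the criterion. Pruned
candidates still migrate from CAND to NOT, so the NOT-empty test at the
leaves keeps certifying maximality. Candidate order is the lexicographic
(organism, COG) vertex order, which makes the search tree — and therefore
node counts and output order — deterministic.

At (alpha=0, beta=#negatives) the criterion is vacuous and the enumeration
degenerates to plain maximal-clique enumeration of the divided network.

Enumerated cliques usually factor as (organism set) x (COG set) — one
orthologous sub-clique per organism — but the edge construction also admits
rare maximal cliques without this product structure (organisms contributing
non-orthologous sub-cliques chained through conserved-association edges).
``ModuleClique`` therefore keeps the exact vertex set and exposes
``is_product``.
"""

from __future__ import annotations

import enum
import sys
import time
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import networkx as nx

from .errors import ParameterError, SizeGuardError
from .network_model import DividedNetwork, Phenotype, Vertex

ORACLE_MAX_VERTICES = 60


class BoundMode(enum.Enum):
    """Which of the two search bounds the enumerator applies."""

    NONE = "none"
    BETA_ONLY = "beta_only"
    ALPHA_BETA = "alpha_beta"

    @classmethod
    def parse(cls, text: "str | BoundMode") -> "BoundMode":
        if isinstance(text, BoundMode):
            return text
        aliases = {
            "none": cls.NONE,
            "beta": cls.BETA_ONLY,
            "beta_only": cls.BETA_ONLY,
            "beta-only": cls.BETA_ONLY,
            "alpha_beta": cls.ALPHA_BETA,
            "alpha-beta": cls.ALPHA_BETA,
        }
        try:
            return aliases[text.strip().lower()]
        except KeyError:
            raise ParameterError(f"unknown bound mode {text!r}") from None


@dataclass(frozen=True, eq=False)
class ModuleClique:
    """One enumerated module: a maximal clique of the divided network.

    Identity (equality/hashing) is by the exact vertex set. ``cog_set`` is
    the union of COGs over all member vertices and equals each organism's
    contribution whenever ``is_product`` is true. Scores default to ``None``
    until the significance / phylogeny stages attach them.
    """

    vertices: frozenset[Vertex]
    cog_set: frozenset[str]
    positive_orgs: frozenset[str]
    negative_orgs: frozenset[str]
    is_product: bool
    p_value: float | None = None
    phylo_score: float | None = None

    @property
    def alpha_count(self) -> int:
        return len(self.positive_orgs)

    @property
    def beta_count(self) -> int:
        return len(self.negative_orgs)

    @property
    def organisms(self) -> frozenset[str]:
        return self.positive_orgs | self.negative_orgs

    def __eq__(self, other) -> bool:
        if not isinstance(other, ModuleClique):
            return NotImplemented
        return self.vertices == other.vertices

    def __hash__(self) -> int:
        return hash(self.vertices)

    @classmethod
    def from_vertices(
        cls, vertices: Iterable[Vertex], network: DividedNetwork
    ) -> "ModuleClique":
        vset = frozenset(vertices)
        orgs = {v.organism_id for v in vset}
        cogs = frozenset(v.cog_id for v in vset)
        pos = frozenset(
            o for o in orgs if network.organism_types[o] is Phenotype.POSITIVE
        )
        neg = frozenset(
            o for o in orgs if network.organism_types[o] is Phenotype.NEGATIVE
        )
        product = vset == frozenset(Vertex(o, c) for o in orgs for c in cogs)
        return cls(
            vertices=vset,
            cog_set=cogs,
            positive_orgs=pos,
            negative_orgs=neg,
            is_product=product,
        )

    def with_scores(
        self, p_value: float | None = None, phylo_score: float | None = None
    ) -> "ModuleClique":
        updates = {}
        if p_value is not None:
            updates["p_value"] = p_value
        if phylo_score is not None:
            updates["phylo_score"] = phylo_score
        return replace(self, **updates)

    def canonical_key(self):
        return (
            -len(self.cog_set),
            tuple(sorted(self.cog_set)),
            tuple(sorted(self.organisms)),
            tuple(sorted(self.vertices)),
        )


def sort_modules(modules: Iterable[ModuleClique]) -> list[ModuleClique]:
    """Canonical order: larger COG sets first, then lexicographic."""
    return sorted(modules, key=ModuleClique.canonical_key)


def _validate_params(network: DividedNetwork, alpha: int, beta: int) -> None:
    # alpha above the positive-organism count is satisfiable by nothing and
    # legitimately yields an empty result; only negative values are errors
    if alpha < 0:
        raise ParameterError(f"alpha={alpha} must be non-negative")
    if beta < 0:
        raise ParameterError(f"beta={beta} must be non-negative")


@dataclass
class SearchStats:
    """Deterministic node-expansion count plus informational wall time."""

    nodes: int
    seconds: float


def _search(
    network: DividedNetwork, alpha: int, beta: int, mode: BoundMode
) -> tuple[list[ModuleClique], SearchStats]:
    """Bounded Bron--Kerbosch over a bitset adjacency. Internal engine."""
    verts = network.vertices()
    n = len(verts)
    index = {v: i for i, v in enumerate(verts)}
    adj = [0] * n
    for i, v in enumerate(verts):
        for u in network.adjacency[v]:
            adj[i] |= 1 << index[u]
    organisms = sorted(network.divisions)
    org_index = {o: k for k, o in enumerate(organisms)}
    org_of = [org_index[v.organism_id] for v in verts]
    is_neg = [
        network.organism_types[o] is Phenotype.NEGATIVE for o in organisms
    ]
    # vertices are sorted by organism, so each organism occupies one
    # contiguous bit segment; these masks project a vertex set onto organisms
    seg_mask = [0] * len(organisms)
    for i, oi in enumerate(org_of):
        seg_mask[oi] |= 1 << i
    pos_indices = [k for k, neg in enumerate(is_neg) if not neg and seg_mask[k]]

    use_beta = mode in (BoundMode.BETA_ONLY, BoundMode.ALPHA_BETA)
    use_alpha = mode is BoundMode.ALPHA_BETA

    clique: list[int] = []
    org_mult = [0] * len(organisms)
    results: list[list[Vertex]] = []
    node_count = 0

    def expand(cand: int, banned: int, n_pos_in: int, n_neg_in: int) -> None:
        nonlocal node_count
        node_count += 1
        if cand == 0:
            # `clique` must be non-empty: the empty set is not a clique even
            # in an edgeless or empty network
            if clique and banned == 0 and n_pos_in >= alpha and n_neg_in <= beta:
                results.append([verts[i] for i in clique])
            return
        rest = cand
        while rest:
            low = rest & -rest
            rest ^= low
            i = low.bit_length() - 1
            oi = org_of[i]
            entering = org_mult[oi] == 0
            neg_entering = entering and is_neg[oi]
            if not (use_beta and neg_entering and n_neg_in >= beta):
                newcand = cand & adj[i]
                recurse = True
                if use_alpha:
                    # upper bound on c(., p) for any descendant: positives
                    # already in the clique plus those reachable from the
                    # extended candidate set (early exit at alpha)
                    reach = newcand | low
                    ub = n_pos_in
                    if ub < alpha:
                        for k in pos_indices:
                            if org_mult[k] == 0 and seg_mask[k] & reach:
                                ub += 1
                                if ub >= alpha:
                                    break
                    recurse = ub >= alpha
                if recurse:
                    org_mult[oi] += 1
                    clique.append(i)
                    expand(
                        newcand,
                        banned & adj[i],
                        n_pos_in + (1 if entering and not is_neg[oi] else 0),
                        n_neg_in + (1 if neg_entering else 0),
                    )
                    clique.pop()
                    org_mult[oi] -= 1
            # lines 17-18: current leaves CAND for NOT even when pruned,
            # so later leaves still see it for the maximality test
            cand ^= low
            banned |= low

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 4 * n + 100))
    t0 = time.perf_counter()
    try:
        expand((1 << n) - 1 if n else 0, 0, 0, 0)
    finally:
        sys.setrecursionlimit(old_limit)
    elapsed = time.perf_counter() - t0

    modules = sort_modules(
        ModuleClique.from_vertices(vs, network) for vs in results
    )
    return modules, SearchStats(nodes=node_count, seconds=elapsed)


def enumerate_ab_cliques(
    network: DividedNetwork,
    alpha: int,
    beta: int,
    bound_mode: "str | BoundMode" = BoundMode.ALPHA_BETA,
) -> list[ModuleClique]:
    """Enumerate all (alpha, beta)-cliques of the divided network.

    Returns, in canonical sorted order, exactly the maximal cliques S of the
    whole network with c(S, positive) >= alpha and c(S, negative) <= beta.
    The ``bound_mode`` only affects how much of the search tree is pruned,
    never the result.
    """
    _validate_params(network, alpha, beta)
    modules, _ = _search(network, alpha, beta, BoundMode.parse(bound_mode))
    return modules


def oracle_ab_cliques(
    network: DividedNetwork,
    alpha: int,
    beta: int,
    max_vertices: int = ORACLE_MAX_VERTICES,
) -> list[ModuleClique]:
    """Reference enumeration for tests: independent of the bounded search.

    Runs networkx's maximal-clique enumeration on the divided network and
    filters by the (alpha, beta)-criterion afterwards. Guarded to small
    networks; not for production use.
    """
    _validate_params(network, alpha, beta)
    verts = network.vertices()
    if len(verts) > max_vertices:
        raise SizeGuardError(
            f"oracle refused: {len(verts)} vertices > guard {max_vertices}"
        )
    graph = nx.Graph()
    graph.add_nodes_from(verts)
    for v in verts:
        for u in network.adjacency[v]:
            graph.add_edge(v, u)
    out = []
    for raw in nx.find_cliques(graph):
        module = ModuleClique.from_vertices(raw, network)
        if module.alpha_count >= alpha and module.beta_count <= beta:
            out.append(module)
    return sort_modules(out)


def scan_parameter_grid(
    network: DividedNetwork,
    alphas: Sequence[int] | None = None,
    betas: Sequence[int] | None = None,
):
    """Clique counts over a grid of (alpha, beta) values.

    Enumerates the full maximal-clique set once (criterion disabled) and
    tabulates, for every grid cell, how many cliques satisfy it. Returns a
    pandas DataFrame indexed by alpha with beta columns. Counts are
    non-increasing in alpha, non-decreasing in beta, with the maximum (the
    total number of maximal cliques) at (0, #negatives).
    """
    import pandas as pd

    if alphas is None:
        alphas = range(network.n_positive + 1)
    if betas is None:
        betas = range(network.n_negative + 1)
    alphas = list(alphas)
    betas = list(betas)
    if any(a < 0 for a in alphas) or any(b < 0 for b in betas):
        raise ParameterError("grid values must be non-negative")

    all_cliques = enumerate_ab_cliques(
        network, 0, network.n_negative, BoundMode.ALPHA_BETA
    )
    grid = pd.DataFrame(0, index=alphas, columns=betas, dtype=int)
    for module in all_cliques:
        for a in alphas:
            if module.alpha_count < a:
                continue
            for b in betas:
                if module.beta_count <= b:
                    grid.loc[a, b] += 1
    grid.index.name = "alpha"
    grid.columns.name = "beta"
    return grid


@dataclass
class BoundBenchmark:
    """Per-mode node counts and wall times for one (alpha, beta) setting."""

    alpha: int
    beta: int
    nodes: dict[str, int]
    seconds: dict[str, float]
    modules: list[ModuleClique]


def benchmark_bounds(
    network: DividedNetwork, alpha: int, beta: int
) -> BoundBenchmark:
    """Run all three bound modes, check they agree, report search effort.

    Node-expansion counts are deterministic and satisfy
    ``alpha_beta <= beta_only <= none``; wall times are informational only.
    """
    _validate_params(network, alpha, beta)
    nodes: dict[str, int] = {}
    seconds: dict[str, float] = {}
    outputs: dict[str, list[ModuleClique]] = {}
    for mode in BoundMode:
        modules, stats = _search(network, alpha, beta, mode)
        nodes[mode.value] = stats.nodes
        seconds[mode.value] = stats.seconds
        outputs[mode.value] = modules
    reference = outputs[BoundMode.NONE.value]
    for mode in (BoundMode.BETA_ONLY, BoundMode.ALPHA_BETA):
        if outputs[mode.value] != reference:
            raise AssertionError(
                f"bound mode {mode.value} changed the output set"
            )
    return BoundBenchmark(
        alpha=alpha, beta=beta, nodes=nodes, seconds=seconds, modules=reference
    )
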