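"""Two-typed, divided network model.

A cohort of per-organism protein functional-association networks (STRING-style
weighted COG–COG graphs) is combined into a single *divided network*: the
vertex set is partitioned into one division per organism, each division
labelled *positive* (phenotype-expressing) or *negative*. Vertices are
(organism, COG) pairs. Edges come in three flavours:

* **intra-organismal** — a functional association between two COGs of one
  organism whose combined score passed the edge threshold;
* **orthology** (inter-organismal) — (A, c)–(B, c) whenever distinct organisms
  A and B both contain COG c;
* **conserved-association** (inter-organismal) — (A, c1)–(B, c2) with
  c1 != c2, present if and only if the association c1–c2 exists (above
  threshold) in *both* A and B.

A functional module conserved across organisms then shows up as a maximal
clique of this single graph, which is what the motif finder enumerates.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, NamedTuple, Sequence

from .errors import ConfigurationError, InputError, ParameterError, ParseError

MAX_SCORE = 999


class Phenotype(enum.Enum):
    """Binary organism type: does the organism express the target phenotype?"""

    POSITIVE = "positive"
    NEGATIVE = "negative"

    @classmethod
    def parse(cls, text: str) -> "Phenotype":
        t = text.strip().lower()
        if t in ("positive", "pos", "+", "1", "true"):
            return cls.POSITIVE
        if t in ("negative", "neg", "-", "0", "false"):
            return cls.NEGATIVE
        raise ParseError(f"unrecognised phenotype value {text!r}")


@dataclass(frozen=True)
class OrganismAnnotation:
    """An organism id together with its phenotype type."""

    organism_id: str
    phenotype: Phenotype


class Vertex(NamedTuple):
    """A vertex of the divided network: one COG inside one organism.

    The tuple order (organism, cog) gives the total lexicographic order used
    wherever the algorithms need a deterministic vertex ordering.
    """

    organism_id: str
    cog_id: str


def _edge_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class FunctionalAssociationNetwork:
    """One organism's COG-level functional association network.

    ``edges`` maps sorted COG-id pairs to integer combined scores in
    [0, 999]. Isolated COGs (present in the organism but without any scored
    association) are legitimate members of ``cogs``.
    """

    organism_id: str
    cogs: frozenset[str]
    edges: Mapping[tuple[str, str], int]

    def __post_init__(self):
        for (a, b), score in self.edges.items():
            if a == b:
                raise InputError(f"self-loop on {a!r} in {self.organism_id!r}")
            if a > b:
                raise InputError(f"edge key {(a, b)!r} not sorted")
            if a not in self.cogs or b not in self.cogs:
                raise InputError(
                    f"edge {(a, b)!r} endpoint missing from cogs of "
                    f"{self.organism_id!r}"
                )
            if not isinstance(score, int) or not 0 <= score <= MAX_SCORE:
                raise InputError(
                    f"score {score!r} for edge {(a, b)!r} outside [0, {MAX_SCORE}]"
                )

    @classmethod
    def from_edge_list(
        cls,
        organism_id: str,
        edge_list: Iterable[tuple[str, str, int]],
        extra_cogs: Iterable[str] = (),
    ) -> "FunctionalAssociationNetwork":
        """Build from (cog, cog, score) triples.

        Reversed duplicates are merged keeping the maximum score; self-loops
        are dropped.
        """
        edges: dict[tuple[str, str], int] = {}
        cogs = set(extra_cogs)
        for a, b, score in edge_list:
            cogs.add(a)
            cogs.add(b)
            if a == b:
                continue
            key = _edge_key(a, b)
            if not 0 <= int(score) <= MAX_SCORE:
                raise InputError(f"score {score!r} outside [0, {MAX_SCORE}]")
            edges[key] = max(edges.get(key, 0), int(score))
        return cls(organism_id, frozenset(cogs), edges)

    def thresholded_pairs(self, threshold: int) -> set[tuple[str, str]]:
        """Sorted COG pairs whose association score is >= threshold."""
        return {pair for pair, s in self.edges.items() if s >= threshold}


@dataclass(frozen=True)
class ProjectionReport:
    """Bookkeeping from a protein->COG projection."""

    organism_id: str
    n_protein_edges: int
    unmapped_proteins: frozenset[str]
    n_dropped_self_pairs: int
    n_dropped_unmapped_edges: int


def project_proteins_to_cogs(
    protein_edges: Sequence[tuple[str, str, int]],
    mapping: Mapping[str, str],
    organism_id: str = "",
) -> tuple[FunctionalAssociationNetwork, ProjectionReport]:
    """Collapse a protein-level network onto COG identifiers.

    Each protein is replaced by its orthology class (COG); protein pairs whose
    endpoints map to the same COG become self-loops and are dropped, and
    duplicate COG pairs keep the maximum combined score over all contributing
    protein pairs. Proteins absent from ``mapping`` are dropped and listed in
    the report.
    """
    unmapped: set[str] = set()
    cogs: set[str] = set()
    edges: dict[tuple[str, str], int] = {}
    n_self = 0
    n_unmapped_edges = 0
    for p1, p2, score in protein_edges:
        try:
            score = int(score)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"malformed score {score!r}") from exc
        if not 0 <= score <= MAX_SCORE:
            raise ParseError(f"score {score!r} outside [0, {MAX_SCORE}]")
        c1 = mapping.get(p1)
        c2 = mapping.get(p2)
        if c1 is None:
            unmapped.add(p1)
        if c2 is None:
            unmapped.add(p2)
        if c1 is None or c2 is None:
            n_unmapped_edges += 1
            continue
        cogs.add(c1)
        cogs.add(c2)
        if c1 == c2:
            n_self += 1
            continue
        key = _edge_key(c1, c2)
        edges[key] = max(edges.get(key, 0), score)
    network = FunctionalAssociationNetwork(organism_id, frozenset(cogs), edges)
    report = ProjectionReport(
        organism_id=organism_id,
        n_protein_edges=len(protein_edges),
        unmapped_proteins=frozenset(unmapped),
        n_dropped_self_pairs=n_self,
        n_dropped_unmapped_edges=n_unmapped_edges,
    )
    return network, report


@dataclass
class DividedNetwork:
    """The combined two-typed, divided network of a cohort.

    ``divisions`` partition the vertex set by organism; ``organism_types``
    label each division positive or negative. The three edge sets are kept
    separately (sorted 2-tuples of :class:`Vertex`), and a symmetric adjacency
    map is built once for the clique search, which treats it as read-only.
    """

    divisions: dict[str, frozenset[Vertex]]
    organism_types: dict[str, Phenotype]
    intra_edges: frozenset[tuple[Vertex, Vertex]]
    orthology_edges: frozenset[tuple[Vertex, Vertex]]
    conserved_edges: frozenset[tuple[Vertex, Vertex]]
    edge_threshold: int = 0
    _adjacency: dict[Vertex, set[Vertex]] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        if self._adjacency is None:
            adj: dict[Vertex, set[Vertex]] = {v: set() for v in self.vertices()}
            for edge_set in (self.intra_edges, self.orthology_edges, self.conserved_edges):
                for a, b in edge_set:
                    adj[a].add(b)
                    adj[b].add(a)
            self._adjacency = adj

    # -- basic views -------------------------------------------------------

    def vertices(self) -> list[Vertex]:
        """All vertices in lexicographic order."""
        return sorted(v for div in self.divisions.values() for v in div)

    @property
    def adjacency(self) -> dict[Vertex, set[Vertex]]:
        return self._adjacency

    @property
    def inter_edges(self) -> frozenset[tuple[Vertex, Vertex]]:
        return self.orthology_edges | self.conserved_edges

    def organisms_of_type(self, t: Phenotype) -> frozenset[str]:
        return frozenset(o for o, ty in self.organism_types.items() if ty is t)

    @property
    def n_positive(self) -> int:
        return len(self.organisms_of_type(Phenotype.POSITIVE))

    @property
    def n_negative(self) -> int:
        return len(self.organisms_of_type(Phenotype.NEGATIVE))

    def summary(self) -> dict[str, int]:
        return {
            "organisms": len(self.divisions),
            "positive_organisms": self.n_positive,
            "negative_organisms": self.n_negative,
            "vertices": sum(len(d) for d in self.divisions.values()),
            "intra_edges": len(self.intra_edges),
            "orthology_edges": len(self.orthology_edges),
            "conserved_association_edges": len(self.conserved_edges),
            "edge_threshold": self.edge_threshold,
        }


def type_count(
    network: DividedNetwork, vertex_set: Iterable[Vertex], t: Phenotype
) -> int:
    """Type-count c(S, t): organisms of type ``t`` touched by ``vertex_set``.

    An organism counts once as soon as any one of its vertices belongs to the
    set; this is the membership test the (alpha, beta)-criterion relies on,
    because each organism contributes at most one sub-clique to any clique of
    the divided network.
    """
    orgs: set[str] = set()
    for v in vertex_set:
        division = network.divisions.get(v.organism_id)
        if division is None or v not in division:
            raise InputError(f"vertex {v!r} not in network")
        orgs.add(v.organism_id)
    return sum(1 for o in orgs if network.organism_types[o] is t)


def build_divided_network(
    networks: Sequence[FunctionalAssociationNetwork],
    annotations: Sequence[OrganismAnnotation],
    edge_threshold: int,
) -> DividedNetwork:
    """Combine per-organism networks into the two-typed, divided network.

    Intra edges are exactly the input associations with score >= the
    threshold. Orthology edges connect equal COGs across every organism pair
    (no score condition: COG co-presence alone). Conserved-association edges
    (A, c1)-(B, c2), c1 != c2, exist iff the thresholded association c1-c2 is
    present in both A and B.
    """
    if not 0 <= edge_threshold <= MAX_SCORE:
        raise ParameterError(
            f"edge_threshold {edge_threshold!r} outside [0, {MAX_SCORE}]"
        )
    ann_map: dict[str, Phenotype] = {}
    for ann in annotations:
        if ann.organism_id in ann_map:
            raise ConfigurationError(f"duplicate organism id {ann.organism_id!r}")
        ann_map[ann.organism_id] = ann.phenotype
    seen_orgs: set[str] = set()
    for net in networks:
        if net.organism_id in seen_orgs:
            raise ConfigurationError(
                f"duplicate network for organism {net.organism_id!r}"
            )
        seen_orgs.add(net.organism_id)
        if net.organism_id not in ann_map:
            raise ConfigurationError(
                f"organism {net.organism_id!r} has a network but no phenotype "
                "annotation"
            )

    divisions: dict[str, frozenset[Vertex]] = {}
    organism_types: dict[str, Phenotype] = {}
    intra: set[tuple[Vertex, Vertex]] = set()
    # per organism: thresholded COG pairs, for the conserved-association rule
    assoc: dict[str, set[tuple[str, str]]] = {}
    cog_presence: dict[str, set[str]] = {}  # cog -> organisms containing it

    for net in networks:
        org = net.organism_id
        organism_types[org] = ann_map[org]
        divisions[org] = frozenset(Vertex(org, c) for c in net.cogs)
        pairs = net.thresholded_pairs(edge_threshold)
        assoc[org] = pairs
        for c1, c2 in pairs:
            intra.add((Vertex(org, c1), Vertex(org, c2)))
        for c in net.cogs:
            cog_presence.setdefault(c, set()).add(org)

    orthology: set[tuple[Vertex, Vertex]] = set()
    for cog, orgs in cog_presence.items():
        for a, b in combinations(sorted(orgs), 2):
            orthology.add((Vertex(a, cog), Vertex(b, cog)))

    conserved: set[tuple[Vertex, Vertex]] = set()
    for a, b in combinations(sorted(assoc), 2):
        for c1, c2 in assoc[a] & assoc[b]:
            e1 = (Vertex(a, c1), Vertex(b, c2))
            e2 = (Vertex(a, c2), Vertex(b, c1))
            conserved.add(tuple(sorted(e1)))  # type: ignore[arg-type]
            conserved.add(tuple(sorted(e2)))  # type: ignore[arg-type]

    return DividedNetwork(
        divisions=divisions,
        organism_types=organism_types,
        intra_edges=frozenset(intra),
        orthology_edges=frozenset(orthology),
        conserved_edges=frozenset(conserved),
        edge_threshold=edge_threshold,
    )
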