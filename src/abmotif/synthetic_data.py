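"""Seeded synthetic cohorts with planted conserved modules.

Emulates the inputs the pipeline consumes — per-organism COG association
networks, a phenotype table and a phylogenetic distance matrix — at desk
scale, with known ground truth. Each organism draws a subset of a shared COG
universe and sparse random background associations with STRING-like integer
scores; *planted modules* then overwrite a chosen COG set in chosen carrier
organisms with a complete clique at a fixed high score. Recovering a planted
module as an (alpha, beta)-clique is the package's end-to-end ground-truth
check.

Defaults mirror a typical small comparative cohort: 9 positive / 8 negative
organisms, a 30-COG universe, 50% COG presence, 5% background association
probability with scores uniform over 1..999, planted cliques scored 900 and
a combined-score threshold of 700 downstream. Random streams are split per
organism (``numpy.random.SeedSequence.spawn``), so enlarging the cohort
never perturbs the networks of existing organisms.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .network_model import (
    FunctionalAssociationNetwork,
    OrganismAnnotation,
    Phenotype,
)
from .phylo import PhyloDistanceMatrix

DEFAULT_PLANTED_SCORE = 900


@dataclass(frozen=True)
class PlantedModule:
    """A conserved clique inserted into chosen carrier organisms.

    Every carrier receives all C(m, 2) edges among ``cog_ids`` at exactly
    ``edge_score`` (overriding any background draw), and the carriers listed
    are exactly the organisms receiving the full clique.
    """

    cog_ids: tuple[str, ...]
    positive_carriers: tuple[str, ...] = ()
    negative_carriers: tuple[str, ...] = ()
    edge_score: int = DEFAULT_PLANTED_SCORE

    def __post_init__(self):
        if len(set(self.cog_ids)) != len(self.cog_ids) or len(self.cog_ids) < 2:
            raise ParameterError("planted module needs >= 2 distinct COGs")
        if not 0 <= self.edge_score <= 999:
            raise ParameterError("edge_score outside [0, 999]")

    @property
    def carriers(self) -> tuple[str, ...]:
        return tuple(self.positive_carriers) + tuple(self.negative_carriers)


@dataclass(frozen=True)
class CohortParams:
    """Generator settings; see module docstring for the default regime."""

    n_pos: int = 9
    n_neg: int = 8
    universe_size: int = 30
    presence_prob: float = 0.5
    background_edge_prob: float = 0.05
    background_score_range: tuple[int, int] = (1, 999)
    planted: tuple[PlantedModule, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_pos < 0 or self.n_neg < 0 or self.n_pos + self.n_neg == 0:
            raise ParameterError("cohort must contain at least one organism")
        if not 0 <= self.presence_prob <= 1:
            raise ParameterError("presence_prob outside [0, 1]")
        if not 0 <= self.background_edge_prob <= 1:
            raise ParameterError("background_edge_prob outside [0, 1]")
        lo, hi = self.background_score_range
        if not 0 <= lo <= hi <= 999:
            raise ParameterError("background_score_range outside [0, 999]")
        ids = set(self.organism_ids)
        for pm in self.planted:
            missing = set(pm.carriers) - ids
            if missing:
                raise ParameterError(
                    f"planted carriers not in cohort: {sorted(missing)}"
                )
            pos_ids = set(self.positive_ids)
            if set(pm.positive_carriers) - pos_ids:
                raise ParameterError("positive carriers must be positive organisms")
            if set(pm.negative_carriers) & pos_ids:
                raise ParameterError("negative carriers must be negative organisms")

    @property
    def positive_ids(self) -> tuple[str, ...]:
        return tuple(f"pos{i:02d}" for i in range(1, self.n_pos + 1))

    @property
    def negative_ids(self) -> tuple[str, ...]:
        return tuple(f"neg{i:02d}" for i in range(1, self.n_neg + 1))

    @property
    def organism_ids(self) -> tuple[str, ...]:
        return self.positive_ids + self.negative_ids

    @property
    def universe(self) -> tuple[str, ...]:
        return tuple(f"COG{i:04d}" for i in range(1, self.universe_size + 1))


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated networks plus annotations and ground truth."""

    params: CohortParams
    networks: tuple[FunctionalAssociationNetwork, ...]
    annotations: tuple[OrganismAnnotation, ...]

    @property
    def ground_truth(self) -> list[dict]:
        return [
            {
                "cog_ids": list(pm.cog_ids),
                "positive_carriers": list(pm.positive_carriers),
                "negative_carriers": list(pm.negative_carriers),
                "edge_score": pm.edge_score,
            }
            for pm in self.params.planted
        ]


def generate_cohort(params: CohortParams) -> SyntheticCohort:
    """Draw a cohort deterministically from ``params.seed``."""
    carriers_of: dict[str, list[PlantedModule]] = {}
    for pm in params.planted:
        for org in pm.carriers:
            carriers_of.setdefault(org, []).append(pm)

    org_ids = params.organism_ids
    streams = np.random.SeedSequence(params.seed).spawn(len(org_ids))
    lo, hi = params.background_score_range
    networks = []
    annotations = []
    for org, stream in zip(org_ids, streams):
        rng = np.random.default_rng(stream)
        present = {
            cog
            for cog, u in zip(params.universe, rng.random(params.universe_size))
            if u < params.presence_prob
        }
        for pm in carriers_of.get(org, ()):
            present.update(pm.cog_ids)
        edges: dict[tuple[str, str], int] = {}
        ordered = sorted(present)
        for a, b in combinations(ordered, 2):
            if rng.random() < params.background_edge_prob:
                edges[(a, b)] = int(rng.integers(lo, hi + 1))
        for pm in carriers_of.get(org, ()):  # planted edges override noise
            for a, b in combinations(sorted(pm.cog_ids), 2):
                edges[(a, b)] = pm.edge_score
        networks.append(
            FunctionalAssociationNetwork(org, frozenset(present), edges)
        )
        phenotype = (
            Phenotype.POSITIVE if org in params.positive_ids else Phenotype.NEGATIVE
        )
        annotations.append(OrganismAnnotation(org, phenotype))
    return SyntheticCohort(
        params=params, networks=tuple(networks), annotations=tuple(annotations)
    )


def generate_distance_matrix(
    organism_ids: Sequence[str], seed: int, scale: float = 1.0
) -> PhyloDistanceMatrix:
    """Random symmetric distance matrix, zero diagonal, entries in (0, scale]."""
    if scale <= 0:
        raise ParameterError("scale must be positive")
    n = len(organism_ids)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    upper = (1.0 - rng.random((n, n))) * scale  # open at 0, closed at scale
    mat = np.triu(upper, k=1)
    mat = mat + mat.T
    return PhyloDistanceMatrix.from_array(organism_ids, mat)
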