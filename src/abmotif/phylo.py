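"""Phylogenetic diversity score of a module.

A module found only in closely related organisms may be conserved through
shared ancestry rather than shared phenotype. The diversity score S_p
quantifies this: with OrgP / OrgN the phenotype-positive / -negative
organisms the module appears in and delta(i, j) a pairwise phylogenetic
distance,

    PP = sum over ordered pairs (i, j) in OrgP x OrgP of delta(i, j)
    PN = sum over (i, j) in OrgP x OrgN of delta(i, j)
    NN = sum over ordered pairs (i, j) in OrgN x OrgN of delta(i, j)
    S_p = (PP - PN - NN) / (PP + PN + NN)

S_p lies in [-1, 1]: +1 for a module carried only by (phylogenetically
spread) positive organisms, -1 for negatives only. The sums run over
*ordered* pairs exactly as written — PP and NN count each unordered pair
twice while the cross term PN counts it once; this asymmetry is part of the
score's definition and is deliberately not "corrected" here. When the
denominator is zero (a module in at most one organism, or a degenerate
all-zero matrix) the score is undefined and a sentinel 0.0 is returned with
a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import InputError

logger = logging.getLogger(__name__)

SYMMETRY_RTOL = 1e-9


@dataclass(frozen=True)
class PhyloDistanceMatrix:
    """Square matrix of pairwise organism distances with labelled axes."""

    organism_ids: tuple[str, ...]
    distances: np.ndarray

    def __post_init__(self):
        d = self.distances
        n = len(self.organism_ids)
        if len(set(self.organism_ids)) != n:
            raise InputError("duplicate organism ids in distance matrix")
        if d.shape != (n, n):
            raise InputError(
                f"matrix shape {d.shape} does not match {n} organism ids"
            )
        if np.any(d < 0):
            raise InputError("negative distances")
        if np.any(np.diag(d) != 0):
            raise InputError("non-zero diagonal in distance matrix")

    @classmethod
    def from_array(
        cls,
        organism_ids: Sequence[str],
        distances,
        rtol: float = SYMMETRY_RTOL,
    ) -> "PhyloDistanceMatrix":
        """Validate and (within tolerance) symmetrize a raw matrix.

        Asymmetries within ``rtol`` relative tolerance are averaged away;
        larger ones are a hard error.
        """
        arr = np.asarray(distances, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise InputError(f"distance matrix must be square, got {arr.shape}")
        scale = np.abs(arr).max() or 1.0
        if not np.allclose(arr, arr.T, rtol=rtol, atol=rtol * scale):
            raise InputError("distance matrix is not symmetric")
        sym = (arr + arr.T) / 2.0
        np.fill_diagonal(sym, 0.0)
        sym.setflags(write=False)
        return cls(tuple(organism_ids), sym)

    def index_of(self, organism_id: str) -> int:
        try:
            return self.organism_ids.index(organism_id)
        except ValueError:
            raise InputError(
                f"organism {organism_id!r} not in distance matrix"
            ) from None

    def submatrix_sum(self, rows: Sequence[int], cols: Sequence[int]) -> float:
        if not rows or not cols:
            return 0.0
        return float(self.distances[np.ix_(rows, cols)].sum())


def phylo_score(
    positive_orgs: Iterable[str],
    negative_orgs: Iterable[str],
    dm: PhyloDistanceMatrix,
) -> float:
    """Diversity score S_p of a module's carrier organisms. See module docs."""
    pos = sorted(set(positive_orgs))
    neg = sorted(set(negative_orgs))
    overlap = set(pos) & set(neg)
    if overlap:
        raise InputError(f"organisms in both type sets: {sorted(overlap)}")
    pi = [dm.index_of(o) for o in pos]
    ni = [dm.index_of(o) for o in neg]
    pp = dm.submatrix_sum(pi, pi)
    pn = dm.submatrix_sum(pi, ni)
    nn = dm.submatrix_sum(ni, ni)
    denom = pp + pn + nn
    if denom == 0:
        logger.warning(
            "phylo_score undefined (zero denominator) for %d positive / %d "
            "negative carriers; returning sentinel 0.0",
            len(pos),
            len(neg),
        )
        return 0.0
    return (pp - pn - nn) / denom
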