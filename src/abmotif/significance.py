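"""Hypergeometric significance machinery.

Two uses of the same one-sided (upper-tail, inclusive) hypergeometric test:

1. *Parameter selection* — before enumeration, decide which (alpha, beta)
   pairs are worth running. Drawing ``alpha + beta`` organisms from the
   cohort (``n_pos`` positive out of ``n_pos + n_neg``), how surprising is it
   to hit at least ``alpha`` positives? Pairs with alpha >= beta whose
   p-value clears the threshold are kept, and for each beta only the
   smallest qualifying alpha (the *non-redundant* pair: its output already
   contains every larger alpha's output at that beta).
2. *Module scoring* — after enumeration, each module's phenotype bias: the
   same tail probability with the module's organism counts as the sample.

The tail is computed with exact rational arithmetic
(``fractions.Fraction`` over ``math.comb``) and converted to float at the
end, so results are exact to float precision for any cohort size this
package targets. No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import TYPE_CHECKING

from .errors import ParameterError

if TYPE_CHECKING:  # pragma: no cover
    from .motif_finder import ModuleClique


def hypergeometric_upper_tail(
    population: int, successes: int, sample: int, observed: int
) -> float:
    """P(X >= observed) for X ~ Hypergeometric(population, successes, sample).

    Inclusive upper tail: sum over i from ``observed`` to
    ``min(sample, successes)`` of C(successes, i) *
    C(population - successes, sample - i) / C(population, sample).
    Exact rational summation; returns the nearest float.
    """
    if not 0 <= successes <= population:
        raise ParameterError(
            f"successes={successes} outside [0, population={population}]"
        )
    if not 0 <= observed <= sample <= population:
        raise ParameterError(
            f"need 0 <= observed={observed} <= sample={sample} "
            f"<= population={population}"
        )
    failures = population - successes
    total = comb(population, sample)
    acc = 0
    for i in range(observed, min(sample, successes) + 1):
        if sample - i > failures:
            continue  # more failures requested than exist
        acc += comb(successes, i) * comb(failures, sample - i)
    return float(Fraction(acc, total))


@dataclass(frozen=True)
class AlphaBetaPair:
    """A candidate (alpha, beta) setting with its selection p-value."""

    alpha: int
    beta: int
    p_value: float

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ParameterError("alpha and beta must be non-negative")


def select_ab_pairs(
    n_pos: int, n_neg: int, p_threshold: float
) -> list[AlphaBetaPair]:
    """Non-redundant statistically significant (alpha, beta) pairs.

    Scans alpha in 1..n_pos crossed with beta in 0..n_neg; keeps pairs with
    alpha >= beta whose upper-tail p-value is <= ``p_threshold`` (ties at the
    threshold included); for each beta returns only the smallest qualifying
    alpha. Sorted by beta ascending.
    """
    if n_pos < 1:
        raise ParameterError("n_pos must be >= 1")
    if n_neg < 0:
        raise ParameterError("n_neg must be >= 0")
    if not 0 < p_threshold <= 1:
        raise ParameterError("p_threshold must be in (0, 1]")
    population = n_pos + n_neg
    selected: list[AlphaBetaPair] = []
    for beta in range(n_neg + 1):
        for alpha in range(1, n_pos + 1):
            if alpha < beta:
                continue
            p = hypergeometric_upper_tail(
                population, n_pos, alpha + beta, alpha
            )
            if p <= p_threshold:
                selected.append(AlphaBetaPair(alpha, beta, p))
                break  # smallest alpha for this beta
    return selected


def clique_significance(
    module: "ModuleClique", n_pos: int, n_neg: int
) -> float:
    """Phenotype bias of one module: upper-tail hypergeometric p-value.

    Population = whole cohort, successes = positive organisms, sample = the
    organisms the module appears in, observed = the positive ones among them.
    """
    a, b = module.alpha_count, module.beta_count
    if a > n_pos or b > n_neg:
        raise ParameterError(
            f"module spans {a} positives / {b} negatives but cohort has only "
            f"{n_pos} / {n_neg}"
        )
    return hypergeometric_upper_tail(n_pos + n_neg, n_pos, a + b, a)
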