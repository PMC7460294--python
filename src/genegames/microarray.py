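"""The microarray game and its Shapley value.

A microarray game is a transferable-utility game built from the Boolean
abnormality matrix of an experimental situation: a coalition's worth is
the fraction of disease arrays whose abnormal gene set (support) is
contained in the coalition.  Empty supports (all-normal arrays) never
count as winning but still appear in the denominator.

Because the game is the mixture (1/k)·Σ_j u_{sp(j)} of unanimity games
over the non-empty supports, the Shapley value has the linear-time
closed form Φ_i = (1/k)·Σ_{j: i∈sp(j)} 1/|sp(j)|.  The factorial
average-marginal-contribution formula is retained only as an
exponential-time test oracle.

Exact rational arithmetic (``fractions.Fraction``) is used throughout;
callers can convert to floats for large score tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from math import factorial
from typing import Callable, Iterable, Mapping, Sequence

from .expression import BooleanMatrix

AllocationVector = dict[str, Fraction]


@dataclass(frozen=True)
class MicroarrayGame:
    """TU-game defined by per-array supports over a gene player set.

    ``supports`` holds the non-empty supports only; ``n_arrays`` is the
    total number of disease arrays (the value-function denominator),
    which may exceed ``len(supports)`` when some arrays were all-normal.
    """

    gene_ids: tuple[str, ...]
    supports: tuple[frozenset[str], ...]
    n_arrays: int

    def __post_init__(self) -> None:
        players = set(self.gene_ids)
        for sp in self.supports:
            if not sp:
                raise ValueError("retained supports must be non-empty")
            if not sp <= players:
                raise ValueError(f"support {sorted(sp)} contains unknown genes")
        if self.n_arrays < len(self.supports):
            raise ValueError("n_arrays cannot be smaller than the retained support count")

    @classmethod
    def from_boolean(cls, b: BooleanMatrix) -> "MicroarrayGame":
        cols = b.column_supports()
        return cls(b.gene_ids, tuple(sp for sp in cols if sp), len(cols))

    def value(self, coalition: Iterable[str]) -> Fraction:
        """v(T): fraction of arrays whose support is contained in T."""
        t = frozenset(coalition)
        unknown = t - set(self.gene_ids)
        if unknown:
            raise KeyError(f"coalition contains unknown genes {sorted(unknown)}")
        if self.n_arrays == 0:
            return Fraction(0)
        return Fraction(sum(1 for sp in self.supports if sp <= t), self.n_arrays)


def shapley_microarray(game: MicroarrayGame) -> AllocationVector:
    """Closed-form Shapley value of a microarray game.

    Each non-empty support sp(j) is a unanimity game paying 1/|sp(j)| to
    each of its members, scaled by 1/n_arrays.  Genes in no support
    (null players) score exactly 0.
    """
    phi: AllocationVector = {g: Fraction(0) for g in game.gene_ids}
    if game.n_arrays == 0:
        return phi
    for sp in game.supports:
        share = Fraction(1, len(sp) * game.n_arrays)
        for g in sp:
            phi[g] += share
    return phi


def shapley_bruteforce(
    players: Sequence[str], value_oracle: Callable[[frozenset[str]], Fraction | float]
) -> AllocationVector:
    """Exact Shapley value by the average-marginal-contribution formula.

    Enumerates all coalitions; guarded to <= 15 players.  Test oracle
    only — use :func:`shapley_microarray` for real instances.
    """
    players = tuple(players)
    n = len(players)
    if n > 15:
        raise ValueError(f"{n} players would need 2^{n} coalitions; use the closed form")
    fact = [factorial(k) for k in range(n + 1)]
    phi: AllocationVector = {p: Fraction(0) for p in players}
    for size in range(1, n + 1):
        weight = Fraction(fact[size - 1] * fact[n - size], fact[n])
        for combo in combinations(players, size):
            s = frozenset(combo)
            v_s = Fraction(value_oracle(s))
            for p in combo:
                phi[p] += weight * (v_s - Fraction(value_oracle(s - {p})))
    return phi


def as_floats(phi: Mapping[str, Fraction]) -> dict[str, float]:
    return {g: float(x) for g, x in phi.items()}
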