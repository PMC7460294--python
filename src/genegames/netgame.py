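"""Microarray network games and the Link Relevance Index (LRI).

Given the co-expression network g^E, each connected gene i has a link
support g_i^E (the links it is involved in).  The value function of the
microarray network game assigns to any query network g the fraction of
connected genes whose whole support lies inside g:

    v(g) = |{i : ∅ ≠ g_i^E ⊆ g}| / n(g^E),        v(∅) = 0,

where n(g^E) counts genes with at least one link.  v is the mixture of
the unanimity basis games on the distinct supports, weighted by how
many genes share each support (the alpha coefficients).

The LRI is the position value of this game: each link earns its Shapley
value and splits it equally between its endpoints.  Thanks to the
unanimity decomposition it reduces to a polynomial-time support sum

    F_i(g) = (1/(2 n(g^E))) Σ_{j: ∅≠g_j^E ⊆ g} |g_j^E ∩ g_i| / |g_j^E|,

and on the full network g = g^E to the degree-based closed form

    F_i = (1/(2 n(g^E))) (1 + Σ_{j ~ i} 1/deg(j)),

so a gene is salient when it links to many sparsely connected partners.
The exponential-time position-value formula over all subnetworks is
kept only as a verification oracle, together with the axioms
(efficiency, superfluous-link invariance, link anonymity) that
characterize the index.

All scores are exact rationals; convert with
:func:`genegames.microarray.as_floats` for large tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import factorial
from typing import Callable, Iterable, Mapping

from .microarray import AllocationVector
from .network import Link, Network

ValueOracle = Callable[[frozenset[Link]], Fraction | float]


@dataclass(frozen=True)
class MicroarrayNetworkGame:
    """The triple (N, v, g^E): gene universe, value function, network.

    Built from a co-expression network with at least one link; the
    supports map and the connected-gene count are derived once.
    """

    network: Network

    def __post_init__(self) -> None:
        if not self.network.links:
            raise ValueError("a microarray network game needs at least one link")
        # supports are queried once per subnetwork in the oracles; derive once
        derived = {i: self.network.support(i) for i in self.network.connected_genes()}
        object.__setattr__(self, "_supports", derived)

    @property
    def universe(self) -> tuple[str, ...]:
        return self.network.universe

    @property
    def n_connected(self) -> int:
        """n(g^E): number of genes with at least one link."""
        return self.network.n_connected

    def supports(self) -> dict[str, frozenset[Link]]:
        """g_i^E for every connected gene i, in universe order."""
        return self._supports  # type: ignore[attr-defined]

    # -- value function ------------------------------------------------

    def value(self, g: Network | Iterable[Link]) -> Fraction:
        """v(g): fraction of connected genes whose support lies in g."""
        links = g.links if isinstance(g, Network) else frozenset(g)
        contained = sum(1 for sp in self.supports().values() if sp <= links)
        return Fraction(contained, self.n_connected)

    def alpha_bar(self) -> dict[frozenset[Link], int]:
        """Unanimity weights: distinct support -> number of genes with it.

        The weights sum to n(g^E); dividing by n(g^E) gives the
        coefficients of v in the unanimity basis.
        """
        counts: dict[frozenset[Link], int] = {}
        for sp in self.supports().values():
            counts[sp] = counts.get(sp, 0) + 1
        return counts

    # -- the Link Relevance Index ---------------------------------------

    def lri(self, g: Network | Iterable[Link] | None = None) -> AllocationVector:
        """LRI restricted to a query network g (default: the full g^E).

        Evaluated through the support decomposition — each contained
        support g_j^E contributes (incident links of i)/(2 n |g_j^E|) to
        gene i — never by enumerating subnetworks.
        """
        if g is None:
            links = self.network.links
        else:
            links = g.links if isinstance(g, Network) else frozenset(g)
        n = self.n_connected
        scores: AllocationVector = {i: Fraction(0) for i in self.universe}
        for sp in self.supports().values():
            if not sp <= links:
                continue
            for a, b in sp:
                share = Fraction(1, 2 * n * len(sp))
                scores[a] += share
                scores[b] += share
        return scores

    def lri_full(self) -> AllocationVector:
        """Degree closed form of the LRI at g = g^E.

        Connected genes earn (1 + Σ_neighbours 1/deg)/(2 n(g^E));
        isolated genes earn 0 (they contribute no basis game, and only
        then does the total equal v(g^E) = 1).
        """
        n = self.n_connected
        supports = self.supports()
        deg = {i: len(sp) for i, sp in supports.items()}
        scores: AllocationVector = {i: Fraction(0) for i in self.universe}
        for i, sp in supports.items():
            neighbours = [a if b == i else b for a, b in sp]
            scores[i] = Fraction(1, 2 * n) * (1 + sum(Fraction(1, deg[j]) for j in neighbours))
        return scores


def position_value_bruteforce(g: Network, value_oracle: ValueOracle) -> AllocationVector:
    """Link-based Shapley allocation by full subnetwork enumeration.

    Each link's Shapley value (over the link "player" set of g) is split
    equally between its endpoints.  Exponential in |g|; guarded to 12
    links.  Verification oracle only.
    """
    m = g.n_links
    if m > 12:
        raise ValueError(f"{m} links would need 2^{m} subnetworks; use the LRI closed form")
    fact = [factorial(k) for k in range(m + 1)]
    scores: AllocationVector = {i: Fraction(0) for i in g.universe}
    for sub in g.subnetworks():
        if not sub:
            continue
        weight = Fraction(fact[len(sub) - 1] * fact[m - len(sub)], fact[m])
        v_sub = Fraction(value_oracle(sub))
        for l in sub:
            marginal = weight * (v_sub - Fraction(value_oracle(sub - {l})))
            half = marginal / 2
            scores[l[0]] += half
            scores[l[1]] += half
    return scores


@dataclass(frozen=True)
class AxiomReport:
    """Outcome of the characterizing-axiom checks on one instance."""

    efficiency: bool
    superfluous_link: bool
    link_anonymity: bool | None  # None when the instance is not link-anonymous
    checked_subnetworks: int

    @property
    def all_pass(self) -> bool:
        return self.efficiency and self.superfluous_link and self.link_anonymity in (True, None)

    def lines(self) -> list[str]:
        def mark(x):
            return "n/a" if x is None else ("pass" if x else "FAIL")

        return [
            f"efficiency over {self.checked_subnetworks} subnetworks: {mark(self.efficiency)}",
            f"superfluous-gene-link invariance: {mark(self.superfluous_link)}",
            f"gene-link anonymity: {mark(self.link_anonymity)}",
        ]


def check_axioms(game: MicroarrayNetworkGame, *, max_links: int = 12) -> AxiomReport:
    """Verify the axioms that characterize the LRI on a small instance.

    Efficiency: Σ_i F_i(g) = v(g) for every subnetwork g ⊆ g^E (exact).
    Superfluous link: adding a link outside every support, or removing
    one, leaves F unchanged.  Anonymity: when the value function is
    link-anonymous on g^E, F_i is proportional to the degree |g_i|.
    """
    net = game.network
    if net.n_links > max_links:
        raise ValueError(f"axiom checks enumerate subnetworks; {net.n_links} links > {max_links}")

    subs = list(net.subnetworks())
    efficiency = all(sum(game.lri(sub).values()) == game.value(sub) for sub in subs)

    # Superfluous links in this game are exactly the complete-network
    # links outside g^E: grow the query by one such link and compare.
    superfluous = True
    complete = Network.complete(net.universe)
    extra = sorted(complete.links - net.links)
    if extra:
        grown = Network(net.universe, net.links | {extra[0]})
        superfluous = game.lri(grown) == game.lri(net)

    by_size: dict[int, set[Fraction]] = {}
    for sub in subs:
        by_size.setdefault(len(sub), set()).add(game.value(sub))
    anonymous = all(len(vals) == 1 for vals in by_size.values())
    link_anonymity: bool | None = None
    if anonymous:
        f = game.lri(net)
        degs = {i: net.degree(i) for i in net.universe}
        ratios = {f[i] / degs[i] for i in net.universe if degs[i] > 0}
        link_anonymity = len(ratios) == 1 and all(f[i] == 0 for i in net.universe if degs[i] == 0)

    return AxiomReport(efficiency, superfluous, link_anonymity, len(subs))


def efficiency_gap(game: MicroarrayNetworkGame, scores: Mapping[str, float]) -> float:
    """|Σ_i F_i − v(g^E)| for float score tables (tolerance 1e-9 in the
    pipeline)."""
    return abs(sum(scores.values()) - float(game.value(game.network)))
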