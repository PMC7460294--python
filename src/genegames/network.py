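"""Canonical unweighted network representation for network games.

A network is a set of unordered gene pairs (links) over a fixed gene
universe.  The universe is carried separately from the set of connected
genes so that "genes with at least one link" and "all genes" are never
conflated: isolated genes are legitimate players that simply score zero.

Links are stored canonically as ``(a, b)`` tuples with ``a < b``
lexicographically; every iteration order in this module is made
deterministic by that ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Iterator, Literal

import networkx as nx

Link = tuple[str, str]


def link(a: str, b: str) -> Link:
    """Canonical unordered link: endpoints sorted lexicographically."""
    if a == b:
        raise ValueError(f"self-loop {a!r}-{b!r} is not a valid link")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class Network:
    """An unweighted network ``g`` over a fixed gene universe.

    Parameters
    ----------
    universe : tuple of str
        All gene identifiers, in a fixed order.  Genes may be isolated.
    links : frozenset of (str, str)
        Unordered pairs, stored canonically (smaller id first).
    """

    universe: tuple[str, ...]
    links: frozenset[Link] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        seen = set(self.universe)
        if len(seen) != len(self.universe):
            raise ValueError("gene universe contains duplicate identifiers")
        for a, b in self.links:
            if a >= b:
                raise ValueError(f"link ({a!r}, {b!r}) not in canonical order")
            if a not in seen or b not in seen:
                raise ValueError(f"link ({a!r}, {b!r}) has endpoint outside the universe")

    # -- construction -------------------------------------------------

    @classmethod
    def from_edges(cls, universe: Iterable[str], edges: Iterable[tuple[str, str]]) -> "Network":
        return cls(tuple(universe), frozenset(link(a, b) for a, b in edges))

    @classmethod
    def complete(cls, universe: Iterable[str]) -> "Network":
        """The complete network g^N on the universe."""
        uni = tuple(universe)
        return cls(uni, frozenset(combinations(sorted(uni), 2)))

    # -- basic structure ----------------------------------------------

    @property
    def n_links(self) -> int:
        return len(self.links)

    def sorted_links(self) -> list[Link]:
        return sorted(self.links)

    def support(self, i: str) -> frozenset[Link]:
        """The links incident to gene ``i`` (g_i); empty for isolated genes."""
        if i not in self.universe:
            raise KeyError(f"unknown gene id {i!r}")
        return frozenset(l for l in self.links if i in l)

    def degree(self, i: str) -> int:
        return len(self.support(i))

    def connected_genes(self) -> tuple[str, ...]:
        """N(g): genes with at least one link, in universe order."""
        involved = {x for l in self.links for x in l}
        return tuple(i for i in self.universe if i in involved)

    @property
    def n_connected(self) -> int:
        """n(g) = |N(g)|."""
        return len(self.connected_genes())

    def components(self) -> list[frozenset[Link]]:
        """Maximally connected subnetworks, as link sets.

        Isolated genes yield no component.  Components are returned in a
        deterministic order (by their smallest link).
        """
        graph = nx.Graph()
        graph.add_edges_from(self.links)
        comps = []
        for nodes in nx.connected_components(graph):
            comps.append(frozenset(l for l in self.links if l[0] in nodes))
        return sorted(comps, key=lambda c: min(c))

    # -- set algebra (links only; universe is preserved) ---------------

    def subnetwork(self, links: Iterable[Link]) -> "Network":
        ls = frozenset(links)
        if not ls <= self.links:
            raise ValueError("subnetwork links must be a subset of the parent's links")
        return Network(self.universe, ls)

    def without(self, l: Link) -> "Network":
        return Network(self.universe, self.links - {l})

    def __le__(self, other: "Network") -> bool:
        return self.links <= other.links

    def subnetworks(self, *, max_links: int = 20) -> Iterator[frozenset[Link]]:
        """All 2^|g| subsets of the link set, smallest first (oracle use only)."""
        if self.n_links > max_links:
            raise ValueError(f"refusing to enumerate 2^{self.n_links} subnetworks")
        ordered = self.sorted_links()
        for r in range(len(ordered) + 1):
            for combo in combinations(ordered, r):
                yield frozenset(combo)


def basis_value(
    kind: Literal["subset", "proper", "exact"],
    base: frozenset[Link] | Network,
    query: frozenset[Link] | Network,
) -> int:
    """The three basis value functions on the space of value functions.

    ``subset`` is the unanimity game v_g (1 iff base ⊆ query), ``proper``
    its strict variant (1 iff base ⊊ query), ``exact`` the Dirac game
    (1 iff base = query).
    """
    b = base.links if isinstance(base, Network) else frozenset(base)
    q = query.links if isinstance(query, Network) else frozenset(query)
    if not b:
        raise ValueError("basis value functions require a non-empty base network")
    if kind == "subset":
        return int(b <= q)
    if kind == "proper":
        return int(b < q)
    if kind == "exact":
        return int(b == q)
    raise ValueError(f"unknown basis kind {kind!r}")


# -- edge-list I/O (shared TSV dialect) --------------------------------


def write_edge_list(net: Network, path: str | Path, *, delimiter: str = "\t") -> None:
    """Write links as two columns (gene_a, gene_b), gene_a < gene_b.

    A header line is included; isolated genes are listed in a trailing
    comment so the universe can be reconstructed.
    """
    path = Path(path)
    lines = ["gene_a" + delimiter + "gene_b"]
    lines += [a + delimiter + b for a, b in net.sorted_links()]
    isolated = [i for i in net.universe if i not in set(net.connected_genes())]
    if isolated:
        lines.append("# isolated: " + ",".join(isolated))
    path.write_text("\n".join(lines) + "\n")


def read_edge_list(path: str | Path, *, delimiter: str = "\t") -> Network:
    path = Path(path)
    edges: list[tuple[str, str]] = []
    isolated: list[str] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        row = raw.strip()
        if not row or row.startswith("gene_a"):
            continue
        if row.startswith("# isolated:"):
            isolated = [x for x in row.split(":", 1)[1].strip().split(",") if x]
            continue
        parts = row.split(delimiter)
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected two columns, got {row!r}")
        edges.append((parts[0], parts[1]))
    universe = sorted({x for e in edges for x in e} | set(isolated))
    return Network.from_edges(universe, edges)
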