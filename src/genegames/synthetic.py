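"""Deterministic synthetic fixtures: experimental situations with
planted co-expressed modules, and random small games for the oracles.

The expression generator emulates the two-matrix layout of a microarray
study: per-gene baselines with Gaussian sampling noise for the normal
samples, and disease samples in which a chosen module of genes is
shifted beyond the observed reference range with block-correlated
deviations (one latent factor per module), so the out-of-range
discriminant retains exactly the planted signal.  Background genes are
shifted too, but with independent deviations, so their pairwise
correlations are sampling noise around zero.

All randomness flows from a single integer seed through one explicit
``numpy.random.Generator``; identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

from .expression import MES, ExpressionMatrix
from .netgame import MicroarrayNetworkGame
from .network import Network


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic experimental situation.

    ``modules`` lists (gene indices, correlation level) pairs: the level
    is the target pairwise Pearson correlation of the module rows in the
    discriminant matrix (factor loading sqrt(level)).  The disease shift
    places module and abnormal-background entries 3 observed reference
    standard deviations beyond the reference maximum, so booleanization
    is unambiguous.
    """

    n_genes: int = 30
    n_reference: int = 20
    n_disease: int = 30
    modules: tuple[tuple[tuple[int, ...], float], ...] = (((0, 1, 2, 3, 4), 0.9),)
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_reference, self.n_disease) < 1:
            raise ValueError("gene and sample counts must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for genes, level in self.modules:
            if not set(genes) <= set(range(self.n_genes)):
                raise ValueError(f"module genes {genes} outside range(n_genes)")
            if not 0 < level <= 1:
                raise ValueError(f"module correlation level {level} not in (0, 1]")

    def gene_ids(self) -> tuple[str, ...]:
        width = len(str(self.n_genes - 1))
        return tuple(f"g{i:0{width}d}" for i in range(self.n_genes))


def generate_mes(spec: FixtureSpec) -> MES:
    """Build a reference/disease matrix pair with planted modules.

    Module genes deviate by ``3 + level-correlated N(0,1)`` reference
    standard deviations above the per-gene reference maximum; background
    genes by an independent deviation of the same magnitude.  Entries
    rarely (P ≈ 1e-3) fall back inside the reference range — the
    discriminant zeroes those, which is part of the emulated noise.
    """
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_ids()
    samples_r = tuple(f"r{j}" for j in range(spec.n_reference))
    samples_d = tuple(f"d{j}" for j in range(spec.n_disease))

    baselines = rng.uniform(2.0, 10.0, size=spec.n_genes)
    ref = baselines[:, None] + rng.normal(0.0, spec.noise_sd, (spec.n_genes, spec.n_reference))
    hi = ref.max(axis=1)
    sd = ref.std(axis=1, ddof=1) if spec.n_reference > 1 else np.full(spec.n_genes, spec.noise_sd)
    sd = np.maximum(sd, 1e-9)

    # independent unit deviations for everyone, then overwrite module
    # genes with factor-correlated ones
    dev = rng.normal(0.0, 1.0, (spec.n_genes, spec.n_disease))
    for gene_idx, level in spec.modules:
        factor = rng.normal(0.0, 1.0, spec.n_disease)
        loading = np.sqrt(level)
        resid = np.sqrt(1.0 - level)
        for i in gene_idx:
            dev[i] = loading * factor + resid * rng.normal(0.0, 1.0, spec.n_disease)

    # centre the shift 3 reference s.d. beyond the observed maximum; the
    # 0.75-s.d. deviation scale keeps entries outside the range (falling
    # back inside would need a 4-sigma draw) without touching the
    # correlation structure, which is scale-free
    disease = hi[:, None] + sd[:, None] * (3.0 + 0.75 * dev)
    return MES(
        ExpressionMatrix(genes, samples_r, ref),
        ExpressionMatrix(genes, samples_d, disease),
    )


def write_fixture(spec: FixtureSpec, out_prefix: str) -> tuple[str, str]:
    """Write ``<prefix>_reference.tsv`` and ``<prefix>_disease.tsv``."""
    from .expression import write_matrix

    mes = generate_mes(spec)
    paths = (f"{out_prefix}_reference.tsv", f"{out_prefix}_disease.tsv")
    write_matrix(mes.genes, mes.reference.sample_ids, mes.reference.values, paths[0])
    write_matrix(mes.genes, mes.disease.sample_ids, mes.disease.values, paths[1])
    return paths


# -- random and special-case games for the oracle suites ----------------


def _ids(n: int) -> tuple[str, ...]:
    width = len(str(max(n - 1, 1)))
    return tuple(f"g{i:0{width}d}" for i in range(n))


def generate_random_game(n_genes: int, n_links: int, seed: int) -> MicroarrayNetworkGame:
    """Uniform random simple network with ``n_links`` links (≥ 1)."""
    ids = _ids(n_genes)
    all_pairs = list(combinations(ids, 2))
    if not 1 <= n_links <= len(all_pairs):
        raise ValueError(f"n_links must be in [1, {len(all_pairs)}], got {n_links}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(all_pairs), size=n_links, replace=False)
    return MicroarrayNetworkGame(Network.from_edges(ids, [all_pairs[k] for k in sorted(chosen)]))


def star_game(n_leaves: int) -> MicroarrayNetworkGame:
    """Hub ``g0`` linked to ``n_leaves`` leaves."""
    ids = _ids(n_leaves + 1)
    return MicroarrayNetworkGame(Network.from_edges(ids, [(ids[0], l) for l in ids[1:]]))


def path_game(n_nodes: int) -> MicroarrayNetworkGame:
    ids = _ids(n_nodes)
    return MicroarrayNetworkGame(Network.from_edges(ids, list(zip(ids, ids[1:]))))


def clique_game(n_nodes: int) -> MicroarrayNetworkGame:
    ids = _ids(n_nodes)
    return MicroarrayNetworkGame(Network.complete(ids))


def random_boolean_supports(
    n_genes: int, n_arrays: int, seed: int, p_abnormal: float = 0.4
) -> tuple[tuple[str, ...], list[frozenset[str]]]:
    """Random per-array abnormal gene sets (possibly empty) for the
    Shapley oracle suite."""
    ids = _ids(n_genes)
    rng = np.random.default_rng(seed)
    flags = rng.random((n_genes, n_arrays)) < p_abnormal
    cols = [frozenset(np.asarray(ids)[flags[:, j]]) for j in range(n_arrays)]
    return ids, cols
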