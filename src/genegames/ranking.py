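"""Ranking, top-k overlap, and combined score tables.

Gene scores from two allocation rules (LRI and microarray-game Shapley)
are compared rank-wise.  Ties are always broken lexicographically by
gene id — overlap counts near ties would otherwise be non-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

Score = float | Fraction


@dataclass(frozen=True)
class RankedList:
    """Genes in non-increasing score order, ties lexicographic."""

    genes: tuple[str, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores must align")
        if any(a < b for a, b in zip(self.scores, self.scores[1:])):
            raise ValueError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.genes)

    def top(self, k: int) -> frozenset[str]:
        if not 1 <= k <= len(self):
            raise ValueError(f"k={k} out of range for a list of {len(self)} genes")
        return frozenset(self.genes[:k])


def rank(scores: Mapping[str, Score]) -> RankedList:
    """Deterministic descending ranking of a score map."""
    if not scores:
        raise ValueError("cannot rank an empty score map")
    ordered = sorted(scores.items(), key=lambda kv: (-float(kv[1]), kv[0]))
    return RankedList(tuple(g for g, _ in ordered), tuple(float(s) for _, s in ordered))


def topk_overlap(a: RankedList, b: RankedList, k: int) -> int:
    """|top-k(a) ∩ top-k(b)|; symmetric and monotone in k."""
    return len(a.top(k) & b.top(k))


def overlap_profile(a: RankedList, b: RankedList, ks: Sequence[int]) -> pd.DataFrame:
    return pd.DataFrame({"k": list(ks), "overlap": [topk_overlap(a, b, k) for k in ks]})


def score_table(lri: Mapping[str, Score], shapley: Mapping[str, Score]) -> pd.DataFrame:
    """Combined table (gene_id, lri, shapley, lri_rank, shapley_rank),
    sorted by LRI rank.  Both maps must cover the same gene universe."""
    if set(lri) != set(shapley):
        missing = set(lri) ^ set(shapley)
        raise ValueError(f"score maps cover different gene universes: {sorted(missing)[:5]}")
    r_lri = rank(lri)
    r_shap = rank(shapley)
    pos_l = {g: i + 1 for i, g in enumerate(r_lri.genes)}
    pos_s = {g: i + 1 for i, g in enumerate(r_shap.genes)}
    return pd.DataFrame(
        {
            "gene_id": list(r_lri.genes),
            "lri": [float(lri[g]) for g in r_lri.genes],
            "shapley": [float(shapley[g]) for g in r_lri.genes],
            "lri_rank": [pos_l[g] for g in r_lri.genes],
            "shapley_rank": [pos_s[g] for g in r_lri.genes],
        }
    )


def score_correlation(table: pd.DataFrame) -> float:
    """Pearson correlation between the LRI and Shapley columns (NaN when
    either column is constant)."""
    l, s = table["lri"].to_numpy(), table["shapley"].to_numpy()
    if np.ptp(l) == 0 or np.ptp(s) == 0:
        return float("nan")
    return float(np.corrcoef(l, s)[0, 1])
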