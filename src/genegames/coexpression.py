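"""Gene–gene similarity and hard-threshold co-expression network
construction.

Similarity between two genes is the absolute Pearson correlation of
their (discriminant) expression rows, giving a symmetric matrix S with
unit diagonal and entries in [0, 1].  The unweighted co-expression
network keeps a link ij exactly when s_ij >= tau (the signum adjacency
function with hard threshold tau; ties at the threshold produce a
link).  Similarities are compared at full floating precision —
rounding is display-only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .expression import DiscriminantMatrix
from .network import Network

#: Sentinel returned by :func:`pearson` when either vector is constant.
UNDEFINED: None = None


def pearson(x: np.ndarray, y: np.ndarray) -> Optional[float]:
    """Pearson correlation coefficient of two equal-length vectors.

    Returns ``None`` (the "undefined" sentinel) when either vector has
    zero variance; downstream that maps to similarity 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"vectors must share one dimension, got {x.shape} and {y.shape}")
    if x.size < 2:
        raise ValueError("Pearson correlation needs at least 2 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return UNDEFINED
    return float(np.corrcoef(x, y)[0, 1])


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric |PCC| matrix with unit diagonal, entries in [0, 1]."""

    gene_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.gene_ids)
        if v.shape != (n, n):
            raise ValueError(f"similarity matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValueError("similarity values must lie in [0, 1]")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("similarity matrix diagonal must be 1")
        v = v.copy()
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=list(self.gene_ids))

    def powered(self, beta: float) -> "SimilarityMatrix":
        """Soft-threshold power transform s_ij^beta (diagnostic only;
        the games downstream are defined on unweighted networks)."""
        if beta <= 0:
            raise ValueError("soft-threshold power beta must be positive")
        return SimilarityMatrix(self.gene_ids, self.values**beta)


@dataclass(frozen=True)
class ThresholdConfig:
    """Hard threshold tau in [0, 1]; optional soft power beta (display)."""

    tau: float = 0.9
    beta: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError(f"tau must lie in [0, 1], got {self.tau}")
        if self.beta is not None and self.beta <= 0:
            raise ValueError("beta must be positive")


def similarity_matrix(d: DiscriminantMatrix | np.ndarray, gene_ids=None) -> SimilarityMatrix:
    """Absolute Pearson correlation between all gene pairs.

    Rows with zero variance get similarity 0 to every partner (their
    correlation is undefined); the diagonal is fixed at 1.
    """
    if isinstance(d, DiscriminantMatrix):
        values, gene_ids = d.values, d.gene_ids
    else:
        values = np.asarray(d, dtype=float)
        if gene_ids is None:
            raise ValueError("gene_ids required when passing a bare array")
    if values.shape[1] < 2:
        raise ValueError("similarity needs at least 2 samples (columns)")
    constant = np.ptp(values, axis=1) == 0
    if constant.any():
        names = [g for g, c in zip(gene_ids, constant) if c]
        warnings.warn(
            f"{len(names)} constant gene row(s) assigned similarity 0: {names[:5]}",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    s = np.abs(corr)
    s[~np.isfinite(s)] = 0.0
    s = np.clip((s + s.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(s, 1.0)
    return SimilarityMatrix(tuple(gene_ids), s)


def threshold_network(s: SimilarityMatrix, cfg: ThresholdConfig | float) -> Network:
    """Signum-function hard thresholding: link ij present iff s_ij >= tau.

    The diagonal never produces links; the output carries the full gene
    universe so isolated genes remain known downstream.
    """
    tau = cfg.tau if isinstance(cfg, ThresholdConfig) else float(cfg)
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau must lie in [0, 1], got {tau}")
    adj = s.values >= tau
    ii, jj = np.where(np.triu(adj, k=1))
    edges = [(s.gene_ids[i], s.gene_ids[j]) for i, j in zip(ii, jj)]
    return Network.from_edges(s.gene_ids, edges)


# -- I/O ----------------------------------------------------------------


def write_similarity(s: SimilarityMatrix, path: str | Path, *, delimiter: str = "\t") -> None:
    s.to_frame().to_csv(path, sep=delimiter, index_label="")


def read_similarity(path: str | Path, *, delimiter: str = "\t") -> SimilarityMatrix:
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    return SimilarityMatrix(tuple(map(str, df.index)), df.to_numpy(dtype=float))


def adjacency_frame(net: Network) -> pd.DataFrame:
    """0/1 adjacency matrix of a network as a labelled DataFrame."""
    ids = list(net.universe)
    pos = {g: k for k, g in enumerate(ids)}
    a = np.zeros((len(ids), len(ids)), dtype=int)
    for x, y in net.links:
        a[pos[x], pos[y]] = a[pos[y], pos[x]] = 1
    return pd.DataFrame(a, index=ids, columns=ids)
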