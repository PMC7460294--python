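"""Expression-matrix I/O, the microarray experimental situation, and the
out-of-range discriminant.

A microarray experimental situation (MES) bundles a gene set with two
expression matrices over the same genes: a reference matrix (normal
tissue samples) and a disease matrix.  The discriminant step zeroes
every disease entry that falls inside the reference range of its gene
and keeps abnormal entries verbatim; booleanization then flags abnormal
entries with 1.  Matrices are genes × samples throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


def _validate_ids(ids: Sequence[str], what: str) -> tuple[str, ...]:
    ids = tuple(str(x) for x in ids)
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if list(ids).count(x) > 1})
        raise ValueError(f"duplicate {what} identifiers: {dupes}")
    if not ids:
        raise ValueError(f"empty {what} identifier list")
    return ids


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes × samples matrix of real expression values.

    Units are whatever the upstream platform produced (raw intensities or
    log-ratios); the algorithms downstream only compare values within a
    gene, so the scale is opaque here.  Missing values are a hard error.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", _validate_ids(self.gene_ids, "gene"))
        object.__setattr__(self, "sample_ids", _validate_ids(self.sample_ids, "sample"))
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"value matrix shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.isfinite(values).all():
            gi, sj = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.gene_ids[gi]!r}, "
                f"sample {self.sample_ids[sj]!r}"
            )
        values = values.copy()
        values.setflags(write=False)
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=list(self.sample_ids))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)), df.to_numpy(dtype=float))


def load_expression_matrix(
    path: str | Path, *, delimiter: str = "\t", transpose: bool = False
) -> ExpressionMatrix:
    """Read a delimited expression table: header row of sample ids, first
    column of gene ids.  Row and column order are preserved.

    Raises a parse error naming the offending gene/sample on any cell
    that is not a finite real, and a validation error on duplicate ids.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str, keep_default_na=False)
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene identifiers {dupes}")
    numeric = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = numeric.isna() | ~np.isfinite(numeric.to_numpy(dtype=float))
    if bad.to_numpy().any():
        gi, sj = np.argwhere(bad.to_numpy())[0]
        cell = raw.iat[gi, sj]
        raise ValueError(
            f"{path}: cannot parse cell {cell!r} at gene {raw.index[gi]!r}, "
            f"column {raw.columns[sj]!r} as a finite real"
        )
    if transpose:
        numeric = numeric.T
    return ExpressionMatrix.from_frame(numeric)


def write_matrix(
    gene_ids: Sequence[str],
    col_ids: Sequence[str],
    values: np.ndarray,
    path: str | Path,
    *,
    delimiter: str = "\t",
) -> None:
    """Write any genes × columns matrix in the shared delimited layout."""
    pd.DataFrame(values, index=list(gene_ids), columns=list(col_ids)).to_csv(
        path, sep=delimiter, index_label=""
    )


@dataclass(frozen=True)
class MES:
    """Microarray experimental situation: genes + reference and disease
    expression matrices sharing the same gene set, in the same order."""

    reference: ExpressionMatrix
    disease: ExpressionMatrix

    def __post_init__(self) -> None:
        if self.reference.gene_ids != self.disease.gene_ids:
            raise ValueError("reference and disease matrices must share the same gene ids in order")

    @property
    def genes(self) -> tuple[str, ...]:
        return self.reference.gene_ids

    @property
    def n_reference(self) -> int:
        return len(self.reference.sample_ids)

    @property
    def n_disease(self) -> int:
        return len(self.disease.sample_ids)


@dataclass(frozen=True)
class DiscriminantMatrix:
    """Genes × disease-samples matrix where 0 marks in-range (normal)
    behaviour and any nonzero entry is the retained abnormal value."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        ExpressionMatrix.__post_init__(self)  # same shape/finite/dupe checks

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=list(self.sample_ids))


@dataclass(frozen=True)
class BooleanMatrix:
    """Genes × arrays {0,1} matrix flagging abnormally expressed entries."""

    gene_ids: tuple[str, ...]
    array_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", _validate_ids(self.gene_ids, "gene"))
        object.__setattr__(self, "array_ids", _validate_ids(self.array_ids, "array"))
        values = np.asarray(self.values)
        if not np.isin(values, (0, 1)).all():
            raise ValueError("Boolean matrix entries must be 0 or 1")
        values = values.astype(np.int8)
        values.setflags(write=False)
        object.__setattr__(self, "values", values)

    def column_supports(self) -> list[frozenset[str]]:
        """sp(B.j) for each array j: the genes flagged 1 on that array."""
        genes = np.asarray(self.gene_ids)
        return [frozenset(genes[self.values[:, j] == 1]) for j in range(self.values.shape[1])]


def apply_discriminant(mes: MES) -> DiscriminantMatrix:
    """Out-of-range discriminant: a disease entry is zeroed when it lies
    within [min, max] of its gene's values across ALL reference samples,
    and kept verbatim otherwise.

    The output never invents values: nonzero entries equal the disease
    matrix entries bit-for-bit, and the result depends on the reference
    matrix only through each gene's min and max.
    """
    lo = mes.reference.values.min(axis=1, keepdims=True)
    hi = mes.reference.values.max(axis=1, keepdims=True)
    d = mes.disease.values
    in_range = (lo <= d) & (d <= hi)
    out = np.where(in_range, 0.0, d)
    return DiscriminantMatrix(mes.disease.gene_ids, mes.disease.sample_ids, out)


def booleanize(d: DiscriminantMatrix) -> BooleanMatrix:
    """1 where the discriminant kept an abnormal value, 0 elsewhere."""
    return BooleanMatrix(d.gene_ids, d.sample_ids, (d.values != 0).astype(np.int8))


def warn_if_degenerate(d: DiscriminantMatrix) -> None:
    """Emit a warning for all-zero rows (genes never abnormal): their
    correlation with any partner is undefined and maps to similarity 0."""
    constant = np.ptp(d.values, axis=1) == 0
    if constant.any():
        names = [g for g, c in zip(d.gene_ids, constant) if c]
        warnings.warn(
            f"{len(names)} gene(s) have constant discriminant rows "
            f"(similarity 0 to all partners): {names[:5]}...",
            stacklevel=2,
        )
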