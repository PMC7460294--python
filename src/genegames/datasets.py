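"""Bundled demonstration data: a five-gene microarray experiment.

A tiny hand-checkable experimental situation — five genes, four normal
samples, three disease samples — whose out-of-range discriminant,
similarity matrix, and hard-threshold networks can all be verified by
hand.  At tau = 0.8 the co-expression network is {12, 23, 45}; at 0.6
it gains links 13, 15, and 34.  Used by the docs, the test suite, and
the acceptance script.
"""

from __future__ import annotations

import numpy as np

from .expression import MES, ExpressionMatrix

GENES = ("1", "2", "3", "4", "5")

_REFERENCE = np.array(
    [
        [0.4, 0.2, 0.3, 0.6],
        [-12.0, 10.0, 4.0, 5.0],
        [4.8, 3.5, 5.5, 6.3],
        [12.0, 14.0, 17.0, 19.0],
        [3.1, 4.6, 7.2, 5.6],
    ]
)

_DISEASE = np.array(
    [
        [0.9, 0.4, 0.1],
        [-11.0, 13.0, 18.0],
        [2.7, 1.9, 5.6],
        [10.0, 20.0, 15.0],
        [2.1, 6.3, 1.9],
    ]
)


def five_gene_mes() -> MES:
    """The five-gene demonstration experimental situation."""
    ref = ExpressionMatrix(GENES, ("s1", "s2", "s3", "s4"), _REFERENCE)
    dis = ExpressionMatrix(GENES, ("d1", "d2", "d3"), _DISEASE)
    return MES(ref, dis)


def write_five_gene_tables(out_dir, *, delimiter: str = "\t") -> tuple[str, str]:
    """Write the demonstration matrices as TSV; returns the two paths."""
    from pathlib import Path

    from .expression import write_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mes = five_gene_mes()
    ref_path, dis_path = out / "reference.tsv", out / "disease.tsv"
    write_matrix(GENES, mes.reference.sample_ids, _REFERENCE, ref_path, delimiter=delimiter)
    write_matrix(GENES, mes.disease.sample_ids, _DISEASE, dis_path, delimiter=delimiter)
    return str(ref_path), str(dis_path)
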