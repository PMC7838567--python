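"""Pairwise structure similarity from key multisets.

Two proteins are compared through their key-frequency vectors with the
generalized Jaccard coefficient

    J(a, b) = sum_k min(a_k, b_k) / sum_k max(a_k, b_k)

over the union of their keys, or with a modified variant whose
denominator is capped by the larger protein's total key count,

    mJ(a, b) = sum_k min(a_k, b_k) / min(sum_k max(a_k, b_k), max(N_a, N_b)).

Distance is 1 - similarity.  Signed (mirror-mode) keys compare as
distinct keys: a key and its negation never match.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .keygen import KeyVector

__all__ = [
    "SimilarityMatrix",
    "generalized_jaccard",
    "modified_generalized_jaccard",
    "similarity_matrix",
    "distance_matrix",
]

MEASURES = ("generalized_jaccard", "modified_generalized_jaccard")


@dataclass
class SimilarityMatrix:
    ids: list[str]
    values: np.ndarray
    measure: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def _min_max_sums(a: KeyVector, b: KeyVector) -> tuple[int, int]:
    if not a.counts and not b.counts:
        raise ValueError("similarity of two empty key vectors is undefined")
    summin = 0
    summax = 0
    bc = b.counts
    for k, ca in a.counts.items():
        cb = bc.get(k, 0)
        summin += ca if ca < cb else cb
        summax += ca if ca > cb else cb
    for k, cb in bc.items():
        if k not in a.counts:
            summax += cb
    return summin, summax


def generalized_jaccard(a: KeyVector, b: KeyVector) -> float:
    """Multiset Jaccard similarity in [0, 1]; 1 for identical vectors."""
    summin, summax = _min_max_sums(a, b)
    return summin / summax


def modified_generalized_jaccard(
    a: KeyVector, b: KeyVector, total: str = "with_multiplicity"
) -> float:
    """Generalized Jaccard with the denominator capped at max(N_a, N_b).

    ``N_p`` defaults to the protein's total key count with multiplicity
    (the number of kept triangles); ``total="distinct"`` uses distinct
    key counts instead.  Never smaller than the plain generalized
    Jaccard on the same pair.
    """
    summin, summax = _min_max_sums(a, b)
    if total == "with_multiplicity":
        na, nb = a.total_triangles, b.total_triangles
    elif total == "distinct":
        na, nb = a.n_distinct, b.n_distinct
    else:
        raise ValueError(f"unknown total mode {total!r}")
    return summin / min(summax, max(na, nb))


def similarity_matrix(
    vectors: Sequence[KeyVector], measure: str = "generalized_jaccard"
) -> SimilarityMatrix:
    """All-against-all similarity of a list of key vectors."""
    if len(vectors) < 2:
        raise ValueError("need at least two key vectors")
    ids = [v.protein_id for v in vectors]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids")
    if measure == "generalized_jaccard":
        fn = generalized_jaccard
    elif measure == "modified_generalized_jaccard":
        fn = modified_generalized_jaccard
    else:
        raise ValueError(f"unknown measure {measure!r}")
    n = len(vectors)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = fn(vectors[i], vectors[j])
    return SimilarityMatrix(ids=ids, values=out, measure=measure)


def distance_matrix(sim: SimilarityMatrix) -> pd.DataFrame:
    """Element-wise 1 - similarity, zero diagonal."""
    d = 1.0 - sim.values
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=sim.ids, columns=sim.ids)
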