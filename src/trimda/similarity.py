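"""Similarity integration and graph-Laplacian construction.

miRNA similarity may come from several sources (e.g. functional similarity
and sequence similarity); disease similarity from two semantic-similarity
variants. The integrated similarity per entity type is their elementwise
average. The unnormalized graph Laplacian L = D - S of the integrated
similarity drives the smoothness regularizers tr(P^T L_m P) and
tr(Q^T L_d Q) of the factor model: feature vectors of similar entities are
pulled together.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SimilarityMatrix",
    "LaplacianMatrix",
    "integrate_similarity",
    "build_laplacian",
]


@dataclass
class SimilarityMatrix:
    """A square symmetric similarity matrix in [0, 1] keyed to an id list.

    Invariants (enforced by :meth:`validate`): ``S == S.T`` exactly,
    unit diagonal, entries in [0, 1], ids unique and of matching length.
    """

    ids: list[str]
    S: np.ndarray

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.S = np.asarray(self.S, dtype=float)

    @property
    def n(self) -> int:
        return len(self.ids)

    def validate(self, atol: float = 1e-6) -> "SimilarityMatrix":
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in similarity matrix")
        n = len(self.ids)
        if self.S.shape != (n, n):
            raise ValueError(f"similarity shape {self.S.shape} != ({n}, {n})")
        if not np.array_equal(self.S, self.S.T):
            raise ValueError("similarity matrix not exactly symmetric")
        if not np.allclose(np.diag(self.S), 1.0, atol=atol):
            raise ValueError("similarity diagonal must be 1")
        if self.S.min() < -atol or self.S.max() > 1 + atol:
            raise ValueError("similarity values outside [0, 1]")
        return self


@dataclass
class LaplacianMatrix:
    """Unnormalized graph Laplacian L = diag(rowsums(S)) - S.

    ``degree`` holds the row sums of the source similarity. L is symmetric
    positive semidefinite with zero row sums; tr(X^T L X) equals
    (1/2) * sum_ij S_ij * ||X_i - X_j||^2 for any feature matrix X.
    """

    L: np.ndarray
    degree: np.ndarray = field(repr=False)


def integrate_similarity(sources: Sequence[SimilarityMatrix]) -> SimilarityMatrix:
    """Elementwise arithmetic mean of similarity matrices over identical ids.

    A single source is passed through unchanged (up to a defensive copy).
    """
    if len(sources) == 0:
        raise ValueError("at least one similarity source required")
    ids0 = sources[0].ids
    for src in sources[1:]:
        if src.ids != ids0:
            raise ValueError("similarity sources have mismatched id lists")
    S = np.mean([src.S for src in sources], axis=0)
    # exact symmetry is preserved by the mean of exactly-symmetric inputs,
    # but guard against accumulated rounding anyway
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(ids=list(ids0), S=S).validate()


def build_laplacian(sim: SimilarityMatrix) -> LaplacianMatrix:
    """L = D - S with D the diagonal matrix of row sums of S."""
    S = sim.S
    degree = S.sum(axis=1)
    L = np.diag(degree) - S
    L = (L + L.T) / 2.0
    return LaplacianMatrix(L=L, degree=degree)
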