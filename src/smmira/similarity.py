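"""Integration and normalization of entity similarity matrices.

A prediction run consumes one similarity matrix per entity type (small
molecules and miRNAs).  Real data typically provides several similarity
sources per type (chemical structure, side effects, gene-set functional
consistency, ...); this module fuses them into a single matrix by a
weighted elementwise average and then applies a symmetric degree
normalization so that rows/columns with very different total similarity
mass become comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass
class SimilarityMatrix:
    """A square, non-negative similarity matrix with entity identifiers.

    Attributes
    ----------
    S : ndarray
        Square matrix of pairwise similarities, entries >= 0.
    ids : list of str
        Entity identifiers, one per row/column, in matrix order.
    """

    S: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.ids = list(self.ids)
        if self.S.ndim != 2 or self.S.shape[0] != self.S.shape[1]:
            raise ValueError(f"similarity matrix must be square, got {self.S.shape}")
        if len(self.ids) != self.S.shape[0]:
            raise ValueError(
                f"{len(self.ids)} ids for a {self.S.shape[0]}x{self.S.shape[1]} matrix"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("similarity ids must be unique")
        if np.any(self.S < 0):
            raise ValueError("similarity entries must be non-negative")

    @property
    def n(self) -> int:
        return self.S.shape[0]


@dataclass
class SimilaritySet:
    """An ordered collection of same-shaped similarity matrices with weights."""

    matrices: list[SimilarityMatrix]
    weights: Sequence[float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.matrices:
            raise ValueError("at least one similarity matrix is required")
        if self.weights is None:
            # equal contribution of every source is the default
            self.weights = [1.0] * len(self.matrices)
        self.weights = [float(w) for w in self.weights]
        if len(self.weights) != len(self.matrices):
            raise ValueError("one weight per matrix required")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be non-negative")
        first = self.matrices[0]
        for m in self.matrices[1:]:
            if m.S.shape != first.S.shape:
                raise ValueError("all similarity matrices must share a shape")
            if m.ids != first.ids:
                raise ValueError("all similarity matrices must share id ordering")


def integrate_similarities(simset: SimilaritySet) -> SimilarityMatrix:
    """Fuse several similarity sources into one matrix.

    The result is the weighted elementwise average
    ``sum_i w_i S_i / sum_i w_i``.  With all weights equal (the default)
    every source contributes equally and the result is the elementwise mean.
    """
    wsum = float(sum(simset.weights))
    if wsum <= 0:
        raise ValueError("at least one weight must be positive")
    acc = np.zeros_like(simset.matrices[0].S)
    for w, m in zip(simset.weights, simset.matrices):
        acc += w * m.S
    return SimilarityMatrix(acc / wsum, simset.matrices[0].ids)


def normalize_similarity(sim: SimilarityMatrix, style: str = "sqrt") -> SimilarityMatrix:
    """Normalize a similarity matrix by its row and column sums.

    With ``style="sqrt"`` (default) entry (i, j) becomes
    ``S_ij / sqrt(rowsum_i * colsum_j)`` — the symmetric normalization that
    parallels the D^{-1/2} S D^{-1/2} convention used for graph adjacency
    matrices and is invariant to a global rescaling of S.  ``style="product"``
    divides by the plain product ``rowsum_i * colsum_j`` instead.

    Entries that are exactly zero stay zero even when their row or column sum
    vanishes, so all-zero rows/columns pass through without division errors.
    """
    if style not in ("sqrt", "product"):
        raise ValueError(f"unknown norm_style {style!r}")
    S = sim.S
    rowsum = S.sum(axis=1)
    colsum = S.sum(axis=0)
    nz = S != 0
    # a nonzero entry forces its row and column sums positive (entries >= 0)
    assert np.all(rowsum[np.any(nz, axis=1)] > 0)
    assert np.all(colsum[np.any(nz, axis=0)] > 0)
    denom = np.outer(rowsum, colsum)
    if style == "sqrt":
        denom = np.sqrt(denom)
    out = np.zeros_like(S)
    np.divide(S, denom, out=out, where=nz)
    return SimilarityMatrix(out, sim.ids)
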