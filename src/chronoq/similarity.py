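"""Pairwise similarity model, ordering objective and validity constraint.

Samples are points in gene-expression space. The similarity between two
samples is ``W - d(s_i, s_j)`` where ``d`` is the Euclidean distance and
``W`` a large constant, so that *more similar* means *closer*. An ordering
is scored by the sum of similarities over consecutive samples (the overall
similarity ``Sim``), which the temporal-ordering objective maximises.

An ordering is *valid* when every sample is at least as similar to its
immediate successor as to any sample placed later in the sequence
(successor dominance over the remaining suffix). Validity is direction
sensitive: the reverse of a valid ordering need not be valid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InputError

__all__ = [
    "SimilarityMatrix",
    "Ordering",
    "euclidean_distance",
    "similarity_from_expression",
    "overall_similarity",
    "is_valid_ordering",
    "check_permutation",
]

#: An ordering is a permutation of the 0-based sample indices.
Ordering = tuple[int, ...]


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise similarity between samples.

    The diagonal is undefined and never consulted (stored as NaN); only
    off-diagonal entries of distinct adjacent pairs enter the objective.

    Parameters
    ----------
    sample_ids
        Sample identifiers, one per row/column.
    sim
        Symmetric ``n x n`` matrix of similarities.
    construction_constant
        The large constant ``W`` used when the matrix was derived from
        expression vectors; ``None`` when the matrix was read directly.
    """

    sample_ids: list[str]
    sim: np.ndarray
    construction_constant: float | None = None

    def __post_init__(self) -> None:
        self.sim = np.asarray(self.sim, dtype=float)
        n = len(self.sample_ids)
        if self.sim.shape != (n, n):
            raise InputError(
                f"similarity matrix shape {self.sim.shape} does not match "
                f"{n} sample ids"
            )
        if len(set(self.sample_ids)) != n:
            raise InputError("duplicate sample ids in similarity matrix")
        off = ~np.eye(n, dtype=bool)
        if not np.all(np.isfinite(self.sim[off])):
            raise InputError("non-finite off-diagonal similarity entries")
        if not np.allclose(self.sim[off], self.sim.T[off], atol=1e-9, rtol=0.0):
            raise InputError("similarity matrix is not symmetric")
        # diagonal is meaningless by construction; normalise it to NaN
        np.fill_diagonal(self.sim, np.nan)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def value(self, i: int, j: int) -> float:
        """Similarity between distinct samples ``i`` and ``j`` (0-based)."""
        if i == j:
            raise InputError("self-similarity is undefined")
        return float(self.sim[i, j])

    def max_offdiagonal(self) -> float:
        off = ~np.eye(self.n, dtype=bool)
        return float(np.max(self.sim[off]))


def check_permutation(ordering: Sequence[int], n: int) -> Ordering:
    """Validate that ``ordering`` is a permutation of ``range(n)``."""
    perm = tuple(int(i) for i in ordering)
    if sorted(perm) != list(range(n)):
        raise InputError(f"{perm!r} is not a permutation of 0..{n - 1}")
    return perm


def euclidean_distance(u: Sequence[float], v: Sequence[float]) -> float:
    """L2 norm of ``u - v``."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise InputError(f"length mismatch: {u.shape} vs {v.shape}")
    return float(np.linalg.norm(u - v))


def similarity_from_expression(matrix, constant: float | str = "auto") -> SimilarityMatrix:
    """Build the pairwise similarity matrix ``sim = W - d`` from expression.

    With ``constant="auto"``, ``W`` is the maximum pairwise distance plus
    one, which makes every similarity at least 1 and leaves the maximiser
    of the objective unchanged (the objective is affine in ``W``).

    Parameters
    ----------
    matrix
        An :class:`~chronoq.dataset_io.ExpressionMatrix` without missing
        entries; samples are its columns.
    constant
        The large constant ``W``, or ``"auto"``.
    """
    if matrix.has_missing():
        raise InputError("expression matrix has missing entries; preprocess first")
    X = matrix.values.T  # samples x genes
    from scipy.spatial.distance import squareform, pdist

    dist = squareform(pdist(X, metric="euclidean"))
    if constant == "auto":
        w = float(dist.max()) + 1.0
    else:
        w = float(constant)
        if w < dist.max():
            warnings.warn(
                "similarity constant is smaller than the maximum pairwise "
                "distance; negative similarities will occur",
                stacklevel=2,
            )
    sim = w - dist
    return SimilarityMatrix(list(matrix.sample_ids), sim, construction_constant=w)


def overall_similarity(ordering: Sequence[int], S: SimilarityMatrix) -> float:
    """Sum of similarities over consecutive samples of ``ordering``.

    Zero when the ordering has a single sample.
    """
    perm = check_permutation(ordering, S.n)
    if len(perm) < 2:
        return 0.0
    idx = np.asarray(perm)
    return float(np.sum(S.sim[idx[:-1], idx[1:]]))


def is_valid_ordering(ordering: Sequence[int], S: SimilarityMatrix) -> bool:
    """Successor dominance over the remaining suffix.

    True iff for every position ``i`` and every later position ``j > i+1``,
    ``sim(t_i, t_{i+1}) >= sim(t_i, t_j)``. Non-strict, so ties never
    invalidate an ordering.
    """
    perm = check_permutation(ordering, S.n)
    n = len(perm)
    for i in range(n - 2):
        succ = S.sim[perm[i], perm[i + 1]]
        later = S.sim[perm[i], list(perm[i + 2:])]
        if np.any(later > succ):
            return False
    return True
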