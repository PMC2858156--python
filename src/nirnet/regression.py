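"""Gram-matrix least squares for candidate regulator subsets.

Best-subset regression evaluates the same normal equations
``(X_S X_S^T) b = X_S y^T`` for an enormous number of regulator subsets
``S``.  The product ``G = X X^T`` is therefore computed once; every
candidate regression afterwards only extracts the symmetric submatrix
``G_S`` (rows and columns of ``S``) and the matching entries of the
projection ``X y^T``, so its cost no longer depends on the number of
experiments.  The s x s system is solved by Cholesky factorization in
packed storage (LAPACK ``dppsv``), and the residual sum of squares follows
algebraically as ``rss = y y^T - b . (X y^T)_S`` without touching ``X``
again.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import lapack

from .matrices import ExpressionMatrix, PerturbationDesign

__all__ = [
    "GramMatrix",
    "ResponseProjection",
    "SubsetSolution",
    "SingularCandidate",
    "compute_gram",
    "response_projection",
    "subset_least_squares",
]


@dataclass
class GramMatrix:
    """``G = X X^T`` with the gene labels of the source expression matrix."""

    values: np.ndarray
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.gene_ids)
        if self.values.shape != (n, n):
            raise ValueError("Gram matrix shape does not match gene labels")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]


@dataclass
class ResponseProjection:
    """Gram-side view of one target gene's regression response.

    ``xty = X y^T`` and ``yty = y y^T`` where ``y`` is the (sign-flipped)
    perturbation profile of the target gene; together with ``G`` they are
    all any subset regression needs.
    """

    xty: np.ndarray
    yty: float
    gene: int

    def __post_init__(self) -> None:
        self.xty = np.asarray(self.xty, dtype=float)
        if self.yty < 0:
            raise ValueError("yty must be non-negative")


@dataclass
class SubsetSolution:
    """Least-squares fit of one regulator subset: coefficients and rss."""

    subset: tuple[int, ...]
    coefficients: np.ndarray
    rss: float


@dataclass
class SingularCandidate:
    """Signal that a subset's normal matrix is not positive definite.

    Returned (never raised) when Cholesky factorization fails, i.e. the
    candidate regressors are linearly dependent; such candidates are simply
    excluded from the search.
    """

    subset: tuple[int, ...]


def compute_gram(X: ExpressionMatrix | np.ndarray) -> GramMatrix:
    """Compute ``G = X X^T`` once, symmetrized exactly."""
    if isinstance(X, ExpressionMatrix):
        vals, ids = X.values, X.gene_ids
    else:
        vals = np.asarray(X, dtype=float)
        ids = [f"g{i + 1}" for i in range(vals.shape[0])]
    G = vals @ vals.T
    G = (G + G.T) / 2.0
    return GramMatrix(G, list(ids))


def response_projection(
    X: ExpressionMatrix, P: PerturbationDesign, gene: int
) -> ResponseProjection:
    """Project gene ``gene``'s regression response onto the Gram side.

    The steady-state model gives ``sum_j a_ij x_j + p_i = 0``, so the
    response regressed on the transcript rows is ``y = -p_i``.  For a
    canonical design (one unit perturbation per experiment) ``X y^T``
    reduces to minus the column of ``X`` belonging to the experiment that
    perturbs the gene — no product is formed.
    """
    n = X.n_genes
    if not 0 <= gene < n:
        raise IndexError(f"gene index {gene} out of range for {n} genes")
    if X.values.shape != P.values.shape:
        raise ValueError("expression and perturbation matrices differ in shape")
    p_row = P.values[gene]
    if P.canonical:
        cols = np.flatnonzero(p_row)
        xty = np.zeros(n)
        yty = 0.0
        if cols.size:
            # unit magnitude: y has a single -1 entry
            xty = -X.values[:, cols[0]].copy()
            yty = 1.0
            for c in cols[1:]:  # same gene perturbed in several experiments
                xty -= X.values[:, c]
                yty += 1.0
    else:
        y = -p_row
        xty = X.values @ y
        yty = float(y @ y)
    return ResponseProjection(xty, yty, gene)


def _pack_upper(A: np.ndarray) -> np.ndarray:
    """Upper triangle of a symmetric matrix in LAPACK column-major packed order."""
    s = A.shape[0]
    ap = np.empty(s * (s + 1) // 2)
    pos = 0
    for j in range(s):
        ap[pos : pos + j + 1] = A[: j + 1, j]
        pos += j + 1
    return ap


def subset_least_squares(
    G: GramMatrix | np.ndarray,
    proj: ResponseProjection,
    subset: Sequence[int],
) -> SubsetSolution | SingularCandidate:
    """Solve the normal equations restricted to ``subset``.

    Extracts the packed symmetric submatrix ``G_S``, solves
    ``G_S b = (X y^T)_S`` via packed Cholesky (``dppsv``) and returns the
    coefficients with ``rss = y y^T - b . (X y^T)_S`` clamped at zero.
    A failed factorization yields :class:`SingularCandidate`.
    """
    Gv = G.values if isinstance(G, GramMatrix) else np.asarray(G, dtype=float)
    idx = np.asarray(subset, dtype=np.intp)
    if idx.size == 0:
        raise ValueError("subset must be non-empty")
    if np.any(np.diff(idx) <= 0):
        raise ValueError("subset must be strictly increasing")
    if idx[0] < 0 or idx[-1] >= Gv.shape[0]:
        raise IndexError("subset index out of range")
    sub = tuple(int(i) for i in idx)
    Gs = Gv[np.ix_(idx, idx)]
    rhs = proj.xty[idx]
    x, info = lapack.dppsv(len(sub), _pack_upper(Gs), rhs[:, None])
    if info != 0:
        return SingularCandidate(sub)
    b = x.ravel().copy()
    rss = max(0.0, proj.yty - float(b @ rhs))
    return SubsetSolution(sub, b, rss)
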