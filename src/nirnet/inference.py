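"""Network inference by per-gene best-subset regression with a beam search.

For every target gene the algorithm looks for the set of at most ``k``
regulator transcripts whose expression profiles best explain the applied
perturbations in the least-squares sense.  Exhaustive best-subset selection
is combinatorial, so a greedy beam heuristic is used instead: step 1 scores
every single regressor; each later step extends the ``beam_width`` best
surviving sets with every unused regressor (duplicate sets merged), and
after step ``k`` the size-``k`` set with minimal residual sum of squares
wins.  Genes are independent, so the per-gene work is distributed over a
worker pool; the result is identical for every worker count.

The public surface is the scikit-learn style estimator :class:`NIR`
(``fit(X, P)`` then ``network_``/``coef_``) plus thin functional wrappers.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
from joblib import Parallel, delayed
from sklearn.base import BaseEstimator

from .matrices import ExpressionMatrix, GeneNetwork, PerturbationDesign
from .regression import (
    GramMatrix,
    ResponseProjection,
    SingularCandidate,
    SubsetSolution,
    compute_gram,
    response_projection,
    subset_least_squares,
)

__all__ = [
    "NIRConfig",
    "BeamCandidate",
    "GeneFailure",
    "EvalCounter",
    "NIR",
    "greedy_gene_regression",
    "infer_network",
    "run_parallel",
]

#: relative magnitude below which a fitted coefficient is treated as zero
#: when edges are assembled (exactly-fitted supports pad the k-set with
#: machine-epsilon coefficients that are not edges)
PRUNE_REL_TOL = 1e-8


@dataclass
class NIRConfig:
    """Search parameters.

    k: sparsity bound — maximum ingoing edges per gene.
    beam_width: candidate sets retained per step (defaults to ``k``).
    workers: degree of gene-level parallelism.
    allow_self: whether a gene's own transcript competes as a regressor
        (the degradation term is a self-influence, so the default is True).
    """

    k: int = 10
    beam_width: int | None = None
    workers: int = 1
    allow_self: bool = True

    def __post_init__(self) -> None:
        if self.beam_width is None:
            self.beam_width = self.k
        if self.k < 1 or self.beam_width < 1 or self.workers < 1:
            raise ValueError("k, beam_width and workers must all be >= 1")

    def pool_size(self, n_genes: int) -> int:
        return n_genes if self.allow_self else n_genes - 1

    def validate_for(self, n_genes: int) -> None:
        pool = self.pool_size(n_genes)
        if self.k > pool:
            raise ValueError(
                f"k={self.k} exceeds the candidate regressor pool ({pool}); "
                "refusing to clamp silently"
            )


@dataclass
class BeamCandidate:
    """One surviving regulator set during the beam search."""

    subset: tuple[int, ...]
    rss: float


@dataclass
class GeneFailure:
    """Per-gene failure: every size-k candidate was singular."""

    gene: int
    reason: str = "all candidate subsets singular"


class EvalCounter:
    """Counts unique candidate subsets evaluated (instrumentation)."""

    def __init__(self) -> None:
        self.count = 0


@dataclass
class _Node:
    """Internal beam node: subset in insertion order with its Cholesky state.

    ``L`` is the Cholesky factor of ``G_S`` in ``order``'s ordering and
    ``c = L^{-1} (X y^T)_S``, so ``rss = yty - c.c`` and extensions cost a
    single triangular solve, independent of the number of experiments.
    """

    order: tuple[int, ...]
    members: frozenset[int]
    L: np.ndarray
    c: np.ndarray
    rss: float
    key: tuple[int, ...] = field(default=())  # sorted subset, for tie-breaks


def _score_extensions(
    node: _Node, js: np.ndarray, Gv: np.ndarray, diag: np.ndarray, xty: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized rss of ``node``'s subset extended by each index in ``js``.

    Returns (rss, d) where d is each extension's Cholesky pivot; d <= 0
    marks a singular (linearly dependent) extension.
    """
    s = len(node.order)
    if s == 0:
        d = diag[js].astype(float)
        num = xty[js]
    else:
        B = Gv[np.ix_(np.asarray(node.order), js)]
        W = sla.solve_triangular(node.L, B, lower=True, check_finite=False)
        d = diag[js] - np.einsum("ij,ij->j", W, W)
        num = xty[js] - node.c @ W
    with np.errstate(divide="ignore", invalid="ignore"):
        rss = node.rss - np.where(d > 0, num * num / np.maximum(d, np.finfo(float).tiny), 0.0)
    return np.maximum(rss, 0.0), d


def _extend_node(node: _Node, j: int, Gv: np.ndarray, xty: np.ndarray, rss: float) -> _Node:
    s = len(node.order)
    if s == 0:
        d = Gv[j, j]
        L = np.array([[np.sqrt(d)]])
        c = np.array([xty[j] / np.sqrt(d)])
    else:
        w = sla.solve_triangular(
            node.L, Gv[np.asarray(node.order), j], lower=True, check_finite=False
        )
        d = max(Gv[j, j] - w @ w, np.finfo(float).tiny)  # scored d > 0 already
        L = np.zeros((s + 1, s + 1))
        L[:s, :s] = node.L
        L[s, :s] = w
        L[s, s] = np.sqrt(d)
        c = np.append(node.c, (xty[j] - w @ node.c) / L[s, s])
    order = node.order + (j,)
    key = tuple(sorted(order))
    return _Node(order, node.members | {j}, L, c, rss, key)


def greedy_gene_regression(
    gene: int,
    G: GramMatrix,
    proj: ResponseProjection,
    config: NIRConfig,
    counter: EvalCounter | None = None,
) -> SubsetSolution | GeneFailure:
    """Beam search over regulator subsets for one target gene.

    Returns the best size-``k`` :class:`~nirnet.regression.SubsetSolution`
    (coefficients from the packed-Cholesky solver), or a
    :class:`GeneFailure` if every candidate was singular.  Ties on rss are
    broken by the lexicographically smallest subset, which makes the result
    deterministic and independent of evaluation order.
    """
    Gv = G.values
    n = Gv.shape[0]
    config.validate_for(n)
    pool = [j for j in range(n) if config.allow_self or j != gene]
    diag = np.diag(Gv).copy()
    xty = proj.xty

    beam: list[_Node] = [_Node((), frozenset(), np.empty((0, 0)), np.empty(0), proj.yty)]
    for _ in range(config.k):
        # child key -> (rss, parent node, extension index)
        seen: dict[tuple[int, ...], tuple[float, _Node, int]] = {}
        for node in beam:
            fresh: list[tuple[int, tuple[int, ...]]] = []
            for j in pool:
                if j in node.members:
                    continue
                child = list(node.key)
                bisect.insort(child, j)
                ck = tuple(child)
                if ck in seen:
                    continue
                fresh.append((j, ck))
                seen[ck] = (np.inf, node, j)  # placeholder until scored
            if not fresh:
                continue
            js = np.asarray([j for j, _ in fresh], dtype=np.intp)
            rss, d = _score_extensions(node, js, Gv, diag, xty)
            for (j, ck), r, dj in zip(fresh, rss, d):
                if dj <= 0:  # singular extension: drop candidate
                    del seen[ck]
                else:
                    seen[ck] = (float(r), node, j)
        if counter is not None:
            counter.count += len(seen)
        if not seen:
            return GeneFailure(gene)
        ranked = sorted(seen.items(), key=lambda kv: (kv[1][0], kv[0]))
        beam = [
            _extend_node(parent, j, Gv, xty, rss)
            for _, (rss, parent, j) in ranked[: config.beam_width]
        ]
    best = min(beam, key=lambda nd: (nd.rss, nd.key))
    sol = subset_least_squares(G, proj, best.key)
    if isinstance(sol, SingularCandidate):
        return GeneFailure(gene, "final subset singular in packed solver")
    return sol


def run_parallel(
    genes: Sequence[int],
    worker_count: int,
    per_gene_task: Callable[[int], object],
) -> list[object]:
    """Run ``per_gene_task`` over ``genes`` on a static worker partition.

    Genes are split into ``worker_count`` near-equal contiguous blocks;
    workers share read-only inputs and never communicate, so results are
    reassembled in gene order and are invariant to ``worker_count``.
    A worker exception aborts the run naming the failing gene.
    """
    if worker_count < 1:
        raise ValueError("worker_count must be >= 1")
    genes = list(genes)

    def run_block(block: Sequence[int]) -> list[object]:
        out = []
        for g in block:
            try:
                out.append(per_gene_task(g))
            except Exception as exc:
                raise RuntimeError(f"worker failed on gene {g}: {exc}") from exc
        return out

    if worker_count == 1 or len(genes) <= 1:
        return run_block(genes)
    blocks = [b for b in np.array_split(np.asarray(genes), worker_count) if b.size]
    results = Parallel(n_jobs=min(worker_count, len(blocks)))(
        delayed(run_block)(list(map(int, b))) for b in blocks
    )
    return [r for block in results for r in block]


class NIR(BaseEstimator):
    """Sparse gene-network inference from steady-state perturbation data.

    Models expression deviations near the unperturbed steady state as
    ``A x + p = 0`` with a sparse influence matrix ``A`` and recovers, for
    each gene, the at-most-``k`` regulators minimizing the residual sum of
    squares of the regression of ``-p_i`` on the transcript profiles.

    Parameters
    ----------
    k : int
        Maximum ingoing edges (regulators) per gene.
    beam_width : int or None
        Candidate sets kept at each search step; ``None`` means ``k``.
    workers : int
        Worker processes for the gene-parallel loop.
    allow_self : bool
        Let a gene's own transcript compete as a regressor (default True;
        degradation is a self-influence).

    Attributes
    ----------
    network_ : GeneNetwork
        Inferred signed directed network; entry ``(i, j)`` is the influence
        of gene ``j`` on gene ``i``.
    coef_ : scipy.sparse.csr_array
        The same adjacency as a sparse matrix.
    failures_ : list of GeneFailure
        Genes for which no candidate subset was solvable.
    n_evaluations_ : numpy.ndarray
        Unique candidate subsets evaluated per gene (instrumentation).

    Examples
    --------
    >>> from nirnet.simulate import SimConfig, random_network, steady_state_data
    >>> truth = random_network(SimConfig(n_genes=20, avg_in_degree=2, seed=0))
    >>> X, P = steady_state_data(truth, SimConfig(n_genes=20, avg_in_degree=2,
    ...                                           noise_sd=0.0, seed=0))
    >>> net = NIR(k=4).fit(X, P).network_
    """

    def __init__(
        self,
        k: int = 10,
        beam_width: int | None = None,
        workers: int = 1,
        allow_self: bool = True,
    ) -> None:
        self.k = k
        self.beam_width = beam_width
        self.workers = workers
        self.allow_self = allow_self

    def _as_domain(
        self, X, P
    ) -> tuple[ExpressionMatrix, PerturbationDesign]:
        if not isinstance(X, ExpressionMatrix):
            X = np.asarray(X, dtype=float)
            X = ExpressionMatrix(
                [f"g{i + 1}" for i in range(X.shape[0])],
                [f"e{i + 1}" for i in range(X.shape[1])],
                X,
            )
        if not isinstance(P, PerturbationDesign):
            P = PerturbationDesign(list(X.gene_ids), list(X.experiment_ids),
                                   np.asarray(P, dtype=float))
        if X.values.shape != P.values.shape:
            raise ValueError(
                f"expression is {X.values.shape[0]}x{X.values.shape[1]} but "
                f"perturbation design is {P.values.shape[0]}x{P.values.shape[1]}"
            )
        if X.gene_ids != P.gene_ids:
            raise ValueError("expression and perturbation gene labels differ")
        if X.experiment_ids != P.experiment_ids:
            raise ValueError("expression and perturbation experiment labels differ")
        return X, P

    def fit(self, X, P, y=None) -> "NIR":
        """Infer the network from expression ``X`` and design ``P``.

        Both are genes x experiments, as :class:`ExpressionMatrix` /
        :class:`PerturbationDesign` or plain arrays.
        """
        X, P = self._as_domain(X, P)
        config = NIRConfig(
            k=self.k,
            beam_width=self.beam_width,
            workers=self.workers,
            allow_self=self.allow_self,
        )
        config.validate_for(X.n_genes)
        G = compute_gram(X)

        def task(gene: int) -> tuple[SubsetSolution | GeneFailure, int]:
            proj = response_projection(X, P, gene)
            counter = EvalCounter()
            res = greedy_gene_regression(gene, G, proj, config, counter)
            return res, counter.count

        results = run_parallel(range(X.n_genes), config.workers, task)

        n = X.n_genes
        rows, cols, data = [], [], []
        failures: list[GeneFailure] = []
        n_evals = np.zeros(n, dtype=int)
        for gene, (res, n_eval) in enumerate(results):
            n_evals[gene] = n_eval
            if isinstance(res, GeneFailure):
                failures.append(res)
                continue
            b = res.coefficients
            tol = PRUNE_REL_TOL * np.max(np.abs(b)) if b.size else 0.0
            for j, w in zip(res.subset, b):
                if abs(w) > tol:
                    rows.append(gene)
                    cols.append(j)
                    data.append(float(w))
        coef = sp.csr_array(sp.coo_array((data, (rows, cols)), shape=(n, n)))
        self.gene_ids_ = list(X.gene_ids)
        self.coef_ = coef
        self.network_ = GeneNetwork(list(X.gene_ids), coef.copy())
        self.failures_ = failures
        self.n_evaluations_ = n_evals
        self.n_features_in_ = n
        return self

    def fit_predict(self, X, P) -> GeneNetwork:
        return self.fit(X, P).network_


def infer_network(
    X: ExpressionMatrix,
    P: PerturbationDesign,
    config: NIRConfig | None = None,
) -> GeneNetwork:
    """Functional wrapper around :class:`NIR` (failures on ``est.failures_``)."""
    config = config or NIRConfig()
    est = NIR(
        k=config.k,
        beam_width=config.beam_width,
        workers=config.workers,
        allow_self=config.allow_self,
    )
    return est.fit(X, P).network_
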