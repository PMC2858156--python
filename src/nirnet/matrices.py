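"""Domain containers and tab-separated I/O.

The tool works on three labelled objects: a genes x experiments expression
matrix ``X`` of deviations from the unperturbed steady state, a matching
perturbation design ``P`` giving the perturbation magnitude applied to each
gene in each experiment, and a signed directed gene network stored as a
sparse adjacency matrix whose entry ``(i, j)`` is the influence of regulator
gene ``j`` on target gene ``i``.

All files are UTF-8 TSV: matrices carry a header row of experiment labels
and a first column of gene labels; networks are exchanged either as a
labelled adjacency matrix or as a three-column edge list
(regulator, target, weight).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "ExpressionMatrix",
    "PerturbationDesign",
    "GeneNetwork",
    "MatrixParseError",
    "read_matrix",
    "write_matrix",
    "read_network",
    "write_network",
]

#: significant digits used when serializing floats; 17 makes round trips exact
_FLOAT_FMT = "%.17g"


class MatrixParseError(ValueError):
    """Raised when a TSV file violates the matrix/network format."""


def _check_labels(labels: Sequence[str], what: str) -> list[str]:
    labels = [str(x) for x in labels]
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise MatrixParseError(f"duplicate {what} label: {lab!r}")
        seen.add(lab)
    return labels


@dataclass
class ExpressionMatrix:
    """Genes x experiments expression deviations from steady state."""

    gene_ids: list[str]
    experiment_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = _check_labels(self.gene_ids, "gene")
        self.experiment_ids = _check_labels(self.experiment_ids, "experiment")
        n, m = self.values.shape
        if len(self.gene_ids) != n or len(self.experiment_ids) != m:
            raise ValueError(
                f"label/matrix shape mismatch: {len(self.gene_ids)} genes, "
                f"{len(self.experiment_ids)} experiments vs values {self.values.shape}"
            )
        if n < 2 or m < 1:
            raise ValueError(f"need at least 2 genes and 1 experiment, got {n}x{m}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_experiments(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.experiment_ids)


@dataclass
class PerturbationDesign(ExpressionMatrix):
    """Genes x experiments perturbation magnitudes.

    ``canonical`` is true when every experiment perturbs exactly one gene
    with magnitude 1 (the single-gene unit-perturbation protocol); it is
    auto-detected unless given explicitly.
    """

    canonical: bool = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        super().__post_init__()
        detected = self._detect_canonical()
        if self.canonical is None:
            self.canonical = detected
        elif self.canonical and not detected:
            raise ValueError("design declared canonical but has a column that does not "
                             "apply exactly one unit perturbation")

    def _detect_canonical(self) -> bool:
        nz_per_col = np.count_nonzero(self.values, axis=0)
        if not np.all(nz_per_col == 1):
            return False
        return bool(np.all(self.values[self.values != 0] == 1.0))

    def perturbed_gene(self, experiment: int) -> int | None:
        """Index of the single gene perturbed in ``experiment`` (canonical only)."""
        nz = np.flatnonzero(self.values[:, experiment])
        return int(nz[0]) if nz.size == 1 else None


@dataclass
class GeneNetwork:
    """Signed weighted directed network; ``weights[i, j]`` = effect of j on i."""

    gene_ids: list[str]
    weights: sp.csr_array

    def __post_init__(self) -> None:
        self.gene_ids = _check_labels(self.gene_ids, "gene")
        w = sp.csr_array(self.weights, dtype=float)
        w.eliminate_zeros()
        n = len(self.gene_ids)
        if w.shape != (n, n):
            raise ValueError(f"weights shape {w.shape} does not match {n} gene labels")
        if w.nnz and not np.all(np.isfinite(w.data)):
            raise ValueError("network contains non-finite weights")
        self.weights = w

    @classmethod
    def from_edges(
        cls,
        gene_ids: Sequence[str],
        edges: Sequence[tuple[str, str, float]],
    ) -> "GeneNetwork":
        """Build from (regulator, target, weight) triples."""
        idx = {g: i for i, g in enumerate(gene_ids)}
        n = len(gene_ids)
        rows, cols, data = [], [], []
        for reg, tgt, w in edges:
            if reg not in idx or tgt not in idx:
                raise MatrixParseError(f"edge references unknown gene: {reg!r} -> {tgt!r}")
            rows.append(idx[tgt])
            cols.append(idx[reg])
            data.append(float(w))
        mat = sp.coo_array((data, (rows, cols)), shape=(n, n))
        return cls(list(gene_ids), sp.csr_array(mat))

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_edges(self) -> int:
        return int(self.weights.nnz)

    def edges(self) -> list[tuple[str, str, float]]:
        """Edges as (regulator, target, weight), sorted by labels."""
        coo = sp.coo_array(self.weights)
        out = [
            (self.gene_ids[j], self.gene_ids[i], float(w))
            for i, j, w in zip(coo.row, coo.col, coo.data)
        ]
        out.sort(key=lambda e: (e[0], e[1]))
        return out

    def dense(self) -> np.ndarray:
        return self.weights.toarray()


def _read_frame(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise MatrixParseError(f"{path}: cannot parse TSV ({exc})") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise MatrixParseError(f"{path}: duplicate gene label {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise MatrixParseError(f"{path}: duplicate experiment label {dup!r}")
    values = np.empty(df.shape, dtype=float)
    for i, (gene, row) in enumerate(df.iterrows()):
        for j, cell in enumerate(row):
            try:
                if not isinstance(cell, str):  # pandas pads ragged rows with NaN
                    raise ValueError
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise MatrixParseError(
                    f"{path}: non-numeric or missing cell at row {gene!r}, "
                    f"column {df.columns[j]!r}: {cell!r}"
                ) from None
    return pd.DataFrame(values, index=df.index.astype(str), columns=df.columns.astype(str))


def read_matrix(
    path: str | Path, kind: Literal["expression", "perturbation"] = "expression"
) -> ExpressionMatrix | PerturbationDesign:
    """Read a labelled genes x experiments TSV matrix.

    ``kind='perturbation'`` returns a :class:`PerturbationDesign` with its
    canonical flag auto-detected.
    """
    df = _read_frame(path)
    args = (list(df.index), list(df.columns), df.to_numpy())
    if kind == "expression":
        return ExpressionMatrix(*args)
    if kind == "perturbation":
        return PerturbationDesign(*args)
    raise ValueError(f"unknown matrix kind: {kind!r}")


def write_matrix(mat: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as labelled TSV (round-trips exactly)."""
    mat.to_frame().to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def write_network(
    net: GeneNetwork,
    path: str | Path,
    format: Literal["edge_list", "adjacency"] = "edge_list",
) -> None:
    """Serialize a network.

    ``edge_list`` emits a header plus one ``regulator<TAB>target<TAB>weight``
    line per edge; ``adjacency`` emits the full labelled dense matrix.
    """
    path = Path(path)
    if format == "edge_list":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("regulator\ttarget\tweight\n")
            for reg, tgt, w in net.edges():
                fh.write(f"{reg}\t{tgt}\t{_FLOAT_FMT % w}\n")
    elif format == "adjacency":
        pd.DataFrame(net.dense(), index=net.gene_ids, columns=net.gene_ids).to_csv(
            path, sep="\t", float_format=_FLOAT_FMT
        )
    else:
        raise ValueError(f"unknown network format: {format!r}")


def read_network(
    path: str | Path,
    format: Literal["edge_list", "adjacency"] = "edge_list",
    gene_ids: Sequence[str] | None = None,
) -> GeneNetwork:
    """Read a network written by :func:`write_network`.

    Edge lists do not carry isolated genes, so ``gene_ids`` may be supplied
    to fix the node set; otherwise it is the sorted set of genes appearing
    in edges.
    """
    path = Path(path)
    if format == "adjacency":
        df = _read_frame(path)
        vals = df.to_numpy()
        if gene_ids is not None and list(df.index) != list(gene_ids):
            raise MatrixParseError(f"{path}: adjacency gene labels do not match")
        return GeneNetwork(list(df.index), sp.csr_array(vals))
    if format != "edge_list":
        raise ValueError(f"unknown network format: {format!r}")
    edges: list[tuple[str, str, float]] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if header.strip() and header.split("\t")[0].strip() != "regulator":
            raise MatrixParseError(f"{path}: missing edge-list header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise MatrixParseError(f"{path}: line {lineno}: expected 3 columns")
            try:
                w = float(parts[2])
            except ValueError:
                raise MatrixParseError(
                    f"{path}: line {lineno}: non-numeric weight {parts[2]!r}"
                ) from None
            edges.append((parts[0], parts[1], w))
    if gene_ids is None:
        gene_ids = sorted({g for e in edges for g in e[:2]})
    return GeneNetwork.from_edges(gene_ids, edges)
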