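"""Accuracy scoring of inferred networks against a known truth.

Standard network-inference benchmarking: the inferred and true networks are
reduced to edge sets — directed (ordered regulator-target pairs), signed
(ordered pairs tagged with the weight's sign) or undirected (unordered
pairs, so orientation is ignored) — and compared by positive predictive
value PPV = TP/(TP+FP) and sensitivity Se = TP/(TP+FN).  Self-loops are
excluded by default: the model's degradation term makes the diagonal
structural, and scoring it would inflate both metrics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Hashable, Literal

import numpy as np
import scipy.sparse as sp

from .matrices import GeneNetwork

__all__ = ["EvalReport", "edge_set", "ppv_se", "random_baseline"]

Mode = Literal["directed", "undirected", "signed"]


@dataclass
class EvalReport:
    """Confusion counts and derived rates for one comparison.

    ``ppv``/``se`` are ``None`` when their denominator is zero (an empty
    prediction or an empty truth), never silently 0.
    """

    tp: int
    fp: int
    fn: int
    mode: Mode

    @property
    def ppv(self) -> float | None:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) > 0 else None

    @property
    def se(self) -> float | None:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) > 0 else None

    def as_dict(self) -> dict:
        return {
            "mode": self.mode,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "ppv": self.ppv,
            "se": self.se,
        }


def edge_set(
    net: GeneNetwork, mode: Mode = "directed", include_self: bool = False
) -> set[Hashable]:
    """Reduce a network to the edge set the chosen mode compares.

    directed: ordered (regulator, target) index pairs; signed: the same
    pairs tagged with the weight sign; undirected: frozensets of endpoint
    indices, so both orientations collapse to one element.
    """
    coo = sp.coo_array(net.weights)
    out: set[Hashable] = set()
    for i, j, w in zip(coo.row, coo.col, coo.data):
        if i == j and not include_self:
            continue
        if mode == "directed":
            out.add((int(j), int(i)))
        elif mode == "signed":
            out.add((int(j), int(i), 1 if w > 0 else -1))
        elif mode == "undirected":
            out.add(frozenset((int(i), int(j))) if i != j else frozenset((int(i),)))
        else:
            raise ValueError(f"unknown mode: {mode!r}")
    return out


def ppv_se(
    inferred: GeneNetwork,
    truth: GeneNetwork,
    mode: Mode = "directed",
    include_self: bool = False,
) -> EvalReport:
    """Score ``inferred`` against ``truth`` under ``mode``'s edge sets."""
    if inferred.gene_ids != truth.gene_ids:
        raise ValueError("inferred and truth networks have different gene labels")
    pred = edge_set(inferred, mode, include_self)
    true = edge_set(truth, mode, include_self)
    tp = len(pred & true)
    return EvalReport(tp=tp, fp=len(pred) - tp, fn=len(true) - tp, mode=mode)


def random_baseline(
    n_genes: int,
    n_edges: int,
    truth: GeneNetwork,
    mode: Mode = "directed",
    seed: int = 0,
    include_self: bool = False,
) -> EvalReport:
    """Score a uniform random predictor of ``n_edges`` distinct edges.

    Its expected PPV is the truth's edge density, the conventional chance
    floor benchmark tables report.
    """
    rng = np.random.default_rng(seed)
    genes = range(n_genes)
    if mode == "undirected":
        universe: list = [
            frozenset(p) for p in itertools.combinations(genes, 2)
        ]
        if include_self:
            universe += [frozenset((g,)) for g in genes]
    else:
        universe = [
            (j, i) for j in genes for i in genes if include_self or i != j
        ]
    if n_edges > len(universe):
        raise ValueError(f"n_edges={n_edges} exceeds {len(universe)} possible edges")
    picks = rng.choice(len(universe), size=n_edges, replace=False)
    pred = {universe[p] for p in picks}
    if mode == "signed":
        signs = rng.choice([-1, 1], size=n_edges)
        pred = {(j, i, int(s)) for (j, i), s in zip(sorted(pred), signs)}
    true = edge_set(truth, mode, include_self)
    tp = len(pred & true)
    return EvalReport(tp=tp, fp=len(pred) - tp, fn=len(true) - tp, mode=mode)
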