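"""In-silico benchmark generator: sparse stable linear networks and noisy
steady-state responses to single-gene perturbations.

The generator emulates the standard local steady-state benchmark protocol:
random sparse signed networks with a self-degradation diagonal, one unit
perturbation per experiment, responses solved from the linear steady-state
condition ``A x + p = 0``, and additive Gaussian measurement noise scaled
to the signal's root mean square.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .matrices import ExpressionMatrix, GeneNetwork, PerturbationDesign

__all__ = ["SimConfig", "random_network", "steady_state_data"]

#: row-sum bound on off-diagonal magnitudes; with the -1 diagonal this gives
#: strict diagonal dominance, hence invertibility and a stable steady state
DOMINANCE_SLACK = 0.9


@dataclass
class SimConfig:
    """Benchmark parameters.

    n_genes: network size N.
    avg_in_degree: expected number of off-diagonal regulators per gene.
    weight_low, weight_high: bounds on |a_ij| before sign assignment and
        the row-dominance rescaling.
    noise_sd: measurement-noise standard deviation as a fraction of the
        noise-free signal's RMS (0 disables noise).
    n_experiments: number of single-gene perturbation experiments
        (default: one per gene).
    seed: RNG seed; identical configs give bit-identical data.
    """

    n_genes: int
    avg_in_degree: float = 10.0
    weight_low: float = 0.1
    weight_high: float = 1.0
    noise_sd: float = 0.1
    n_experiments: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("need at least 2 genes")
        if not 0 <= self.avg_in_degree <= self.n_genes - 1:
            raise ValueError(
                f"avg_in_degree must be in [0, {self.n_genes - 1}], "
                f"got {self.avg_in_degree}"
            )
        if not 0 < self.weight_low <= self.weight_high:
            raise ValueError("require 0 < weight_low <= weight_high")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_experiments is None:
            self.n_experiments = self.n_genes
        if not 1 <= self.n_experiments <= self.n_genes:
            raise ValueError("n_experiments must be in [1, n_genes]")

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]


def random_network(config: SimConfig) -> GeneNetwork:
    """Sample a sparse stable signed network.

    Each off-diagonal entry is present independently with probability
    ``avg_in_degree / (n_genes - 1)``, magnitude uniform in
    ``[weight_low, weight_high]`` with equiprobable sign.  The diagonal is
    fixed at -1 (first-order self-degradation) and each row's off-diagonal
    magnitudes are rescaled, when needed, so their sum stays <= 0.9,
    guaranteeing invertibility.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    p_edge = config.avg_in_degree / (n - 1)
    mask = rng.random((n, n)) < p_edge
    np.fill_diagonal(mask, False)
    mag = rng.uniform(config.weight_low, config.weight_high, size=(n, n))
    sign = rng.choice([-1.0, 1.0], size=(n, n))
    A = np.where(mask, mag * sign, 0.0)
    row_sums = np.abs(A).sum(axis=1)
    scale = np.where(row_sums > DOMINANCE_SLACK, DOMINANCE_SLACK / np.maximum(row_sums, 1e-300), 1.0)
    A *= scale[:, None]
    np.fill_diagonal(A, -1.0)
    return GeneNetwork(config.gene_ids(), sp.csr_array(A))


def steady_state_data(
    A: GeneNetwork, config: SimConfig
) -> tuple[ExpressionMatrix, PerturbationDesign]:
    """Simulate noisy steady-state responses to single-gene perturbations.

    Experiment ``l`` applies a unit perturbation to gene ``l``; the
    noise-free response solves ``A x_l + p_l = 0``.  Gaussian noise with
    standard deviation ``noise_sd * RMS(X)`` is added entrywise.
    """
    n = A.n_genes
    m = config.n_experiments
    Ad = A.dense()
    P = np.zeros((n, m))
    P[np.arange(m), np.arange(m)] = 1.0
    try:
        X = np.linalg.solve(Ad, -P)
    except np.linalg.LinAlgError as exc:
        raise ValueError("network matrix is singular; no steady state") from exc
    if config.noise_sd > 0:
        rms = float(np.sqrt(np.mean(X**2)))
        # derived stream: independent of the network-sampling draws
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
        X = X + rng.normal(0.0, config.noise_sd * rms, size=X.shape)
    exp_ids = [f"e{l + 1}" for l in range(m)]
    gene_ids = list(A.gene_ids)
    return (
        ExpressionMatrix(gene_ids, exp_ids, X),
        PerturbationDesign(gene_ids, exp_ids, P),
    )
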