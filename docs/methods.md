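# Methods

## Model and estimator

The package infers a gene regulatory network from local steady-state
perturbation data under the linearized transcription model
`dx/dt = A x + p`. At steady state `A x_l + p_l = 0` for every experiment
`l`, so row `i` of the influence matrix satisfies
`sum_j a_ij x_jl = -p_il`. Stacking experiments, the regression response
for target gene `i` is `y_i = -p_i` (the sign-flipped row of the design
matrix `P`) and the regressors are the transcript rows of `X`; the fitted
coefficients are the `a_ij` themselves, which keeps the recovered signs
directly comparable to a generating network. Perturbation magnitudes are
normalized to 1, which fixes the scale that the model otherwise leaves
free.

Each gene's regulators are found by best-subset least squares under a
sparsity bound `k` (maximum ingoing edges per gene). The exact search is
infeasible beyond tiny networks, so a greedy beam heuristic is used:

1. score all single-regressor fits, keep the `beam_width` best;
2. at step `s`, extend every surviving set with every unused regressor,
   merge duplicate sets (the same set reached through different parents is
   scored once), score each, keep the `beam_width` best;
3. stop at size `k`; the size-`k` set with minimal residual sum of squares
   wins, and its coefficients become the edge weights.

`beam_width` defaults to `k`. Ties on rss (exact float ties) are broken by
the lexicographically smallest subset, so the search is deterministic and
independent of evaluation order and of the worker partition.

## Fast regression core

`G = X X^T` is computed once per run. A candidate subset `S` then needs
only the symmetric submatrix `G_S` and the projections `(X y^T)_S`,
`y y^T`; the normal equations `G_S b = (X y^T)_S` are solved by Cholesky
factorization in packed storage (LAPACK `dppsv`), and
`rss = y y^T - b . (X y^T)_S`, clamped at zero, never touches `X` again.
With the canonical single-gene unit-perturbation design, `X y^T` for gene
`i` is just minus the column of `X` from the experiment perturbing `i` —
no product is formed. The per-candidate cost is therefore independent of
the number of experiments.

Inside the beam loop the same quantities are obtained incrementally: each
surviving node carries the Cholesky factor `L` of its `G_S` and
`c = L^{-1} (X y^T)_S`, so scoring all one-regressor extensions of a node
is a single triangular solve (`rss_new = rss - (xty_j - w.c)^2 / d` with
`w = L^{-1} G_{S,j}`, pivot `d = G_jj - w.w`). This is algebraically
identical to re-solving each subset; the final coefficients of the winning
subset are always recomputed with the packed solver, and the test suite
asserts the two routes agree to 1e-8 relative against a generic
least-squares oracle.

A candidate whose Cholesky pivot is non-positive (equivalently, `dppsv`
reports failure) has linearly dependent regressors; it is excluded from
the beam rather than regularized — the model assumes independent
regressors and provides no ridge term. No explicit condition-number
threshold is applied. If every candidate for a gene is singular the gene
is reported as a per-gene failure with an empty regulator set; the run
continues.

A gene's own transcript competes as a regressor by default
(`allow_self=True`): degradation is a genuine self-influence with a large
coefficient, and forcing it in or out would change the model class.
Self-loops are excluded from accuracy metrics (below). `k` larger than the
candidate pool is an error, never a silent clamp.

Coefficients smaller than 1e-8 of the gene's largest fitted coefficient
are dropped when edges are assembled. On noise-free data a gene whose true
regulator count is below `k` is fitted exactly before the search finishes,
and the remaining slots receive machine-epsilon coefficients; those are
padding, not edges (the network container stores non-zero weights only).
The threshold is eight orders of magnitude below any weight the simulator
generates, and noisy fits never approach it.

## Parallel execution

Genes are independent, so the per-gene searches are distributed over a
worker pool (joblib/loky processes): the gene list is split into
`worker_count` near-equal contiguous blocks, workers share the read-only
inputs (`G`, `X`, `P`) and never communicate, and results are reassembled
in gene order. The output is invariant to `worker_count` by construction,
and a test checks byte-identical serialized networks for 1, 2, 4 and 8
workers. A worker exception aborts the run naming the failing gene.
Multi-node (message-passing) execution is out of scope.

## In-silico benchmark generator

`random_network` samples sparse stable linear networks: each off-diagonal
entry is present independently with probability
`avg_in_degree / (n_genes - 1)`; magnitudes are uniform in
`[weight_low, weight_high]` (defaults 0.1 and 1.0 — a spread wide enough
that weak and strong regulations coexist, with the weakest edge an order
of magnitude below the degradation rate) with equiprobable sign, so both
activation and repression occur. The diagonal is fixed at −1
(self-degradation; this sets the time scale to match the unit perturbation
magnitude), and each row's off-diagonal magnitudes are rescaled when
needed so their sum stays ≤ 0.9. Strict row diagonal dominance certifies
invertibility and a stable steady state — the simplest checkable
condition.

`steady_state_data` applies one unit perturbation per experiment (gene `l`
in experiment `l`, `n_experiments ≤ n_genes`), solves `x_l = -A^{-1} p_l`,
and adds i.i.d. Gaussian noise with standard deviation
`noise_sd × RMS(noise-free X)`; the default `noise_sd = 0.1` represents a
moderately noisy microarray experiment. Identical configurations give
bit-identical data; the noise stream is decoupled from the topology stream
so the same network can be re-simulated at different noise levels.

What the generator does *not* emulate: nonlinear (saturating) regulation,
correlated or intensity-dependent measurement noise, unobserved
perturbation spillover, and hub-heavy degree distributions — real
expression data has all of these. Accuracy measured on these benchmarks
therefore characterizes the estimator under its own model assumptions, not
its field performance on biological data.

## Evaluation

Inferred and true networks are reduced to edge sets and compared by
PPV = TP/(TP+FP) and sensitivity Se = TP/(TP+FN) in three modes: directed
(ordered regulator→target pairs), signed (directed plus sign agreement),
and undirected (orientation collapsed to unordered pairs, for comparison
with orientation-blind methods). Self-loops are excluded by default
because the degradation diagonal is structural and would inflate both
metrics; undefined ratios (empty prediction or empty truth) are reported
as absent, never as 0. A uniform random predictor of the same edge count
is provided as the chance baseline; its expected PPV is the truth's edge
density.

## Problem sizes and reported figures

The shipped benchmarks run at desk scale: 10 replicate 100-gene networks
and 5 replicate 200-gene networks (average in-degree 10, `k = 10`,
noise 0.1) as stand-ins for the published 100- and 1000-gene experiments,
plus 20 replicate 10-gene networks (average in-degree 3, `k = 3`). Against
exhaustive search the beam is validated on networks of up to 8 genes,
where brute force is cheap.

Two structural observations about these conditions, confirmed by the test
suite and the acceptance script rather than asserted:

- With average off-diagonal in-degree equal to `k` and the self-influence
  occupying one of the `k` slots, sensitivity is capped near
  `E[min(d, k-1)] / E[d]` for in-degree distribution `d` — roughly 0.8 for
  the 100/200-gene settings. The recovered values sit there.
- At 10 genes with `k = 3` the same cap is much more severe (≈ 0.6): three
  slots minus self leave two predictions against three expected true
  regulators. The small-network sensitivity figure this package reports is
  therefore substantially below published small-network values obtained
  under other (unrecorded) parameter settings; we report what the stated
  protocol produces.

## Known limitations

- Ordinary (unweighted) least squares: measurement variances, if known,
  are not used to weight residuals.
- Steady-state data only; the time-derivative term of the dynamical model
  is assumed zero.
- The greedy beam is a heuristic: it never beats exhaustive best-subset
  selection and can miss it (a property test asserts the inequality).
- Single-node parallelism only.
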