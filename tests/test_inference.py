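"""Beam search, network assembly, and the gene-parallel execution contract."""

import itertools

import numpy as np
import pytest

from nirnet.inference import (
    NIR,
    EvalCounter,
    GeneFailure,
    NIRConfig,
    greedy_gene_regression,
    infer_network,
    run_parallel,
)
from nirnet.regression import (
    ResponseProjection,
    SubsetSolution,
    compute_gram,
    response_projection,
    subset_least_squares,
)
from nirnet.simulate import SimConfig, random_network, steady_state_data

from conftest import make_matrices


def brute_force_best(G, proj, n, k):
    """Independent oracle: exhaustive best-subset search."""
    best = None
    for subset in itertools.combinations(range(n), k):
        sol = subset_least_squares(G, proj, list(subset))
        if isinstance(sol, SubsetSolution):
            key = (sol.rss, sol.subset)
            if best is None or key < best[0]:
                best = (key, sol)
    return best[1]


class TestConfig:
    def test_beam_width_defaults_to_k(self):
        assert NIRConfig(k=4).beam_width == 4

    def test_k_larger_than_pool_is_an_error(self):
        with pytest.raises(ValueError, match="pool"):
            NIRConfig(k=5, allow_self=False).validate_for(5)

    @pytest.mark.parametrize("bad", [dict(k=0), dict(beam_width=0), dict(workers=0)])
    def test_positive_parameters_enforced(self, bad):
        with pytest.raises(ValueError):
            NIRConfig(**bad)


class TestGreedyGeneRegression:
    def test_perfect_single_predictor_wins_first_step(self, rng):
        # y exactly proportional to regressor 1 of 2
        x2 = rng.normal(size=6)
        X = np.vstack([rng.normal(size=6), x2])
        y = 2.0 * x2
        G = compute_gram(X)
        proj = ResponseProjection(X @ y, float(y @ y), 0)
        sol = greedy_gene_regression(0, G, proj, NIRConfig(k=1))
        assert sol.subset == (1,)
        assert sol.rss == pytest.approx(0.0, abs=1e-9 * proj.yty)
        assert sol.coefficients[0] == pytest.approx(2.0)

    def test_candidate_count_matches_enumeration(self, rng):
        # N=5, k=2, beam 2: 5 singles, then 2*4 - 1 = 7 deduplicated pairs
        X = rng.normal(size=(5, 8))
        y = rng.normal(size=8)
        G = compute_gram(X)
        proj = ResponseProjection(X @ y, float(y @ y), 0)
        counter = EvalCounter()
        greedy_gene_regression(0, G, proj, NIRConfig(k=2, beam_width=2), counter)
        assert counter.count == 5 + 7

    def test_candidate_count_closed_form_larger(self, rng):
        """Instrumented counts equal direct enumeration of the beam's frontier."""
        n, k, w = 10, 4, 3
        X = rng.normal(size=(n, 12))
        y = rng.normal(size=12)
        G = compute_gram(X)
        proj = ResponseProjection(X @ y, float(y @ y), 0)
        counter = EvalCounter()
        greedy_gene_regression(0, G, proj, NIRConfig(k=k, beam_width=w), counter)

        # replay the search structurally to enumerate unique candidate sets
        def rss_of(subset):
            return subset_least_squares(G, proj, sorted(subset)).rss

        beams = [frozenset()]
        total = 0
        for _ in range(k):
            children = {frozenset(b | {j}) for b in beams for j in range(n) if j not in b}
            total += len(children)
            beams = sorted(children, key=lambda c: (rss_of(c), tuple(sorted(c))))[:w]
        assert counter.count == total

    def test_full_beam_equals_brute_force(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = r.normal(size=(6, 9))
            y = r.normal(size=9)
            G = compute_gram(X)
            proj = ResponseProjection(X @ y, float(y @ y), 0)
            sol = greedy_gene_regression(0, G, proj, NIRConfig(k=3, beam_width=60))
            ref = brute_force_best(G, proj, 6, 3)
            assert sol.subset == ref.subset
            assert sol.rss == pytest.approx(ref.rss, rel=1e-9, abs=1e-12)

    def test_greedy_never_beats_exhaustive(self, rng):
        """Admissibility: heuristic rss >= exhaustive best-subset rss."""
        for seed in range(10):
            r = np.random.default_rng(100 + seed)
            X = r.normal(size=(7, 10))
            y = r.normal(size=10)
            G = compute_gram(X)
            proj = ResponseProjection(X @ y, float(y @ y), 0)
            sol = greedy_gene_regression(0, G, proj, NIRConfig(k=3, beam_width=1))
            ref = brute_force_best(G, proj, 7, 3)
            assert sol.rss >= ref.rss - 1e-9 * max(1.0, proj.yty)

    def test_beam_minimum_rss_non_increasing_across_steps(self, rng):
        """Each step's best candidate is at least as good as the previous."""
        X = rng.normal(size=(9, 12))
        y = rng.normal(size=12)
        G = compute_gram(X)
        proj = ResponseProjection(X @ y, float(y @ y), 0)
        prev = None
        for k in range(1, 6):
            sol = greedy_gene_regression(0, G, proj, NIRConfig(k=k, beam_width=3))
            if prev is not None:
                assert sol.rss <= prev + 1e-9 * max(1.0, proj.yty)
            prev = sol.rss

    def test_all_singular_reports_failure(self):
        # identical regressor rows: every subset of size 2 is singular,
        # and the zero response makes every pivot degenerate at step 1 too
        X = np.zeros((3, 4))
        G = compute_gram(X)
        proj = ResponseProjection(np.zeros(3), 1.0, 0)
        res = greedy_gene_regression(0, G, proj, NIRConfig(k=2))
        assert isinstance(res, GeneFailure)
        assert res.gene == 0


class TestInferNetwork:
    def test_noise_free_recovery_small(self):
        cfg = SimConfig(n_genes=10, avg_in_degree=1.5, noise_sd=0.0, seed=3)
        truth = random_network(cfg)
        X, P = steady_state_data(truth, cfg)
        k = 4
        net = infer_network(X, P, NIRConfig(k=k))
        Td, Id = truth.dense(), net.dense()
        for i in range(10):
            tsup = set(np.flatnonzero(Td[i]))
            if len(tsup) <= k:  # gene fits in the sparsity budget incl. self
                assert set(np.flatnonzero(Id[i])) == tsup
                np.testing.assert_allclose(Id[i, list(tsup)], Td[i, list(tsup)],
                                           rtol=1e-6)

    def test_zero_expression_gene_never_a_regulator(self, rng):
        Xv = rng.normal(size=(5, 5))
        Xv[3] = 0.0
        X, P = make_matrices(Xv, np.eye(5))
        net = infer_network(X, P, NIRConfig(k=2, allow_self=False))
        assert not np.any(net.dense()[:, 3])

    def test_worker_count_does_not_change_result(self, small_dataset):
        truth, X, P = small_dataset
        nets = [
            NIR(k=4, workers=w).fit(X, P).network_.dense() for w in (1, 4)
        ]
        np.testing.assert_array_equal(nets[0], nets[1])

    def test_mismatched_matrices_rejected(self, rng):
        X, P = make_matrices(rng.normal(size=(4, 4)), np.eye(4))
        X2 = make_matrices(rng.normal(size=(4, 3)))
        with pytest.raises(ValueError, match="4x3|shape"):
            NIR(k=2).fit(X2, P)

    def test_estimator_is_sklearn_compatible(self):
        from sklearn.base import clone

        est = NIR(k=3, workers=2)
        params = est.get_params()
        assert params["k"] == 3 and params["workers"] == 2
        clone(est).set_params(k=5)


class TestRunParallel:
    def test_partition_covers_all_genes_in_blocks(self):
        calls = []
        out = run_parallel(range(10), 1, lambda g: calls.append(g) or g * 2)
        assert out == [g * 2 for g in range(10)]
        assert calls == list(range(10))

    def test_block_sizes_near_equal(self):
        # 10 genes over 3 workers -> contiguous blocks of sizes {4, 3, 3}
        sizes = [len(b) for b in np.array_split(np.arange(10), 3)]
        assert sorted(sizes, reverse=True) == [4, 3, 3]

    def test_oversubscription_is_harmless(self):
        out = run_parallel(range(3), 8, lambda g: g + 1)
        assert out == [1, 2, 3]

    def test_worker_failure_names_gene(self):
        def task(g):
            if g == 5:
                raise ValueError("boom")
            return g

        with pytest.raises(RuntimeError, match="gene 5"):
            run_parallel(range(8), 2, task)
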