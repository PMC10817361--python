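"""Contracts of the four biclustering algorithms."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from biclog import (
    BCCConfig,
    Bicluster,
    BimaxConfig,
    FabiaConfig,
    SpectralConfig,
    column_standardize,
    msr_score,
    run_bcc,
    run_bimax,
    run_fabia,
    run_spectral,
)
from biclog.algorithms import binarize, maximal_ones_submatrices


# ---------------------------------------------------------------------------
# BCC
# ---------------------------------------------------------------------------


class TestBCC:
    def test_whole_matrix_when_already_coherent(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 6), rng.normal(0, 1, 5)
        M = a[:, None] + b[None, :]  # perfect shifting: MSR 0 everywhere
        res = run_bcc(M, BCCConfig(delta=0.5, n_biclusters=3, standardize=False, seed=0))
        assert res[0].shape == (6, 5)

    def test_msr_contract_on_random_matrices(self):
        delta = 0.5
        for seed in range(15):
            rng = np.random.default_rng(seed)
            M = rng.normal(size=(15, 10)) * rng.uniform(0.5, 5)
            W = column_standardize(M)
            res = run_bcc(M, BCCConfig(delta=delta, n_biclusters=20, seed=seed))
            for b in res:
                assert msr_score(W, b) <= delta + 1e-12

    def test_all_biclusters_at_least_2x2(self):
        rng = np.random.default_rng(3)
        M = rng.normal(size=(20, 12))
        res = run_bcc(M, BCCConfig(delta=0.3, n_biclusters=30, seed=3))
        for b in res:
            assert len(b.rows) >= 2 and len(b.cols) >= 2

    def test_invalid_parameters_rejected(self):
        M = np.zeros((4, 4))
        with pytest.raises(ValueError):
            run_bcc(M, BCCConfig(delta=0.0))
        with pytest.raises(ValueError):
            run_bcc(np.zeros((1, 5)), BCCConfig())
        with pytest.raises(ValueError):
            run_bcc(M, BCCConfig(alpha=0.5))

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(8)
        M = rng.normal(size=(15, 8))
        r1 = run_bcc(M, BCCConfig(delta=0.4, n_biclusters=10, seed=5))
        r2 = run_bcc(M, BCCConfig(delta=0.4, n_biclusters=10, seed=5))
        assert [(b.rows, b.cols) for b in r1] == [(b.rows, b.cols) for b in r2]

    def test_no_duplicate_biclusters(self):
        rng = np.random.default_rng(4)
        M = rng.normal(size=(12, 8))
        res = run_bcc(M, BCCConfig(delta=0.6, n_biclusters=40, seed=4))
        keys = [(b.rows, b.cols) for b in res]
        assert len(keys) == len(set(keys))


# ---------------------------------------------------------------------------
# BIMAX
# ---------------------------------------------------------------------------


def brute_force_maximal(B, min_rows, min_cols):
    """2^N row-subset enumeration of maximal all-ones submatrices."""
    n, p = B.shape
    concepts = set()
    for mask in range(1, 2**n):
        extent = np.array([(mask >> i) & 1 for i in range(n)], dtype=bool)
        intent = B[extent].all(axis=0)
        if not intent.any():
            continue
        closure = B[:, intent].all(axis=1)
        concepts.add(
            (tuple(np.flatnonzero(closure)), tuple(np.flatnonzero(intent)))
        )
    return {
        c for c in concepts if len(c[0]) >= min_rows and len(c[1]) >= min_cols
    }


class TestBimax:
    def test_all_ones_matrix_single_bicluster(self):
        res = run_bimax(np.ones((5, 5)), BimaxConfig(binarization="positive"))
        assert len(res) == 1
        assert res[0].shape == (5, 5)

    def test_worked_binary_example(self):
        B = np.array([[1, 1, 0], [1, 1, 0], [0, 1, 1]], dtype=float)
        res = run_bimax(B, BimaxConfig(binarization="positive", min_rows=2, min_cols=2))
        assert len(res) == 1
        assert res[0].rows == (0, 1) and res[0].cols == (0, 1)

    def test_all_zero_matrix_empty_set(self):
        res = run_bimax(np.zeros((4, 4)), BimaxConfig(binarization="positive"))
        assert len(res) == 0

    @pytest.mark.parametrize("trial", range(100))
    def test_equals_bruteforce_enumeration(self, trial):
        rng = np.random.default_rng(5000 + trial)
        n, p = int(rng.integers(2, 9)), int(rng.integers(2, 9))
        B = (rng.random((n, p)) < rng.uniform(0.2, 0.8)).astype(float)
        got = {
            (b.rows, b.cols)
            for b in run_bimax(
                B,
                BimaxConfig(binarization="positive", min_rows=2, min_cols=2, max_biclusters=10_000),
            )
        }
        assert got == brute_force_maximal(B > 0, 2, 2)

    def test_truncation_orders_by_area(self):
        B = np.zeros((8, 8))
        B[:4, :4] = 1  # area 16
        B[6:, 6:] = 1  # area 4
        res = run_bimax(B, BimaxConfig(binarization="positive", max_biclusters=1))
        assert len(res) == 1
        assert res[0].size == 16

    def test_median_binarization_handles_zero_median_counts(self):
        # count column with median 0: cells > 0 are hits
        X = np.array([[0.0, 5.0], [0.0, 6.0], [3.0, 7.0], [4.0, 8.0]])
        B = binarize(X, "median")
        np.testing.assert_array_equal(B[:, 0], [False, False, True, True])

    def test_enumeration_cap_warns(self):
        rng = np.random.default_rng(0)
        B = rng.random((20, 20)) < 0.5
        with pytest.warns(UserWarning, match="truncated"):
            maximal_ones_submatrices(B, 1, 1, max_concepts=10)


# ---------------------------------------------------------------------------
# Spectral
# ---------------------------------------------------------------------------


def checkerboard(row_sizes, col_sizes, means, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rl = np.repeat(np.arange(len(row_sizes)), row_sizes)
    cl = np.repeat(np.arange(len(col_sizes)), col_sizes)
    X = means[np.ix_(rl, cl)].astype(float)
    if noise_sd:
        X = X + rng.normal(0, noise_sd, X.shape)
    return X, rl, cl


def recovered_partitions(res, n, p):
    rlab, clab = np.full(n, -1), np.full(p, -1)
    for i, g in enumerate(sorted({b.rows for b in res})):
        rlab[list(g)] = i
    for i, g in enumerate(sorted({b.cols for b in res})):
        clab[list(g)] = i
    return rlab, clab


class TestSpectral:
    @pytest.mark.parametrize(
        "means",
        [
            np.array([[1.0, 5.0], [6.0, 2.0]]),
            np.array([[1.0, 7.0], [5.0, 2.0], [9.0, 4.0]]),
        ],
        ids=["2x2", "3x2"],
    )
    def test_noiseless_checkerboard_recovered_exactly(self, means):
        R, C = means.shape
        X, rl, cl = checkerboard([20] * R, [15] * C, means)
        res = run_spectral(X, SpectralConfig(n_eigenvalues=2, seed=0))
        rlab, clab = recovered_partitions(res, X.shape[0], X.shape[1])
        assert adjusted_rand_score(rl, rlab) == 1.0
        assert adjusted_rand_score(cl, clab) == 1.0
        assert len(res) == R * C

    def test_checkerboard_tiles_every_cell_once(self):
        X, _, _ = checkerboard([10, 10], [8, 8], np.array([[1.0, 4.0], [5.0, 2.0]]))
        res = run_spectral(X, SpectralConfig(n_eigenvalues=1, seed=0))
        counts = np.zeros(X.shape, dtype=int)
        for b in res:
            counts[np.ix_(b.rows, b.cols)] += 1
        assert np.all(counts == 1)

    def test_every_feature_in_one_bicluster_per_row_class(self):
        X, rl, _ = checkerboard([15, 15, 15], [10, 10], np.array([[1.0, 7.0], [5.0, 2.0], [9.0, 4.0]]))
        res = run_spectral(X, SpectralConfig(n_eigenvalues=2, seed=0))
        n_row_classes = len({b.rows for b in res})
        per_feature = np.zeros(X.shape[1], dtype=int)
        for b in res:
            per_feature[list(b.cols)] += 1
        assert np.all(per_feature == n_row_classes)

    def test_constant_matrix_degenerates_to_whole(self):
        res = run_spectral(np.full((9, 7), 2.0), SpectralConfig(n_eigenvalues=2))
        assert len(res) == 1
        assert res[0].shape == (9, 7)

    def test_too_many_eigenvalues_rejected(self):
        with pytest.raises(ValueError):
            run_spectral(np.zeros((5, 4)), SpectralConfig(n_eigenvalues=4))

    def test_agrees_with_reference_implementation_on_noisy_board(self):
        # independent cross-check: scikit-learn's checkerboard biclustering
        # given the true class counts should match our recovered partitions
        from sklearn.cluster import SpectralBiclustering

        X, rl, cl = checkerboard(
            [20, 20, 20], [15, 15], np.array([[1.0, 7.0], [5.0, 2.0], [9.0, 4.0]]), noise_sd=0.2, seed=4
        )
        ours = run_spectral(
            X, SpectralConfig(n_eigenvalues=2, n_row_classes=3, n_col_classes=2, seed=0)
        )
        rlab, clab = recovered_partitions(ours, X.shape[0], X.shape[1])
        ref = SpectralBiclustering(n_clusters=(3, 2), method="bistochastic", random_state=0).fit(X)
        assert adjusted_rand_score(ref.row_labels_, rlab) == 1.0
        assert adjusted_rand_score(ref.column_labels_, clab) == 1.0

    def test_log_normalization_variant_runs(self):
        rng = np.random.default_rng(1)
        X = rng.poisson(3.0, size=(20, 10)).astype(float)
        res = run_spectral(X, SpectralConfig(normalization="log", n_eigenvalues=2, seed=0))
        assert len(res) >= 1


# ---------------------------------------------------------------------------
# FABIA-style
# ---------------------------------------------------------------------------


class TestFabia:
    def test_zero_matrix_yields_empty_set(self):
        res = run_fabia(np.zeros((10, 8)), FabiaConfig(n_factors=3, seed=0))
        assert len(res) == 0

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        M = rng.normal(size=(20, 10))
        r1 = run_fabia(M, FabiaConfig(n_factors=3, seed=7))
        r2 = run_fabia(M, FabiaConfig(n_factors=3, seed=7))
        assert [(b.rows, b.cols) for b in r1] == [(b.rows, b.cols) for b in r2]

    def test_recovers_single_planted_multiplicative_block(self):
        from biclog import PlantedBlockModel, plant_biclusters, recovery_score

        rng = np.random.default_rng(0)
        blk = PlantedBlockModel(
            "scaling", range(10, 25), range(5, 13),
            alpha=rng.uniform(1, 2, 15), beta=rng.uniform(1, 2, 8),
        )
        A, truth = plant_biclusters(50, 20, [blk], background_sd=0.1, seed=1)
        best = max(
            recovery_score(run_fabia(A, FabiaConfig(n_factors=1, seed=s)), truth)[0]
            for s in range(3)
        )
        assert best >= 0.7

    def test_index_sets_valid(self):
        rng = np.random.default_rng(5)
        M = rng.normal(size=(15, 9))
        res = run_fabia(M, FabiaConfig(n_factors=4, seed=1))
        for b in res:
            assert max(b.rows, default=0) < 15
            assert max(b.cols, default=0) < 9

    def test_invalid_factor_count_rejected(self):
        with pytest.raises(ValueError):
            run_fabia(np.zeros((5, 5)), FabiaConfig(n_factors=0))
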