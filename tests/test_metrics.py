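"""VAR / MSR / VE against independent brute-force oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biclog import (
    Bicluster,
    BiclusterSet,
    msr_score,
    partition_to_biclusters,
    quality_of_set,
    residue_decomposition,
    var_score,
    ve_score,
)


# ---------------------------------------------------------------------------
# Naive-loop oracles (kept deliberately dumb and independent)
# ---------------------------------------------------------------------------


def naive_var(M, rows, cols):
    cells = [M[i][j] for i in rows for j in cols]
    mean = sum(cells) / len(cells)
    return sum((c - mean) ** 2 for c in cells) / len(cells)


def naive_msr(M, rows, cols):
    row_means = {i: sum(M[i][j] for j in cols) / len(cols) for i in rows}
    col_means = {j: sum(M[i][j] for i in rows) / len(rows) for j in cols}
    overall = sum(M[i][j] for i in rows for j in cols) / (len(rows) * len(cols))
    total = 0.0
    for i in rows:
        for j in cols:
            r = M[i][j] - row_means[i] - col_means[j] + overall
            total += r * r
    return total / (len(rows) * len(cols))


def naive_ve(M, rows, cols):
    import math

    norm = {}
    for i in rows:
        vals = [M[i][j] for j in cols]
        mu = sum(vals) / len(vals)
        sigma = math.sqrt(sum((v - mu) ** 2 for v in vals) / len(vals))
        for j in cols:
            norm[(i, j)] = (M[i][j] - mu) / sigma if sigma > 0 else 0.0
    rho = {j: sum(norm[(i, j)] for i in rows) / len(rows) for j in cols}
    return sum(abs(norm[(i, j)] - rho[j]) for i in rows for j in cols) / (
        len(rows) * len(cols)
    )


def random_bicluster(rng, n, p):
    nr = int(rng.integers(1, n + 1))
    nc = int(rng.integers(1, p + 1))
    rows = rng.choice(n, size=nr, replace=False)
    cols = rng.choice(p, size=nc, replace=False)
    return Bicluster(rows.tolist(), cols.tolist())


# ---------------------------------------------------------------------------
# Worked values
# ---------------------------------------------------------------------------


class TestWorkedValues:
    def test_var_on_2x2(self, worked_2x2):
        b = Bicluster([0, 1], [0, 1])
        assert var_score(worked_2x2, b) == pytest.approx(2.1875, abs=1e-12)

    def test_msr_on_2x2(self, worked_2x2):
        b = Bicluster([0, 1], [0, 1])
        assert msr_score(worked_2x2, b) == pytest.approx(0.0625, abs=1e-12)

    def test_ve_on_2x3(self):
        M = np.array([[1.0, 2.0, 6.0], [2.0, 4.0, 5.0]])
        b = Bicluster([0, 1], [0, 1, 2])
        assert ve_score(M, b) == pytest.approx(naive_ve(M, [0, 1], [0, 1, 2]), abs=1e-12)
        assert ve_score(M, b) == pytest.approx(0.2434, abs=5e-5)

    def test_decomposition_means(self, worked_2x2):
        dec = residue_decomposition(worked_2x2, Bicluster([0, 1], [0, 1]))
        assert dec.overall_mean == pytest.approx(2.75)
        np.testing.assert_allclose(dec.row_means, [1.5, 4.0])
        np.testing.assert_allclose(dec.col_means, [2.0, 3.5])

    def test_one_by_two_var(self):
        assert var_score(np.array([[0.0, 2.0]]), Bicluster([0], [0, 1])) == 1.0


# ---------------------------------------------------------------------------
# Oracle equivalence and analytic zeros
# ---------------------------------------------------------------------------


class TestOracleEquivalence:
    def test_matches_naive_loops_on_random_pairs(self):
        rng = np.random.default_rng(1234)
        for _ in range(200):
            n, p = int(rng.integers(2, 12)), int(rng.integers(2, 10))
            M = rng.normal(size=(n, p)) * rng.uniform(0.5, 20)
            b = random_bicluster(rng, n, p)
            rows, cols = list(b.rows), list(b.cols)
            assert var_score(M, b) == pytest.approx(naive_var(M, rows, cols), abs=1e-10)
            assert msr_score(M, b) == pytest.approx(naive_msr(M, rows, cols), abs=1e-10)
            assert ve_score(M, b) == pytest.approx(naive_ve(M, rows, cols), abs=1e-10)


class TestAnalyticZeros:
    """Pattern taxonomy ties to the statistics: constant / shifting / scaling."""

    @pytest.mark.parametrize("trial", range(10))
    def test_constant_blocks(self, trial):
        rng = np.random.default_rng(trial)
        M = np.full((int(rng.integers(2, 9)), int(rng.integers(2, 9))), rng.normal())
        b = Bicluster(range(M.shape[0]), range(M.shape[1]))
        assert var_score(M, b) == pytest.approx(0.0, abs=1e-12)
        assert msr_score(M, b) == pytest.approx(0.0, abs=1e-12)
        assert ve_score(M, b) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("trial", range(100))
    def test_shifting_blocks(self, trial):
        rng = np.random.default_rng(10_000 + trial)
        a = rng.normal(0, 3, int(rng.integers(2, 9)))
        c = rng.normal(0, 3, int(rng.integers(2, 9)))
        M = a[:, None] + c[None, :]
        b = Bicluster(range(len(a)), range(len(c)))
        assert msr_score(M, b) == pytest.approx(0.0, abs=1e-12)
        assert ve_score(M, b) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("trial", range(100))
    def test_positive_scaling_blocks(self, trial):
        rng = np.random.default_rng(20_000 + trial)
        a = rng.uniform(0.2, 4, int(rng.integers(2, 9)))
        c = rng.normal(0, 3, int(rng.integers(2, 9)))
        M = a[:, None] * c[None, :]
        b = Bicluster(range(len(a)), range(len(c)))
        assert ve_score(M, b) == pytest.approx(0.0, abs=1e-12)

    def test_two_column_bicluster_has_zero_ve(self):
        rng = np.random.default_rng(0)
        M = rng.normal(size=(5, 2))
        # every row standardizes to (-1, +1) up to sign; with consistent
        # ordering across rows the pattern deviation vanishes
        M = np.sort(M, axis=1)
        assert ve_score(M, Bicluster(range(5), [0, 1])) == pytest.approx(0.0, abs=1e-12)

    def test_constant_row_flagged(self):
        M = np.array([[1.0, 1.0, 1.0], [0.0, 2.0, 4.0]])
        dec = residue_decomposition(M, Bicluster([0, 1], [0, 1, 2]))
        assert list(dec.zero_sigma_rows) == [0]
        np.testing.assert_array_equal(dec.normalized[0], 0.0)


# ---------------------------------------------------------------------------
# Invariances (property-based)
# ---------------------------------------------------------------------------


@st.composite
def matrix_and_bicluster(draw):
    n = draw(st.integers(2, 7))
    p = draw(st.integers(2, 7))
    # values on a coarse grid: keeps row spreads either exactly zero or
    # large enough that the sigma = 0 rule is not toggled by float round-off
    vals = draw(
        st.lists(
            st.lists(
                st.floats(-50, 50).map(lambda x: round(x, 3)),
                min_size=p,
                max_size=p,
            ),
            min_size=n,
            max_size=n,
        )
    )
    M = np.asarray(vals)
    nr = draw(st.integers(2, n))
    nc = draw(st.integers(2, p))
    rows = draw(st.permutations(range(n)))[:nr]
    cols = draw(st.permutations(range(p)))[:nc]
    return M, Bicluster(sorted(rows), sorted(cols))


class TestInvariances:
    @settings(max_examples=60, deadline=None)
    @given(matrix_and_bicluster(), st.floats(-20, 20))
    def test_msr_and_ve_invariant_to_row_shift(self, mb, shift):
        M, b = mb
        M2 = M.copy()
        M2[b.rows[0], :] += shift
        assert msr_score(M2, b) == pytest.approx(msr_score(M, b), abs=1e-8)
        assert ve_score(M2, b) == pytest.approx(ve_score(M, b), abs=1e-8)

    @settings(max_examples=60, deadline=None)
    @given(matrix_and_bicluster(), st.floats(0.1, 10))
    def test_ve_invariant_to_positive_row_rescale(self, mb, scale):
        M, b = mb
        M2 = M.copy()
        M2[b.rows[0], :] *= scale
        assert ve_score(M2, b) == pytest.approx(ve_score(M, b), abs=1e-8)

    @settings(max_examples=60, deadline=None)
    @given(matrix_and_bicluster(), st.randoms(use_true_random=False))
    def test_permutation_invariance(self, mb, rnd):
        M, b = mb
        rows = list(b.rows)
        cols = list(b.cols)
        rnd.shuffle(rows)
        rnd.shuffle(cols)
        b2 = Bicluster(rows, cols)
        assert var_score(M, b2) == pytest.approx(var_score(M, b), abs=1e-9)
        assert msr_score(M, b2) == pytest.approx(msr_score(M, b), abs=1e-9)
        assert ve_score(M, b2) == pytest.approx(ve_score(M, b), abs=1e-9)


# ---------------------------------------------------------------------------
# Set-level aggregation and the one-mode adapter
# ---------------------------------------------------------------------------


class TestQualityOfSet:
    def test_singleton_set_equals_bicluster_scores(self, worked_2x2):
        b = Bicluster([0, 1], [0, 1])
        q = quality_of_set(worked_2x2, BiclusterSet([b]))
        assert q.mean_var == pytest.approx(2.1875)
        assert q.mean_msr == pytest.approx(0.0625)

    def test_mean_is_unweighted(self):
        M = np.array([[0.0, 0.0], [0.0, 2.0]])
        b_zero = Bicluster([0], [0, 1])  # VAR 0
        b_one = Bicluster([1], [0, 1])  # VAR 1
        q = quality_of_set(M, BiclusterSet([b_zero, b_one]))
        assert q.mean_var == pytest.approx(0.5)

    def test_weighted_mean_available(self):
        M = np.array([[0.0, 0.0, 0.0], [0.0, 3.0, 3.0], [0.0, 3.0, 3.0]])
        big = Bicluster([0, 1, 2], [0, 1, 2])
        small = Bicluster([1, 2], [1, 2])  # VAR 0, 4 cells vs 9
        q = quality_of_set(M, BiclusterSet([big, small]))
        assert q.weighted_mean_var != q.mean_var

    def test_empty_set_rejected(self, worked_2x2):
        with pytest.raises(ValueError):
            quality_of_set(worked_2x2, BiclusterSet([]))

    def test_matches_bruteforce_on_random_sets(self):
        rng = np.random.default_rng(9)
        M = rng.normal(size=(20, 10))
        bics = [random_bicluster(rng, 20, 10) for _ in range(5)]
        q = quality_of_set(M, BiclusterSet(bics))
        expected = np.mean([naive_var(M, list(b.rows), list(b.cols)) for b in bics])
        assert q.mean_var == pytest.approx(expected, abs=1e-10)


class TestPartitionAdapter:
    def test_single_cluster_is_whole_matrix(self, worked_2x2):
        S = partition_to_biclusters([0, 0], worked_2x2)
        assert len(S) == 1
        assert S[0].shape == (2, 2)

    def test_two_clusters_cover_all_rows_with_all_columns(self):
        M = np.zeros((4, 3))
        S = partition_to_biclusters([0, 0, 1, 1], M)
        assert len(S) == 2
        assert all(len(b.cols) == 3 for b in S)
        covered = sorted(i for b in S for i in b.rows)
        assert covered == [0, 1, 2, 3]

    def test_label_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            partition_to_biclusters([0, 1], np.zeros((3, 2)))
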