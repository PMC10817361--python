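"""Four biclustering algorithms behind a common contract.

All four return a :class:`~biclog.metrics.BiclusterSet` whose index sets
refer to the input matrix; any stochastic step is driven by an explicit
seed in the config, and ties are broken deterministically.

``run_bcc``
    Cheng--Church greedy search: repeatedly carve out a submatrix whose
    mean squared residue (MSR) is at most ``delta`` by multiple/single
    node deletion followed by node addition, then mask the found cells
    with uniform random values and continue.  The search operates on a
    column-standardized working copy (the "standardized data matrix" of
    the original algorithm); every returned bicluster satisfies
    ``MSR <= delta`` on the clean standardized matrix.

``run_bimax``
    Exact enumeration of all inclusion-maximal all-ones submatrices of
    the binarized matrix (formal concepts of the binary relation),
    filtered by minimum size and truncated by decreasing area.

``run_spectral``
    Checkerboard biclustering: bistochastic (or log-interaction)
    normalization, SVD, k-means on the row/column projections onto the
    kept singular vector pairs; the crossing of the row and column
    partitions is returned, so the biclusters tile the matrix.

``run_fabia``
    Sparse-factor biclustering: an alternating least-squares EM with
    Laplace-inspired L1 shrinkage on both factor scores and loadings
    (a practically specified approximation of factor analysis for
    bicluster acquisition); one bicluster per factor via thresholds on
    |score| and |loading|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from sklearn.cluster import KMeans

from .data import FeatureMatrix
from .metrics import Bicluster, BiclusterSet, msr_score

__all__ = [
    "BCCConfig",
    "BimaxConfig",
    "SpectralConfig",
    "FabiaConfig",
    "column_standardize",
    "run_bcc",
    "run_bimax",
    "run_spectral",
    "run_fabia",
]


def _values(A: FeatureMatrix | np.ndarray) -> np.ndarray:
    return A.values if isinstance(A, FeatureMatrix) else np.asarray(A, dtype=float)


# ---------------------------------------------------------------------------
# BCC (Cheng--Church)
# ---------------------------------------------------------------------------


@dataclass
class BCCConfig:
    """Cheng--Church parameters.

    ``delta`` is the MSR ceiling (in the standardized space when
    ``standardize`` is on), ``alpha >= 1`` the multiple-deletion rate, and
    ``n_biclusters`` the target count; fewer are returned when the search
    exhausts.
    """

    delta: float = 1.0
    alpha: float = 1.5
    n_biclusters: int = 100
    seed: int = 0
    standardize: bool = True


def column_standardize(A: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Column z-scores; constant columns map to zero."""
    X = _values(A)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd


def _msr_parts(W: np.ndarray, rows: np.ndarray, cols: np.ndarray):
    sub = W[np.ix_(rows, cols)]
    res = (
        sub
        - sub.mean(axis=1, keepdims=True)
        - sub.mean(axis=0, keepdims=True)
        + sub.mean()
    )
    sq = res**2
    return float(sq.mean()), sq.mean(axis=1), sq.mean(axis=0)


def _single_bcc(W: np.ndarray, delta: float, alpha: float):
    """One Cheng--Church bicluster on the working matrix, or None."""
    n, p = W.shape
    rows = np.arange(n)
    cols = np.arange(p)

    # node deletion: batch-drop every row/column whose contribution exceeds
    # alpha * MSR whenever any does (multiple node deletion), otherwise drop
    # the single worst node; the batch rule is re-checked after every step,
    # so once the submatrix is dominated by a coherent core the remaining
    # incoherent nodes are swept out together and the MSR lands well below
    # delta rather than just under it
    while True:
        msr, rc, cc = _msr_parts(W, rows, cols)
        if msr <= delta:
            break
        changed = False
        if len(rows) > 2:
            keep = rc > alpha * msr
            if keep.any() and len(rows) - keep.sum() >= 2:
                rows = rows[~keep]
                changed = True
                msr, rc, cc = _msr_parts(W, rows, cols)
                if msr <= delta:
                    break
        if len(cols) > 2:
            keep = cc > alpha * msr
            if keep.any() and len(cols) - keep.sum() >= 2:
                cols = cols[~keep]
                changed = True
                msr, rc, cc = _msr_parts(W, rows, cols)
                if msr <= delta:
                    break
        if changed:
            continue
        can_row = len(rows) > 2
        can_col = len(cols) > 2
        if not can_row and not can_col:
            return None  # cannot reach delta with a >= 2x2 submatrix
        if can_row and (not can_col or rc.max() >= cc.max()):
            rows = np.delete(rows, int(np.argmax(rc)))
        else:
            cols = np.delete(cols, int(np.argmax(cc)))

    # node addition (columns then rows, one pass each; inverted rows omitted)
    before = (rows.copy(), cols.copy())
    msr, _, _ = _msr_parts(W, rows, cols)
    sub = W[np.ix_(rows, cols)]
    row_mean = sub.mean(axis=1)
    overall = sub.mean()
    out_cols = np.setdiff1d(np.arange(p), cols)
    if out_cols.size:
        cand = W[np.ix_(rows, out_cols)]
        col_mean_cand = cand.mean(axis=0)
        score = ((cand - row_mean[:, None] - col_mean_cand[None, :] + overall) ** 2).mean(axis=0)
        cols = np.sort(np.concatenate([cols, out_cols[score <= msr]]))

    msr, _, _ = _msr_parts(W, rows, cols)
    sub = W[np.ix_(rows, cols)]
    col_mean = sub.mean(axis=0)
    overall = sub.mean()
    out_rows = np.setdiff1d(np.arange(n), rows)
    if out_rows.size:
        cand = W[np.ix_(out_rows, cols)]
        row_mean_cand = cand.mean(axis=1)
        score = ((cand - row_mean_cand[:, None] - col_mean[None, :] + overall) ** 2).mean(axis=1)
        rows = np.sort(np.concatenate([rows, out_rows[score <= msr]]))

    msr, _, _ = _msr_parts(W, rows, cols)
    if msr > delta:  # addition overshot: fall back to the deletion result
        rows, cols = before
    return rows, cols


def run_bcc(A: FeatureMatrix | np.ndarray, cfg: BCCConfig | None = None) -> BiclusterSet:
    """Cheng--Church biclustering with random masking of found biclusters."""
    cfg = cfg or BCCConfig()
    if cfg.delta <= 0:
        raise ValueError("delta must be positive")
    if cfg.alpha < 1:
        raise ValueError("alpha must be >= 1")
    X = _values(A)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("matrix must be at least 2 x 2")

    clean = column_standardize(X) if cfg.standardize else X.copy()
    W = clean.copy()
    lo, hi = float(clean.min()), float(clean.max())
    if hi <= lo:
        hi = lo + 1.0
    rng = np.random.default_rng(cfg.seed)

    found: list[Bicluster] = []
    seen: set[tuple] = set()
    for _ in range(cfg.n_biclusters):
        res = _single_bcc(W, cfg.delta, cfg.alpha)
        if res is None:
            break
        rows, cols = res
        key = (tuple(rows), tuple(cols))
        # contract check against the clean (unmasked) working matrix
        b = Bicluster(rows.tolist(), cols.tolist())
        if key not in seen and msr_score(clean, b) <= cfg.delta:
            seen.add(key)
            found.append(b)
        W[np.ix_(rows, cols)] = rng.uniform(lo, hi, size=(len(rows), len(cols)))
    return BiclusterSet(
        found,
        provenance={
            "algorithm": "bcc",
            "delta": cfg.delta,
            "alpha": cfg.alpha,
            "n_biclusters": cfg.n_biclusters,
            "standardize": cfg.standardize,
            "seed": cfg.seed,
        },
    )


# ---------------------------------------------------------------------------
# BIMAX
# ---------------------------------------------------------------------------


@dataclass
class BimaxConfig:
    """BIMAX parameters.

    ``binarization`` is either a rule name (``"median"``: 1 iff the value
    exceeds max(column median, 0), which handles count columns whose
    median is often 0 and time columns uniformly; ``"positive"``: 1 iff
    value > 0; ``"mean"``: 1 iff above the column mean) or a callable
    mapping the value matrix to a boolean matrix.
    """

    binarization: str | Callable[[np.ndarray], np.ndarray] = "median"
    min_rows: int = 2
    min_cols: int = 2
    max_biclusters: int = 100
    max_concepts: int = 200_000


def binarize(X: np.ndarray, rule: str | Callable[[np.ndarray], np.ndarray]) -> np.ndarray:
    if callable(rule):
        return np.asarray(rule(X), dtype=bool)
    if rule == "median":
        thr = np.maximum(np.median(X, axis=0), 0.0)
        return X > thr[None, :]
    if rule == "positive":
        return X > 0
    if rule == "mean":
        return X > X.mean(axis=0, keepdims=True)
    raise ValueError(f"unknown binarization rule {rule!r}")


def maximal_ones_submatrices(
    B: np.ndarray, min_rows: int = 1, min_cols: int = 1, max_concepts: int = 200_000
) -> list[tuple[np.ndarray, np.ndarray]]:
    """All inclusion-maximal all-ones submatrices of a boolean matrix.

    Enumerates the formal concepts of the binary relation with a
    Close-by-One recursion over columns, pruning branches whose row set
    falls below ``min_rows``.  Concepts with fewer than ``min_cols``
    columns are filtered afterwards (maximality is with respect to all
    all-ones submatrices, not the filtered set).
    """
    B = np.asarray(B, dtype=bool)
    n, p = B.shape
    out: list[tuple[np.ndarray, np.ndarray]] = []
    budget = [max_concepts]

    def close(extent: np.ndarray) -> np.ndarray:
        return B[extent].all(axis=0) if extent.any() else np.ones(p, dtype=bool)

    def cbo(extent: np.ndarray, intent: np.ndarray, j0: int) -> None:
        if budget[0] <= 0:
            return
        budget[0] -= 1
        if extent.sum() >= min_rows and intent.sum() >= 1:
            out.append((np.flatnonzero(extent), np.flatnonzero(intent)))
        for j in range(j0, p):
            if intent[j]:
                continue
            new_extent = extent & B[:, j]
            if new_extent.sum() < max(min_rows, 1):
                continue
            new_intent = close(new_extent)
            if np.any(new_intent[:j] & ~intent[:j]):
                continue  # canonicity: concept already reached via a smaller column
            cbo(new_extent, new_intent, j + 1)

    top_extent = np.ones(n, dtype=bool)
    cbo(top_extent, close(top_extent), 0)
    if budget[0] <= 0:
        warnings.warn(
            "concept enumeration truncated at max_concepts; "
            "the returned set may be incomplete",
            stacklevel=2,
        )
    return [(r, c) for r, c in out if len(c) >= min_cols]


def run_bimax(A: FeatureMatrix | np.ndarray, cfg: BimaxConfig | None = None) -> BiclusterSet:
    """Inclusion-maximal all-ones biclustering of the binarized matrix.

    Results are ordered by decreasing area with a deterministic
    lexicographic tie-break on (sorted row ids, sorted col ids), then
    truncated to ``max_biclusters``.  An all-zero binarized matrix yields
    an empty set.
    """
    cfg = cfg or BimaxConfig()
    X = _values(A)
    B = binarize(X, cfg.binarization)
    concepts = maximal_ones_submatrices(
        B, cfg.min_rows, cfg.min_cols, cfg.max_concepts
    )
    concepts.sort(key=lambda rc: (-len(rc[0]) * len(rc[1]), tuple(rc[0]), tuple(rc[1])))
    bics = [
        Bicluster(r.tolist(), c.tolist())
        for r, c in concepts[: cfg.max_biclusters]
    ]
    return BiclusterSet(
        bics,
        provenance={
            "algorithm": "bimax",
            "binarization": cfg.binarization if isinstance(cfg.binarization, str) else "custom",
            "min_rows": cfg.min_rows,
            "min_cols": cfg.min_cols,
            "max_biclusters": cfg.max_biclusters,
        },
    )


# ---------------------------------------------------------------------------
# Spectral checkerboard
# ---------------------------------------------------------------------------


@dataclass
class SpectralConfig:
    """Spectral checkerboard parameters.

    ``n_eigenvalues`` non-trivial singular vector pairs are kept;
    ``normalization`` is ``"bistochastic"`` (Sinkhorn scaling) or
    ``"log"`` (log(1+x) interactions, suited to count data).  Row/column
    class counts default to an elbow on the k-means inertia of the
    projections; a ``within_variance_cap`` optionally drops checkerboard
    blocks with VAR above the cap.
    """

    normalization: str = "bistochastic"
    n_eigenvalues: int = 2
    n_row_classes: int | None = None
    n_col_classes: int | None = None
    max_classes: int = 8
    within_variance_cap: float | None = None
    seed: int = 0
    n_init: int = 10
    sinkhorn_iter: int = 200
    sinkhorn_tol: float = 1e-10


def _bistochastize(X: np.ndarray, n_iter: int, tol: float) -> np.ndarray:
    """Sinkhorn row/column scaling to (approximately) constant margins."""
    B = X.copy()
    for _ in range(n_iter):
        r = B.sum(axis=1, keepdims=True)
        B = B / r * r.mean()
        c = B.sum(axis=0, keepdims=True)
        B = B / c * c.mean()
        if (
            np.abs(B.sum(axis=1) - B.sum(axis=1).mean()).max() < tol
            and np.abs(B.sum(axis=0) - B.sum(axis=0).mean()).max() < tol
        ):
            break
    return B


def _elbow_k(proj: np.ndarray, max_k: int, seed: int, n_init: int) -> tuple[int, np.ndarray]:
    """Pick the class count by an elbow on k-means inertia.

    The smallest k whose inertia is essentially zero relative to the
    total spread is chosen (this recovers the exact class count for
    noiseless piecewise-constant projections); otherwise the k with the
    largest relative inertia drop is used.
    """
    n = proj.shape[0]
    n_unique = np.unique(np.round(proj, 12), axis=0).shape[0]
    max_k = max(2, min(max_k, n, n_unique))
    total = float(((proj - proj.mean(axis=0)) ** 2).sum())
    if total <= 1e-12 or n_unique == 1:
        return 1, np.zeros(n, dtype=int)
    inertias, labelings = [total], [np.zeros(n, dtype=int)]
    for k in range(2, max_k + 1):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(proj)
        inertias.append(float(km.inertia_))
        labelings.append(km.labels_)
    inertias_arr = np.asarray(inertias)
    small = np.flatnonzero(inertias_arr <= 1e-9 * total)
    if small.size:
        idx = int(small[0])
    else:
        drops = (inertias_arr[:-1] - inertias_arr[1:]) / np.maximum(inertias_arr[:-1], 1e-30)
        idx = int(np.argmax(drops)) + 1
    return idx + 1, labelings[idx]


def run_spectral(
    A: FeatureMatrix | np.ndarray, cfg: SpectralConfig | None = None
) -> BiclusterSet:
    """Checkerboard biclustering via SVD of the normalized matrix.

    Returns the full crossing of the recovered row and column partitions;
    with no variance cap the biclusters tile the matrix cells exactly
    once.  A matrix with no non-trivial spectral structure (e.g. a
    constant matrix) degenerates to a single whole-matrix bicluster.
    """
    cfg = cfg or SpectralConfig()
    X = _values(A)
    n, p = X.shape
    if cfg.n_eigenvalues >= min(n, p):
        raise ValueError("n_eigenvalues must be smaller than min(N, P)")

    shift = X.min()
    pos = X - shift + 1e-6 * max(1.0, float(X.max() - shift))

    if cfg.normalization == "bistochastic":
        B = _bistochastize(pos, cfg.sinkhorn_iter, cfg.sinkhorn_tol)
        skip = 1  # leading pair of a bistochastic-like matrix is trivial
    elif cfg.normalization == "log":
        L = np.log1p(pos)
        B = L - L.mean(axis=1, keepdims=True) - L.mean(axis=0, keepdims=True) + L.mean()
        skip = 0
    else:
        raise ValueError(f"unknown normalization {cfg.normalization!r}")

    U, s, Vt = np.linalg.svd(B, full_matrices=False)
    sel = slice(skip, skip + cfg.n_eigenvalues)
    scale = s[0] if s[0] > 0 else 1.0
    if s[sel].size == 0 or np.all(s[sel] <= 1e-9 * scale):
        whole = Bicluster(list(range(n)), list(range(p)))
        return BiclusterSet([whole], provenance={"algorithm": "spectral", "degenerate": True})

    row_proj = U[:, sel] * s[sel]
    col_proj = Vt[sel].T * s[sel]

    if cfg.n_row_classes is not None:
        km = KMeans(cfg.n_row_classes, n_init=cfg.n_init, random_state=cfg.seed).fit(row_proj)
        row_labels = km.labels_
    else:
        _, row_labels = _elbow_k(row_proj, cfg.max_classes, cfg.seed, cfg.n_init)
    if cfg.n_col_classes is not None:
        km = KMeans(cfg.n_col_classes, n_init=cfg.n_init, random_state=cfg.seed).fit(col_proj)
        col_labels = km.labels_
    else:
        _, col_labels = _elbow_k(col_proj, cfg.max_classes, cfg.seed, cfg.n_init)

    bics = []
    for rl in sorted(set(row_labels.tolist())):
        rows = np.flatnonzero(row_labels == rl)
        for cl in sorted(set(col_labels.tolist())):
            cols = np.flatnonzero(col_labels == cl)
            bics.append(Bicluster(rows.tolist(), cols.tolist()))

    if cfg.within_variance_cap is not None:
        from .metrics import var_score

        bics = [b for b in bics if var_score(X, b) <= cfg.within_variance_cap]

    return BiclusterSet(
        bics,
        provenance={
            "algorithm": "spectral",
            "normalization": cfg.normalization,
            "n_eigenvalues": cfg.n_eigenvalues,
            "n_row_classes": int(len(set(row_labels.tolist()))),
            "n_col_classes": int(len(set(col_labels.tolist()))),
            "seed": cfg.seed,
        },
    )


# ---------------------------------------------------------------------------
# FABIA-style sparse factor biclustering
# ---------------------------------------------------------------------------


@dataclass
class FabiaConfig:
    """Sparse-factor biclustering parameters.

    The model is ``X ~ Z L^T`` with ``p = n_factors`` factors;
    ``sparseness`` scales the L1 soft-threshold applied to factor scores
    and loadings each iteration (the Laplace-prior-inspired shrinkage).
    Columns are z-scored internally by default (the factor model's
    native scale), as with the published implementations of this family;
    biclusters are reported against the original matrix.  Extraction:
    rows whose |score - median score| is at least ``thres_z`` times the
    factor's largest such deviation, columns with |loading| >=
    ``thres_l`` times the factor's largest |loading|.
    """

    n_factors: int = 5
    sparseness: float = 0.25
    max_iter: int = 300
    tol: float = 1e-7
    thres_z: float = 0.5
    thres_l: float = 0.5
    seed: int = 0
    center: bool = True
    standardize: bool = True
    restarts: int = 5


def _soft(M: np.ndarray, thr: np.ndarray) -> np.ndarray:
    return np.sign(M) * np.maximum(np.abs(M) - thr, 0.0)


def run_fabia(A: FeatureMatrix | np.ndarray, cfg: FabiaConfig | None = None) -> BiclusterSet:
    """Fit the sparse factor model and extract one bicluster per factor.

    Deterministic under ``cfg.seed``; factors whose thresholded row or
    column set is empty are dropped (a zero matrix yields an empty set).
    Non-convergence after ``max_iter`` returns the final iterate with a
    warning.
    """
    cfg = cfg or FabiaConfig()
    if cfg.n_factors < 1:
        raise ValueError("n_factors must be >= 1")
    X = _values(A).copy()
    n, p = X.shape
    if cfg.standardize:
        X = column_standardize(X)
    elif cfg.center:
        X = X - X.mean(axis=0, keepdims=True)

    data_scale = float(np.sqrt(np.mean(X**2))) or 1.0
    ridge = 1e-8
    eye = np.eye(cfg.n_factors)

    def _fit(rng: np.random.Generator):
        L = rng.normal(0.0, 0.1, size=(p, cfg.n_factors))
        conv = False
        for _ in range(cfg.max_iter):
            L_old = L.copy()
            G = L.T @ L + ridge * eye
            Z = X @ L @ np.linalg.inv(G)
            Z = _soft(Z, cfg.sparseness * np.mean(np.abs(Z), axis=0, keepdims=True))

            H = Z.T @ Z + ridge * eye
            L = X.T @ Z @ np.linalg.inv(H)
            L = _soft(L, cfg.sparseness * np.mean(np.abs(L), axis=0, keepdims=True))

            # fix the scale ambiguity: unit-norm loadings, scale in the scores
            norms = np.linalg.norm(L, axis=0)
            nz = norms > 1e-12 * data_scale
            L[:, nz] = L[:, nz] / norms[nz]
            if np.max(np.abs(L - L_old)) < cfg.tol:
                conv = True
                break
        # final factor scores, with the same shrinkage the model was fit under
        G = L.T @ L + ridge * eye
        Z = X @ L @ np.linalg.inv(G)
        Z = _soft(Z, cfg.sparseness * np.mean(np.abs(Z), axis=0, keepdims=True))
        err = float(np.mean((X - Z @ L.T) ** 2))
        return L, Z, err, conv

    # several seeded random starts; keep the fit reconstructing X best
    seeds = np.random.SeedSequence(cfg.seed).spawn(max(1, cfg.restarts))
    best = None
    for ss in seeds:
        fit = _fit(np.random.default_rng(ss))
        if best is None or fit[2] < best[2]:
            best = fit
    L, Z, _, converged = best
    if not converged:
        warnings.warn("sparse factor EM did not converge; returning final iterate", stacklevel=2)

    bics = []
    for k in range(cfg.n_factors):
        lmax = np.max(np.abs(L[:, k]))
        # row membership by deviation from the median factor score: the
        # median tracks the constant offset that column-centering induces
        # on non-member rows, so deviations isolate the member mode
        dev = np.abs(Z[:, k] - np.median(Z[:, k]))
        dmax = dev.max()
        if lmax <= 1e-9 * max(data_scale, 1e-30) or dmax <= 1e-12 * data_scale:
            continue
        rows = np.flatnonzero(dev >= cfg.thres_z * dmax)
        cols = np.flatnonzero(np.abs(L[:, k]) >= cfg.thres_l * lmax)
        if rows.size == 0 or cols.size == 0:
            continue
        bics.append(Bicluster(rows.tolist(), cols.tolist()))

    return BiclusterSet(
        bics,
        provenance={
            "algorithm": "fabia",
            "n_factors": cfg.n_factors,
            "sparseness": cfg.sparseness,
            "thres_z": cfg.thres_z,
            "thres_l": cfg.thres_l,
            "seed": cfg.seed,
            "converged": converged,
        },
    )
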