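"""Internal validity statistics for biclusters: VAR, MSR and VE.

A bicluster ``B_s = (b_ij)`` is a submatrix of the data matrix ``A``
selected by a row index set ``I_s`` (examinees) and a column index set
``J_s`` (features); both rows and columns may overlap across biclusters.
Three within-bicluster homogeneity statistics are computed:

* ``VAR`` -- mean squared deviation from the bicluster's grand mean;
  zero exactly for constant biclusters.
* ``MSR`` -- mean squared residue of the two-way additive fit
  ``b_ij - b_iJ - b_Ij + b_IJ``; zero for constant and shifting
  (``b_ij = alpha_i + beta_j``) patterns.
* ``VE`` -- virtual error: mean absolute deviation of the row-standardized
  entries from their column-wise mean pattern; zero for shifting and for
  positive-scaling (``b_ij = alpha_i * beta_j``) patterns.

Row standardization in VE uses the population denominator ``|J_s|`` for
the row standard deviation, consistent with VAR's normalization.  Rows
with zero standard deviation are flagged and their standardized entries
defined as 0, which keeps constant biclusters at VE = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import FeatureMatrix

__all__ = [
    "Bicluster",
    "BiclusterSet",
    "ResidueDecomposition",
    "QualityScores",
    "residue_decomposition",
    "var_score",
    "msr_score",
    "ve_score",
    "quality_of_set",
    "partition_to_biclusters",
]


@dataclass(frozen=True)
class Bicluster:
    """Index-set pair (I_s, J_s) into a feature matrix (0-based)."""

    rows: tuple[int, ...]
    cols: tuple[int, ...]

    def __init__(self, rows: Sequence[int], cols: Sequence[int]):
        rows = tuple(int(r) for r in rows)
        cols = tuple(int(c) for c in cols)
        if not rows or not cols:
            raise ValueError("bicluster must have at least one row and one column")
        if len(set(rows)) != len(rows) or len(set(cols)) != len(cols):
            raise ValueError("bicluster index sets must not contain duplicates")
        if min(rows) < 0 or min(cols) < 0:
            raise ValueError("bicluster indices must be non-negative")
        object.__setattr__(self, "rows", rows)
        object.__setattr__(self, "cols", cols)

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.rows), len(self.cols)

    @property
    def size(self) -> int:
        return len(self.rows) * len(self.cols)

    def cells(self) -> set[tuple[int, int]]:
        return {(i, j) for i in self.rows for j in self.cols}

    def submatrix(self, A: FeatureMatrix | np.ndarray) -> np.ndarray:
        values = A.values if isinstance(A, FeatureMatrix) else np.asarray(A, float)
        ri, ci = np.asarray(self.rows), np.asarray(self.cols)
        if ri.max() >= values.shape[0] or ci.max() >= values.shape[1]:
            raise ValueError("bicluster indices out of matrix bounds")
        return values[np.ix_(ri, ci)]

    def sorted(self) -> "Bicluster":
        return Bicluster(sorted(self.rows), sorted(self.cols))


@dataclass
class BiclusterSet:
    """Ordered list of biclusters with provenance (algorithm + parameters)."""

    biclusters: list[Bicluster]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.biclusters)

    def __iter__(self):
        return iter(self.biclusters)

    def __getitem__(self, i: int) -> Bicluster:
        return self.biclusters[i]

    @property
    def S(self) -> int:
        return len(self.biclusters)

    def to_json_dict(self, A: FeatureMatrix) -> dict:
        return {
            "provenance": self.provenance,
            "biclusters": [
                {
                    "rows": [A.row_ids[i] for i in b.rows],
                    "cols": [A.col_ids[j] for j in b.cols],
                }
                for b in self.biclusters
            ],
        }

    @classmethod
    def from_json_dict(cls, doc: dict, A: FeatureMatrix) -> "BiclusterSet":
        bics = [
            Bicluster(A.row_index(d["rows"]), A.col_index(d["cols"]))
            for d in doc["biclusters"]
        ]
        return cls(biclusters=bics, provenance=doc.get("provenance", {}))


@dataclass
class ResidueDecomposition:
    """Means and row-standardized entries of a bicluster submatrix."""

    row_means: np.ndarray      # b_iJ, length |I|
    col_means: np.ndarray      # b_Ij, length |J|
    overall_mean: float        # b_IJ
    row_mu: np.ndarray         # mu_i, == row_means
    row_sigma: np.ndarray      # population sd per row (divide by |J|)
    normalized: np.ndarray     # b^_ij, zero rows where sigma_i == 0
    pattern: np.ndarray        # rho^_j = column means of b^
    zero_sigma_rows: np.ndarray  # positions (within the bicluster) flagged


def residue_decomposition(A: FeatureMatrix | np.ndarray, b: Bicluster) -> ResidueDecomposition:
    sub = b.submatrix(A)
    row_means = sub.mean(axis=1)
    col_means = sub.mean(axis=0)
    overall = float(sub.mean())
    sigma = sub.std(axis=1)  # population sd (denominator |J_s|) per row
    zero_rows = np.flatnonzero(sigma == 0)
    safe = np.where(sigma == 0, 1.0, sigma)
    normalized = (sub - row_means[:, None]) / safe[:, None]
    normalized[zero_rows, :] = 0.0
    pattern = normalized.mean(axis=0)
    return ResidueDecomposition(
        row_means=row_means,
        col_means=col_means,
        overall_mean=overall,
        row_mu=row_means,
        row_sigma=sigma,
        normalized=normalized,
        pattern=pattern,
        zero_sigma_rows=zero_rows,
    )


def var_score(A: FeatureMatrix | np.ndarray, b: Bicluster) -> float:
    """Within-bicluster variance about the grand mean."""
    sub = b.submatrix(A)
    return float(np.mean((sub - sub.mean()) ** 2))


def msr_score(A: FeatureMatrix | np.ndarray, b: Bicluster) -> float:
    """Mean squared residue of the additive row+column fit."""
    sub = b.submatrix(A)
    res = sub - sub.mean(axis=1, keepdims=True) - sub.mean(axis=0, keepdims=True) + sub.mean()
    return float(np.mean(res**2))


def ve_score(A: FeatureMatrix | np.ndarray, b: Bicluster) -> float:
    """Virtual error of the row-standardized pattern."""
    dec = residue_decomposition(A, b)
    return float(np.mean(np.abs(dec.normalized - dec.pattern[None, :])))


@dataclass
class QualityScores:
    """Per-bicluster VAR/MSR/VE plus their (unweighted) set-level means."""

    var: np.ndarray
    msr: np.ndarray
    ve: np.ndarray
    mean_var: float
    mean_msr: float
    mean_ve: float
    weighted_mean_var: float
    weighted_mean_msr: float
    weighted_mean_ve: float

    def as_dict(self) -> dict:
        return {
            "VAR": self.mean_var,
            "MSR": self.mean_msr,
            "VE": self.mean_ve,
        }


def quality_of_set(
    A: FeatureMatrix | np.ndarray, S: BiclusterSet | Sequence[Bicluster]
) -> QualityScores:
    """Score every bicluster in a set and aggregate.

    Set-level values are unweighted arithmetic means across biclusters;
    size-weighted means (weights = cell counts) are reported alongside.
    """
    bics = list(S)
    if not bics:
        raise ValueError("cannot score an empty bicluster set")
    var = np.asarray([var_score(A, b) for b in bics])
    msr = np.asarray([msr_score(A, b) for b in bics])
    ve = np.asarray([ve_score(A, b) for b in bics])
    w = np.asarray([b.size for b in bics], dtype=float)
    w = w / w.sum()
    return QualityScores(
        var=var,
        msr=msr,
        ve=ve,
        mean_var=float(var.mean()),
        mean_msr=float(msr.mean()),
        mean_ve=float(ve.mean()),
        weighted_mean_var=float(var @ w),
        weighted_mean_msr=float(msr @ w),
        weighted_mean_ve=float(ve @ w),
    )


def partition_to_biclusters(
    labels: Sequence[int], A: FeatureMatrix | np.ndarray
) -> BiclusterSet:
    """Adapt a one-mode row partition to biclusters spanning all P columns.

    This is how a k-means solution is made comparable to biclustering
    output: each cluster becomes a bicluster whose column set is the full
    feature set.
    """
    labels = np.asarray(labels)
    n = A.n_rows if isinstance(A, FeatureMatrix) else np.asarray(A).shape[0]
    p = A.n_cols if isinstance(A, FeatureMatrix) else np.asarray(A).shape[1]
    if labels.shape[0] != n:
        raise ValueError("labels must cover every row of the matrix")
    cols = tuple(range(p))
    bics = []
    for lab in sorted(set(labels.tolist())):
        members = np.flatnonzero(labels == lab)
        bics.append(Bicluster(members.tolist(), cols))
    return BiclusterSet(biclusters=bics, provenance={"algorithm": "partition"})
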