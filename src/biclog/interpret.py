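"""Interpretation of a bicluster solution.

Feature contribution counts, per-bicluster feature profiles, the
association between biclusters and rubric scores (full / partial / zero /
mixed classes), the cross-tabulation of bicluster membership against a
one-mode partition, pairwise overlap statistics, and a deterministic
report bundle (CSV/JSON tables plus heatmap images).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .baseline import ClusterSolution
from .data import FeatureMatrix, ScoreVector
from .metrics import BiclusterSet, quality_of_set

__all__ = [
    "FeatureContribution",
    "ScoreAssociation",
    "feature_contribution",
    "bicluster_profiles",
    "score_association",
    "cross_tabulate",
    "overlap_statistics",
    "render_report",
]

SCORE_CLASSES = ("full", "partial", "zero", "mixed")


@dataclass
class FeatureContribution:
    """How often each feature is included across the biclusters."""

    counts: pd.Series  # index = feature name, value = inclusion count
    n_used: int        # features included at least once
    unused: list[str]  # features never included


def feature_contribution(
    S: BiclusterSet, all_features: Sequence[str]
) -> FeatureContribution:
    if len(S) == 0:
        raise ValueError("bicluster set is empty")
    counts = pd.Series(0, index=list(all_features), dtype=int)
    for b in S:
        for j in b.cols:
            counts.iloc[j] += 1
    used = counts[counts > 0]
    return FeatureContribution(
        counts=counts,
        n_used=int((counts > 0).sum()),
        unused=list(counts.index[counts == 0]),
    )


def bicluster_profiles(A: FeatureMatrix, S: BiclusterSet) -> pd.DataFrame:
    """Per-bicluster feature means with an inclusion mask.

    For each bicluster, included features report the mean over member
    rows; excluded features report the full-sample mean with
    ``included = False``, so included and excluded columns can be
    contrasted side by side.
    """
    records = []
    full_means = A.values.mean(axis=0)
    for s, b in enumerate(S):
        sub_mean = A.values[np.asarray(b.rows)].mean(axis=0)
        included = np.zeros(A.n_cols, dtype=bool)
        included[np.asarray(b.cols)] = True
        for j, name in enumerate(A.col_ids):
            records.append(
                {
                    "bicluster": s,
                    "feature": name,
                    "included": bool(included[j]),
                    "mean": float(sub_mean[j]) if included[j] else float(full_means[j]),
                    "member_mean": float(sub_mean[j]),
                }
            )
    return pd.DataFrame.from_records(records)


@dataclass
class ScoreAssociation:
    """Distribution of rubric scores within each bicluster."""

    table: pd.DataFrame  # rows = biclusters; columns: n, score_0/1/2, class
    purity: float

    @property
    def classes(self) -> list[str]:
        return list(self.table["class"])


def score_association(
    S: BiclusterSet,
    scores: ScoreVector | np.ndarray,
    A: FeatureMatrix | None = None,
    purity: float = 0.9,
) -> ScoreAssociation:
    """Classify each bicluster by the scores of its members.

    A bicluster is ``full``/``partial``/``zero`` when at least ``purity``
    of its members scored 2/1/0 respectively, else ``mixed``.
    """
    if isinstance(scores, ScoreVector):
        if A is None:
            raise ValueError("a FeatureMatrix is needed to align a ScoreVector")
        vec = scores.aligned_to(A)
    else:
        vec = np.asarray(scores, dtype=int)
    if vec.size and not np.isin(vec, [0, 1, 2]).all():
        raise ValueError("scores must lie in {0, 1, 2}")

    records = []
    for s, b in enumerate(S):
        member = vec[np.asarray(b.rows)]
        n = member.shape[0]
        dist = {f"score_{v}": int((member == v).sum()) for v in (0, 1, 2)}
        if dist["score_2"] >= purity * n:
            cls = "full"
        elif dist["score_1"] >= purity * n:
            cls = "partial"
        elif dist["score_0"] >= purity * n:
            cls = "zero"
        else:
            cls = "mixed"
        records.append({"bicluster": s, "n": n, **dist, "class": cls})
    return ScoreAssociation(table=pd.DataFrame.from_records(records), purity=purity)


def cross_tabulate(S: BiclusterSet, solution: ClusterSolution) -> pd.DataFrame:
    """Bicluster x one-mode-cluster membership counts.

    Cell (s, c) counts the members of bicluster s carrying one-mode label
    c; row sums equal bicluster sizes (biclusters may overlap, so column
    sums need not equal cluster sizes).
    """
    labels = solution.labels
    cols = [f"cluster_{c}" for c in range(solution.k)]
    rows = []
    for b in S:
        member = labels[np.asarray(b.rows)]
        rows.append([int((member == c).sum()) for c in range(solution.k)])
    frame = pd.DataFrame(rows, columns=cols)
    frame.index.name = "bicluster"
    return frame


def _jaccard(a: set, b: set) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def overlap_statistics(S: BiclusterSet) -> dict:
    """Pairwise row-set and column-set Jaccard summaries."""
    if len(S) < 2:
        raise ValueError("overlap statistics need at least 2 biclusters")
    row_sets = [set(b.rows) for b in S]
    col_sets = [set(b.cols) for b in S]
    row_j, col_j = [], []
    for i in range(len(S)):
        for k in range(i + 1, len(S)):
            row_j.append(_jaccard(row_sets[i], row_sets[k]))
            col_j.append(_jaccard(col_sets[i], col_sets[k]))
    return {
        "row_jaccard_max": max(row_j),
        "row_jaccard_mean": float(np.mean(row_j)),
        "col_jaccard_max": max(col_j),
        "col_jaccard_mean": float(np.mean(col_j)),
        "rows_overlap": any(j > 0 for j in row_j),
        "cols_overlap": any(j > 0 for j in col_j),
    }


def _heatmap(A: FeatureMatrix, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # examinees ordered by total time when present, the heatmap convention
    if "T_time" in A.col_ids:
        order = np.argsort(A.values[:, A.col_ids.index("T_time")], kind="stable")
    else:
        order = np.arange(A.n_rows)
    fig, ax = plt.subplots(figsize=(8, 6))
    with np.errstate(all="ignore"):
        scaled = np.log1p(np.clip(A.values[order], 0, None))
    im = ax.imshow(scaled, aspect="auto", interpolation="nearest", cmap="viridis")
    ax.set_xlabel("feature")
    ax.set_ylabel("examinee (ascending total time)")
    ax.set_xticks(range(A.n_cols))
    ax.set_xticklabels(A.col_ids, rotation=90, fontsize=5)
    fig.colorbar(im, ax=ax, label="log(1 + value)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_report(
    out_dir: str | Path,
    A: FeatureMatrix,
    S: BiclusterSet,
    scores: ScoreVector | None = None,
    solution: ClusterSolution | None = None,
    purity: float = 0.9,
    heatmaps: bool = True,
) -> dict:
    """Write the full interpretation bundle to a directory.

    Sections: metric table, feature contribution, profiles, score
    classes, cross-tabulation (when a one-mode solution is given) and
    overlap statistics, plus a heatmap image.  CSV/JSON outputs are
    byte-identical across re-renders of the same inputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"n_biclusters": len(S), "provenance": S.provenance}

    if len(S) == 0:
        (out / "summary.json").write_text(
            json.dumps({**summary, "note": "empty bicluster set"}, indent=1, sort_keys=True)
        )
        return summary

    q = quality_of_set(A, S)
    pd.DataFrame(
        {"bicluster": range(len(S)), "VAR": q.var, "MSR": q.msr, "VE": q.ve}
    ).to_csv(out / "metrics.csv", index=False)
    summary["criteria_means"] = q.as_dict()

    contrib = feature_contribution(S, A.col_ids)
    contrib.counts.rename("count").to_csv(out / "feature_contribution.csv")
    summary["features_used"] = contrib.n_used

    bicluster_profiles(A, S).to_csv(out / "profiles.csv", index=False)

    if scores is not None:
        assoc = score_association(S, scores, A, purity=purity)
        assoc.table.to_csv(out / "score_association.csv", index=False)
        summary["score_classes"] = assoc.classes

    if solution is not None:
        cross_tabulate(S, solution).to_csv(out / "cross_tab.csv")

    if len(S) >= 2:
        summary["overlap"] = overlap_statistics(S)

    if heatmaps:
        _heatmap(A, out / "heatmap.png")

    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
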