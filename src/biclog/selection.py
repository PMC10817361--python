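"""Configuration grids over bicluster counts and cross-method comparison.

``grid_search`` runs a method over a grid of bicluster counts (2..30 by
default), scores each solution with the three internal validity
statistics, and picks the count minimizing each criterion (smallest k on
ties, favouring parsimony).  ``compare_methods`` assembles the
criterion x method comparison table, adapting one-mode k-means solutions
to biclusters so all columns are scored identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .algorithms import (
    BCCConfig,
    BimaxConfig,
    FabiaConfig,
    SpectralConfig,
    run_bcc,
    run_bimax,
    run_fabia,
    run_spectral,
)
from .baseline import run_kmeans
from .data import FeatureMatrix
from .metrics import BiclusterSet, partition_to_biclusters, quality_of_set

logger = logging.getLogger("biclog")

__all__ = ["SelectionResult", "grid_search", "scan_native", "compare_methods"]

CRITERIA = ("VAR", "MSR", "VE")


@dataclass
class SelectionResult:
    """Criterion grid and the chosen count per criterion."""

    method: str
    grid: pd.DataFrame  # columns: k, S, VAR, MSR, VE
    chosen: dict[str, int]
    consensus: bool
    params: dict = field(default_factory=dict)

    def chosen_consensus(self) -> int | None:
        vals = set(self.chosen.values())
        return vals.pop() if len(vals) == 1 else None


def _run_with_k(A: FeatureMatrix, method: str, k: int, seed: int, cfg) -> BiclusterSet:
    if method == "bimax":
        base = cfg or BimaxConfig()
        return run_bimax(
            A,
            BimaxConfig(
                binarization=base.binarization,
                min_rows=base.min_rows,
                min_cols=base.min_cols,
                max_biclusters=k,
                max_concepts=base.max_concepts,
            ),
        )
    if method == "fabia":
        base = cfg or FabiaConfig()
        return run_fabia(
            A,
            FabiaConfig(
                n_factors=k,
                sparseness=base.sparseness,
                max_iter=base.max_iter,
                tol=base.tol,
                thres_z=base.thres_z,
                thres_l=base.thres_l,
                seed=seed,
                center=base.center,
            ),
        )
    if method == "kmeans":
        sol = run_kmeans(A, k, seed=seed)
        return partition_to_biclusters(sol.labels, A)
    raise ValueError(f"grid_search does not handle method {method!r}")


def grid_search(
    A: FeatureMatrix,
    method: str,
    k_grid: Sequence[int] = tuple(range(2, 31)),
    cfg=None,
    seed: int = 0,
) -> SelectionResult:
    """Scan bicluster/cluster counts and choose the optimum per criterion.

    ``method`` is one of ``bimax``, ``fabia`` (k = bicluster count) or
    ``kmeans`` (k = cluster count, adapted via partition_to_biclusters).
    BCC and spectral have no bicluster-count knob: use
    :func:`scan_native` with their native parameters instead.
    """
    if method in ("bcc", "spectral"):
        raise ValueError(
            f"{method} is not selected by a bicluster count; scan its native "
            "configuration (delta / n_eigenvalues) with scan_native()"
        )
    k_grid = list(dict.fromkeys(int(k) for k in k_grid))
    if not k_grid:
        raise ValueError("empty k grid")
    records = []
    for k in k_grid:
        result = _run_with_k(A, method, k, seed, cfg)
        if len(result) == 0:
            logger.warning("%s produced no biclusters at k=%d; skipped", method, k)
            continue
        q = quality_of_set(A, result)
        records.append(
            {"k": k, "S": len(result), "VAR": q.mean_var, "MSR": q.mean_msr, "VE": q.mean_ve}
        )
    if not records:
        raise ValueError("no grid point produced a scoreable bicluster set")
    grid = pd.DataFrame.from_records(records)
    chosen = {
        crit: int(grid.loc[grid[crit].idxmin(), "k"]) for crit in CRITERIA
    }
    # idxmin returns the first minimum; the grid is scanned in ascending k,
    # so ties already resolve to the smallest count
    return SelectionResult(
        method=method,
        grid=grid,
        chosen=chosen,
        consensus=len(set(chosen.values())) == 1,
        params={"seed": seed},
    )


def scan_native(
    A: FeatureMatrix,
    method: str,
    param_grid: Sequence,
    cfg=None,
    seed: int = 0,
) -> SelectionResult:
    """Criterion scan over BCC's delta or spectral's n_eigenvalues."""
    records = []
    for val in param_grid:
        if method == "bcc":
            base = cfg or BCCConfig()
            result = run_bcc(
                A,
                BCCConfig(
                    delta=float(val),
                    alpha=base.alpha,
                    n_biclusters=base.n_biclusters,
                    seed=seed,
                    standardize=base.standardize,
                ),
            )
        elif method == "spectral":
            base = cfg or SpectralConfig()
            result = run_spectral(
                A,
                SpectralConfig(
                    normalization=base.normalization,
                    n_eigenvalues=int(val),
                    n_row_classes=base.n_row_classes,
                    n_col_classes=base.n_col_classes,
                    max_classes=base.max_classes,
                    within_variance_cap=base.within_variance_cap,
                    seed=seed,
                ),
            )
        else:
            raise ValueError(f"scan_native handles bcc/spectral, not {method!r}")
        if len(result) == 0:
            logger.warning("%s produced no biclusters at %s; skipped", method, val)
            continue
        q = quality_of_set(A, result)
        records.append(
            {"k": val, "S": len(result), "VAR": q.mean_var, "MSR": q.mean_msr, "VE": q.mean_ve}
        )
    if not records:
        raise ValueError("no grid point produced a scoreable bicluster set")
    grid = pd.DataFrame.from_records(records)
    chosen = {crit: grid.loc[grid[crit].idxmin(), "k"] for crit in CRITERIA}
    return SelectionResult(
        method=method,
        grid=grid,
        chosen=chosen,
        consensus=len(set(chosen.values())) == 1,
        params={"seed": seed},
    )


def compare_methods(
    A: FeatureMatrix,
    method_configs: dict | None = None,
    kmeans_ks: Sequence[int] = (2,),
    seed: int = 0,
) -> pd.DataFrame:
    """Criterion x method comparison table of set-level means.

    ``method_configs`` maps method names (``bcc``, ``bimax``, ``spectral``,
    ``fabia``) to their configs (None values use defaults); k-means
    columns ``KM{k}`` are added for each requested k.  A failing method
    yields a missing (NaN) column and the run continues.
    """
    if method_configs is None:
        method_configs = {
            "bcc": BCCConfig(),
            "bimax": BimaxConfig(),
            "spectral": SpectralConfig(),
            "fabia": FabiaConfig(),
        }
    runners = {
        "bcc": run_bcc,
        "bimax": run_bimax,
        "spectral": run_spectral,
        "fabia": run_fabia,
    }
    table: dict[str, dict[str, float]] = {}
    for k in kmeans_ks:
        name = f"KM{k}"
        try:
            sol = run_kmeans(A, int(k), seed=seed)
            q = quality_of_set(A, partition_to_biclusters(sol.labels, A))
            table[name] = q.as_dict()
        except Exception as exc:  # noqa: BLE001 - table cell marked missing
            logger.warning("k-means at k=%d failed: %s", k, exc)
            table[name] = {c: float("nan") for c in CRITERIA}
    for method, cfg in method_configs.items():
        try:
            result = runners[method](A, cfg)
            if len(result) == 0:
                raise ValueError("empty bicluster set")
            q = quality_of_set(A, result)
            table[method] = q.as_dict()
        except Exception as exc:  # noqa: BLE001
            logger.warning("method %s failed: %s", method, exc)
            table[method] = {c: float("nan") for c in CRITERIA}
    frame = pd.DataFrame(table)
    return frame.loc[list(CRITERIA)]
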