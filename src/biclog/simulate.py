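"""Synthetic data: planted-bicluster matrices and simulated ticket cohorts.

Two generators make the whole pipeline testable without the external
assessment logs:

``plant_biclusters``
    builds an N x P Gaussian background and overlays blocks following the
    canonical bicluster taxonomy -- constant, constant rows/columns,
    shifting (``alpha_i + beta_j``) and scaling (``alpha_i * beta_j``) --
    returning the matrix together with the ground-truth bicluster set.

``simulate_ticket_cohort``
    draws examinees from strategy archetypes, each a minimal finite-state
    grammar over the ticket-machine alphabet: a mandatory exploration
    prefix, Poisson-count extra actions from an archetype-specific pool,
    a fixed purchase segment, and log-normal inter-event gaps.  The
    archetype determines the rubric score deterministically, so rubric,
    extractor and biclustering can be tested jointly.

Recovery/relevance against planted truth use cell-level Jaccard matching
(each bicluster is compared as its set of (row, column) cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import (
    KIND_REAL,
    EventLog,
    FeatureMatrix,
)
from .metrics import Bicluster, BiclusterSet

__all__ = [
    "PlantedBlockModel",
    "plant_biclusters",
    "StrategyArchetype",
    "TICKET_ARCHETYPES",
    "DEFAULT_COHORT_MIXTURE",
    "simulate_ticket_cohort",
    "recovery_score",
]

BLOCK_KINDS = ("constant", "constant_rows", "constant_cols", "shifting", "scaling")


# ---------------------------------------------------------------------------
# Planted-block matrices
# ---------------------------------------------------------------------------


@dataclass
class PlantedBlockModel:
    """One block to plant: pattern kind, index sets and effect parameters.

    ``alpha``/``beta`` are the row/column effects used by the patterned
    kinds; for ``scaling`` all alpha of one sign keeps the block a zero-VE
    pattern.  Gaussian noise with sd ``noise_sd`` is added on top of the
    pattern.
    """

    kind: str
    rows: Sequence[int]
    cols: Sequence[int]
    base: float = 0.0
    alpha: Sequence[float] | None = None
    beta: Sequence[float] | None = None
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in BLOCK_KINDS:
            raise ValueError(f"unknown block kind {self.kind!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        self.rows = [int(r) for r in self.rows]
        self.cols = [int(c) for c in self.cols]
        if len(self.rows) < 2 or len(self.cols) < 2:
            raise ValueError("planted blocks must be at least 2 x 2")

    def pattern(self) -> np.ndarray:
        nr, nc = len(self.rows), len(self.cols)
        a = np.asarray(self.alpha, float) if self.alpha is not None else np.zeros(nr)
        b = np.asarray(self.beta, float) if self.beta is not None else np.zeros(nc)
        if a.shape[0] != nr or b.shape[0] != nc:
            raise ValueError("alpha/beta lengths must match block shape")
        if self.kind == "constant":
            return np.full((nr, nc), self.base)
        if self.kind == "constant_rows":
            return self.base + np.tile(a[:, None], (1, nc))
        if self.kind == "constant_cols":
            return self.base + np.tile(b[None, :], (nr, 1))
        if self.kind == "shifting":
            return self.base + a[:, None] + b[None, :]
        # scaling
        return (self.base if self.base != 0 else 1.0) * a[:, None] * b[None, :]


def plant_biclusters(
    N: int,
    P: int,
    blocks: Sequence[PlantedBlockModel],
    background_sd: float = 1.0,
    background_mean: float = 0.0,
    seed: int = 0,
) -> tuple[FeatureMatrix, BiclusterSet]:
    """Plant blocks in i.i.d. Gaussian background noise.

    Blocks may overlap (later blocks overwrite the pattern on shared
    cells).  Returns the matrix (generic ids, column kind ``real``) and
    the ground-truth bicluster set.
    """
    rng = np.random.default_rng(seed)
    values = rng.normal(background_mean, background_sd, size=(N, P))
    truth = []
    for blk in blocks:
        if max(blk.rows) >= N or max(blk.cols) >= P:
            raise ValueError("planted block exceeds matrix bounds")
        noise = rng.normal(0.0, blk.noise_sd, size=(len(blk.rows), len(blk.cols)))
        values[np.ix_(blk.rows, blk.cols)] = blk.pattern() + noise
        truth.append(Bicluster(blk.rows, blk.cols))
    matrix = FeatureMatrix(
        values=values,
        row_ids=[f"r{i}" for i in range(N)],
        col_ids=[f"f{j}" for j in range(P)],
        col_kind=[KIND_REAL] * P,
    )
    return matrix, BiclusterSet(truth, provenance={"algorithm": "planted", "seed": seed})


def subset_group_matrix(
    n_groups: int = 4,
    rows_per_group: int = 30,
    cols_per_group: int = 6,
    levels: Sequence[float] = (3.0, 10.0, 30.0, 60.0),
    row_effect_frac: float = 0.1,
    background_frac: float = 0.2,
    block_noise_frac: float = 0.05,
    seed: int = 0,
) -> tuple[FeatureMatrix, np.ndarray, BiclusterSet]:
    """Matrix whose row groups are defined by distinct feature subsets.

    Each group ``g`` sits at level ``levels[g]`` plus a per-row shifting
    effect on its own disjoint column subset; off-block cells of that
    subset are mean-zero Gaussian background.  All noise scales with the
    subset's level (background sd ``background_frac * level``), the way
    second-scale timing features and unit-scale action counts carry
    proportionally different noise in log-file matrices.  The widely
    differing levels give the columns heterogeneous scales, so one-mode
    clustering on all columns carries large within-cluster variance while
    column-subsetting methods can isolate homogeneous blocks.  Returns
    the matrix, the true group label per row, and the planted group x
    subset blocks.
    """
    if len(levels) < n_groups:
        raise ValueError("need a level per group")
    rng = np.random.default_rng(seed)
    n = n_groups * rows_per_group
    p = n_groups * cols_per_group
    values = np.empty((n, p))
    labels = np.repeat(np.arange(n_groups), rows_per_group)
    truth = []
    for g in range(n_groups):
        cols = np.arange(g * cols_per_group, (g + 1) * cols_per_group)
        values[:, cols] = rng.normal(
            0.0, background_frac * levels[g], size=(n, cols_per_group)
        )
    for g in range(n_groups):
        rows = np.arange(g * rows_per_group, (g + 1) * rows_per_group)
        cols = np.arange(g * cols_per_group, (g + 1) * cols_per_group)
        effects = rng.normal(0.0, row_effect_frac * levels[g], size=rows_per_group)
        values[np.ix_(rows, cols)] = (
            levels[g]
            + effects[:, None]
            + rng.normal(
                0.0, block_noise_frac * levels[g], size=(rows_per_group, cols_per_group)
            )
        )
        truth.append(Bicluster(rows.tolist(), cols.tolist()))
    matrix = FeatureMatrix(
        values=values,
        row_ids=[f"r{i}" for i in range(n)],
        col_ids=[f"f{j}" for j in range(p)],
        col_kind=[KIND_REAL] * p,
    )
    return matrix, labels, BiclusterSet(truth, provenance={"algorithm": "planted", "seed": seed})


# ---------------------------------------------------------------------------
# Ticket cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class StrategyArchetype:
    """A minimal generative grammar for one problem-solving strategy.

    A log is ``start`` + exploration prefix with Poisson-many extra
    actions from ``extra_pool`` spliced in at random positions + the fixed
    ``purchase`` segment + ``end``, with log-normal inter-event gaps.
    ``extra_pool`` is restricted so inserted actions can never change the
    purchase state or create/destroy the price comparison; the implied
    rubric score is therefore deterministic.
    """

    name: str
    explore: tuple[str, ...]
    purchase: tuple[str, ...]
    extra_pool: tuple[str, ...]
    extra_rate: float
    gap_mu: float      # log-scale mean of inter-event gaps (seconds)
    gap_sigma: float   # log-scale sd
    implied_score: int

    def draw_labels(self, rng: np.random.Generator) -> list[str]:
        body = list(self.explore)
        n_extra = int(rng.poisson(self.extra_rate))
        for _ in range(n_extra):
            pos = int(rng.integers(0, len(body) + 1))
            body.insert(pos, str(rng.choice(self.extra_pool)))
        return ["start", *body, *self.purchase, "end"]

    def draw_log(self, examinee_id: str, rng: np.random.Generator) -> EventLog:
        labels = self.draw_labels(rng)
        gaps = rng.lognormal(self.gap_mu, self.gap_sigma, size=len(labels) - 1)
        times = np.concatenate([[0.0], np.cumsum(gaps)])
        return EventLog(examinee_id, list(zip(labels, np.round(times, 3))))


#: Strategy archetypes of the ticket task.  ``comparer`` opens the daily
#: price screen, cancels, and buys the four individual concession trips
#: (full credit).  ``daily_only`` / ``individual_only`` commit to one
#: solution without comparing (partial credit).  ``explorer`` roams the
#: whole interface and finally buys the daily ticket after having seen the
#: individual prices (credited 1, flagged).  ``misfit`` buys a wrong
#: country-trains full fare (score 0).
TICKET_ARCHETYPES: dict[str, StrategyArchetype] = {
    a.name: a
    for a in [
        StrategyArchetype(
            name="comparer",
            explore=("city_subway", "concession", "daily", "cancel"),
            purchase=("individual", "trip_4", "buy"),
            extra_pool=("city_subway", "concession", "individual", "trip_4", "daily", "cancel"),
            extra_rate=3.0,
            gap_mu=1.0,
            gap_sigma=0.5,
            implied_score=2,
        ),
        StrategyArchetype(
            name="daily_only",
            explore=("city_subway", "concession"),
            purchase=("daily", "buy"),
            extra_pool=("city_subway", "concession", "cancel"),
            extra_rate=1.0,
            gap_mu=0.8,
            gap_sigma=0.4,
            implied_score=1,
        ),
        StrategyArchetype(
            name="individual_only",
            explore=("city_subway", "concession"),
            purchase=("individual", "trip_4", "buy"),
            extra_pool=("city_subway", "concession", "trip_4", "cancel"),
            extra_rate=1.0,
            gap_mu=0.8,
            gap_sigma=0.4,
            implied_score=1,
        ),
        StrategyArchetype(
            name="explorer",
            explore=(
                "city_subway",
                "concession",
                "individual",
                "trip_4",
                "cancel",
                "country_trains",
                "full_fare",
                "cancel",
            ),
            purchase=("city_subway", "concession", "daily", "buy"),
            extra_pool=(
                "city_subway",
                "country_trains",
                "concession",
                "full_fare",
                "individual",
                "daily",
                "trip_1",
                "trip_2",
                "trip_3",
                "trip_4",
                "trip_5",
                "cancel",
            ),
            extra_rate=8.0,
            gap_mu=1.3,
            gap_sigma=0.6,
            implied_score=1,
        ),
        StrategyArchetype(
            name="misfit",
            explore=("country_trains", "full_fare"),
            purchase=("individual", "trip_2", "buy"),
            extra_pool=("country_trains", "full_fare", "trip_1", "trip_5", "cancel"),
            extra_rate=2.0,
            gap_mu=1.0,
            gap_sigma=0.6,
            implied_score=0,
        ),
    ]
}

#: Default cohort composition: the four strategy classes mirroring the
#: full / partial / partial / zero score profile of the task.
DEFAULT_COHORT_MIXTURE: dict[str, float] = {
    "comparer": 0.35,
    "daily_only": 0.25,
    "individual_only": 0.25,
    "misfit": 0.15,
}


def simulate_ticket_cohort(
    n: int,
    mixture: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[list[EventLog], list[str]]:
    """Simulate a cohort of examinee logs from an archetype mixture.

    Returns the logs and the true archetype label per examinee.
    Reproducible under ``seed``; ``n = 0`` yields empty collections.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if mixture is None:
        mixture = dict(DEFAULT_COHORT_MIXTURE)
    names = list(mixture)
    props = np.asarray([mixture[k] for k in names], dtype=float)
    if np.any(props < 0) or not np.isclose(props.sum(), 1.0):
        raise ValueError("mixture proportions must be non-negative and sum to 1")
    unknown = [k for k in names if k not in TICKET_ARCHETYPES]
    if unknown:
        raise ValueError(f"unknown archetypes {unknown}")

    rng = np.random.default_rng(seed)
    assignments = rng.choice(names, size=n, p=props)
    width = max(4, len(str(max(n - 1, 0))))
    logs, labels = [], []
    for i, name in enumerate(assignments):
        arch = TICKET_ARCHETYPES[str(name)]
        logs.append(arch.draw_log(f"ex{i:0{width}d}", rng))
        labels.append(str(name))
    return logs, labels


# ---------------------------------------------------------------------------
# Planted-truth matching
# ---------------------------------------------------------------------------


def _cell_jaccard(a: Bicluster, b: Bicluster) -> float:
    ra, rb = set(a.rows), set(b.rows)
    ca, cb = set(a.cols), set(b.cols)
    inter = len(ra & rb) * len(ca & cb)
    union = a.size + b.size - inter
    return inter / union if union else 0.0


def recovery_score(
    found: BiclusterSet | Sequence[Bicluster],
    truth: BiclusterSet | Sequence[Bicluster],
) -> tuple[float, float]:
    """Cell-level Jaccard match scores against planted truth.

    ``recovery`` is the mean over true biclusters of the best Jaccard
    against the found set (how well truth was found); ``relevance`` is the
    symmetric counterpart (how well found biclusters match truth).
    """
    found, truth = list(found), list(truth)
    if not truth:
        raise ValueError("truth bicluster set must be nonempty")
    if not found:
        return 0.0, 0.0
    rec = float(np.mean([max(_cell_jaccard(t, f) for f in found) for t in truth]))
    rel = float(np.mean([max(_cell_jaccard(f, t) for t in truth) for f in found]))
    return rec, rel
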