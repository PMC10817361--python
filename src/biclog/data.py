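"""Core data types, readers/writers, feature extraction and the Ticket rubric.

The pipeline operates on an N x P feature matrix ``A = (a_ip)`` extracted
from per-examinee event logs of a computer-based problem-solving task
(modelled on the ticket-machine item of a complex-problem-solving
assessment).  Rows are examinees, columns are features of two families:

* ``time_seconds`` -- four summary latencies of the interaction
  (``T_time`` total, ``S_time`` start latency, ``A_time`` action span,
  ``E_time`` end latency), and
* ``action_count`` -- counts of single actions and of adjacent ordered
  action n-grams (bigrams, fourgrams) in the event sequence.

The rubric scorer maps a raw event log to a polytomous score in {0, 1, 2}.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("biclog")

START_MARKER = "start"
END_MARKER = "end"

#: Action alphabet of the simulated ticket-machine task.  Buttons select a
#: network (city subway / country trains), a fare type (concession / full
#: fare), a ticket type (daily / individual), a trip count, and finally
#: buy or cancel.
TICKET_ALPHABET = (
    START_MARKER,
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
    "buy",
    "cancel",
    END_MARKER,
)

TIME_FEATURES = ("T_time", "S_time", "A_time", "E_time")

KIND_TIME = "time_seconds"
KIND_COUNT = "action_count"
KIND_REAL = "real"  # synthetic benchmark matrices (unconstrained values)

_VALID_KINDS = (KIND_TIME, KIND_COUNT, KIND_REAL)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class FeatureMatrix:
    """The N x P real matrix ``A`` with row/column identifiers.

    Parameters
    ----------
    values : (N, P) float array
    row_ids : examinee identifiers, unique strings
    col_ids : feature names, unique strings
    col_kind : per-column tag, one of ``time_seconds``, ``action_count``,
        ``real``
    """

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    col_kind: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.row_ids = [str(r) for r in self.row_ids]
        self.col_ids = [str(c) for c in self.col_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, p = self.values.shape
        if n < 1 or p < 1:
            raise ValueError("feature matrix must be at least 1 x 1")
        if len(self.row_ids) != n or len(self.col_ids) != p:
            raise ValueError("id lengths do not match matrix shape")
        if len(set(self.row_ids)) != n:
            raise ValueError("duplicate examinee ids")
        if len(set(self.col_ids)) != p:
            raise ValueError("duplicate feature names")
        if len(self.col_kind) != p:
            raise ValueError("col_kind length does not match P")
        for k in self.col_kind:
            if k not in _VALID_KINDS:
                raise ValueError(f"unknown column kind {k!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains missing or non-finite entries")
        kinds = np.asarray(self.col_kind)
        counts = self.values[:, kinds == KIND_COUNT]
        if counts.size and (np.any(counts < 0) or np.any(counts != np.round(counts))):
            raise ValueError("action_count columns must be non-negative integers")
        times = self.values[:, kinds == KIND_TIME]
        if times.size and np.any(times < 0):
            raise ValueError("time_seconds columns must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def row_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {r: i for i, r in enumerate(self.row_ids)}
        return np.asarray([lookup[r] for r in ids], dtype=int)

    def col_index(self, names: Iterable[str]) -> np.ndarray:
        lookup = {c: j for j, c in enumerate(self.col_ids)}
        return np.asarray([lookup[c] for c in names], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)

    def to_csv(self, path: str | Path, schema: bool = True) -> None:
        """Write the matrix as CSV plus a JSON sidecar with column kinds."""
        path = Path(path)
        frame = self.to_frame()
        frame.index.name = "examinee_id"
        frame.to_csv(path)
        if schema:
            sidecar = path.with_suffix(path.suffix + ".schema.json")
            sidecar.write_text(
                json.dumps(dict(zip(self.col_ids, self.col_kind)), indent=1)
            )


@dataclass
class EventLog:
    """Ordered, time-stamped action sequence of a single examinee."""

    examinee_id: str
    events: list[tuple[str, float]]

    def __post_init__(self) -> None:
        if not self.events:
            raise ValueError(f"empty event log for examinee {self.examinee_id!r}")
        times = [t for _, t in self.events]
        if any(t < 0 for t in times):
            raise ValueError(
                f"negative timestamp in log for examinee {self.examinee_id!r}"
            )
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError(
                f"decreasing timestamps in log for examinee {self.examinee_id!r}"
            )
        if self.events[0][0] != START_MARKER:
            raise ValueError(
                f"log for examinee {self.examinee_id!r} does not begin with "
                f"{START_MARKER!r}"
            )
        if self.events[-1][0] != END_MARKER:
            raise ValueError(
                f"log for examinee {self.examinee_id!r} does not end with "
                f"{END_MARKER!r}"
            )

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.events]

    @property
    def times(self) -> list[float]:
        return [t for _, t in self.events]


@dataclass
class ScoreVector:
    """Polytomous scores in {0, 1, 2}, aligned with a FeatureMatrix's rows."""

    ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=int)
        if len(self.ids) != self.scores.shape[0]:
            raise ValueError("ids and scores differ in length")
        if self.scores.size and not np.isin(self.scores, [0, 1, 2]).all():
            raise ValueError("scores must lie in {0, 1, 2}")

    def aligned_to(self, matrix: FeatureMatrix) -> np.ndarray:
        lookup = dict(zip(self.ids, self.scores.tolist()))
        missing = [r for r in matrix.row_ids if r not in lookup]
        if missing:
            raise ValueError(f"scores missing for examinees {missing[:5]}")
        return np.asarray([lookup[r] for r in matrix.row_ids], dtype=int)


@dataclass
class FeatureDictionary:
    """The feature families extracted from an event log.

    ``unigrams`` count single action labels, ``bigrams``/``fourgrams`` count
    adjacent ordered label pairs/quadruples (overlapping windows, markers
    included), and ``time_features`` is the fixed latency quadruple.
    """

    unigrams: list[str] = field(default_factory=list)
    bigrams: list[tuple[str, ...]] = field(default_factory=list)
    fourgrams: list[tuple[str, ...]] = field(default_factory=list)
    bigram_names: dict[tuple[str, ...], str] = field(default_factory=dict)
    fourgram_names: dict[tuple[str, ...], str] = field(default_factory=dict)
    time_features: tuple[str, ...] = TIME_FEATURES

    def __post_init__(self) -> None:
        self.bigrams = [tuple(b) for b in self.bigrams]
        self.fourgrams = [tuple(g) for g in self.fourgrams]
        names = self.feature_names()
        if len(names) != len(set(names)):
            raise ValueError("feature names are not unique across families")

    def name_of(self, gram: tuple[str, ...]) -> str:
        if len(gram) == 2:
            return self.bigram_names.get(gram, "_".join(gram))
        return self.fourgram_names.get(gram, "_".join(gram))

    def feature_names(self) -> list[str]:
        return (
            list(self.time_features)
            + list(self.unigrams)
            + [self.name_of(b) for b in self.bigrams]
            + [self.name_of(g) for g in self.fourgrams]
        )

    @property
    def size(self) -> int:
        return len(self.feature_names())

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "unigrams": list(self.unigrams),
            "bigrams": [
                {"actions": list(b), "name": self.name_of(b)} for b in self.bigrams
            ],
            "fourgrams": [
                {"actions": list(g), "name": self.name_of(g)} for g in self.fourgrams
            ],
            "time_features": list(self.time_features),
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FeatureDictionary":
        doc = yaml.safe_load(Path(path).read_text())
        bigrams = [tuple(d["actions"]) for d in doc.get("bigrams", [])]
        fourgrams = [tuple(d["actions"]) for d in doc.get("fourgrams", [])]
        return cls(
            unigrams=list(doc.get("unigrams", [])),
            bigrams=bigrams,
            fourgrams=fourgrams,
            bigram_names={
                tuple(d["actions"]): d["name"] for d in doc.get("bigrams", [])
            },
            fourgram_names={
                tuple(d["actions"]): d["name"] for d in doc.get("fourgrams", [])
            },
            time_features=tuple(doc.get("time_features", TIME_FEATURES)),
        )


def default_ticket_dictionary() -> FeatureDictionary:
    """The 36-feature dictionary for the ticket task.

    4 time-based features plus 32 action-based features: 13 unigrams,
    15 bigrams and 4 fourgrams.  The named subsequences cover the two
    solution paths (individual x 4 trips vs. the daily ticket, both city
    subway concession fares) and the comparison/cancel behaviour; the
    remaining entries are placeholders completing the families so that the
    dictionary is data, not code, and can be swapped via YAML.
    """
    unigrams = [
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
        "buy",
        "cancel",
    ]
    bigrams = {
        (START_MARKER, "city_subway"): "S_city",
        (START_MARKER, "country_trains"): "S_country",
        ("city_subway", "concession"): "city_concession",
        ("city_subway", "full_fare"): "city_full",
        ("country_trains", "concession"): "country_concession",
        ("country_trains", "full_fare"): "country_full",
        ("concession", "daily"): "concession_daily",
        ("concession", "individual"): "concession_individual",
        ("full_fare", "individual"): "full_individual",
        ("full_fare", "daily"): "full_daily",
        ("individual", "trip_4"): "individual_trip4",
        ("daily", "cancel"): "daily_cancel",
        ("daily", "buy"): "daily_buy",
        ("trip_4", "cancel"): "trip4_cancel",
        ("trip_4", "buy"): "trip4_buy",
    }
    fourgrams = {
        ("city_subway", "concession", "individual", "trip_4"): "city_con_ind_4",
        ("city_subway", "concession", "daily", "cancel"): "city_con_daily_cancel",
        ("city_subway", "concession", "daily", "buy"): "city_con_daily_buy",
        ("concession", "individual", "trip_4", "buy"): "con_ind_4_buy",
    }
    return FeatureDictionary(
        unigrams=unigrams,
        bigrams=list(bigrams),
        fourgrams=list(fourgrams),
        bigram_names=bigrams,
        fourgram_names=fourgrams,
    )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _infer_kind(name: str) -> str:
    return KIND_TIME if name in TIME_FEATURES or name.endswith("_time") else KIND_COUNT


def read_feature_matrix(
    path: str | Path, policy: str = "strict"
) -> FeatureMatrix:
    """Read a feature matrix CSV (first column = examinee id, header row).

    Column kinds are taken from a ``<path>.schema.json`` sidecar when
    present, otherwise inferred from the feature name (``*_time`` and the
    four canonical latencies are ``time_seconds``).  Rows with missing ids
    are dropped and the count logged.  Under ``policy="strict"`` any
    remaining missing or non-numeric cell is a hard error; under
    ``"permissive"`` such cells are zero-filled.
    """
    if policy not in ("strict", "permissive"):
        raise ValueError(f"unknown missing-data policy {policy!r}")
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw_header = next(csv.reader(fh))
    feature_names = raw_header[1:]
    if len(set(feature_names)) != len(feature_names):
        raise ValueError("duplicate feature names in header")
    frame = pd.read_csv(path, dtype={0: str})

    ids = frame.iloc[:, 0]
    bad = ids.isna() | (ids.astype(str).str.strip() == "")
    if bad.any():
        logger.warning("dropping %d rows with missing examinee ids", int(bad.sum()))
        frame = frame.loc[~bad]
    values = frame.iloc[:, 1:].apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        if policy == "strict":
            raise ValueError("missing or non-numeric cells under strict policy")
        values = values.fillna(0.0)

    sidecar = path.with_suffix(path.suffix + ".schema.json")
    if sidecar.exists():
        kinds_map = json.loads(sidecar.read_text())
        col_kind = [kinds_map.get(c, _infer_kind(c)) for c in feature_names]
    else:
        col_kind = [_infer_kind(c) for c in feature_names]

    return FeatureMatrix(
        values=values.to_numpy(dtype=float),
        row_ids=frame.iloc[:, 0].astype(str).tolist(),
        col_ids=feature_names,
        col_kind=col_kind,
    )


def read_event_logs(path: str | Path) -> list[EventLog]:
    """Read event logs from a CSV with columns examinee_id,event_label,timestamp.

    Rows may interleave examinees; each examinee's events are gathered in
    file order (which doubles as the stable tie order).  A negative
    timestamp, or timestamps that decrease within an examinee, raise an
    error naming the examinee.
    """
    frame = pd.read_csv(path, dtype={"examinee_id": str})
    required = {"examinee_id", "event_label", "timestamp"}
    if not required.issubset(frame.columns):
        raise ValueError(f"log CSV must contain columns {sorted(required)}")
    logs = []
    for ex_id, grp in frame.groupby("examinee_id", sort=False):
        events = list(zip(grp["event_label"].astype(str), grp["timestamp"].astype(float)))
        logs.append(EventLog(examinee_id=str(ex_id), events=events))
    return logs


def write_event_logs(logs: Sequence[EventLog], path: str | Path) -> None:
    rows = [
        (log.examinee_id, lab, t) for log in logs for lab, t in log.events
    ]
    pd.DataFrame(rows, columns=["examinee_id", "event_label", "timestamp"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------


def _ngram_counts(labels: Sequence[str], grams: Sequence[tuple[str, ...]]) -> list[int]:
    counts = []
    for gram in grams:
        k = len(gram)
        c = sum(
            1
            for i in range(len(labels) - k + 1)
            if tuple(labels[i : i + k]) == gram
        )
        counts.append(c)
    return counts


def time_summary(log: EventLog) -> tuple[float, float, float, float]:
    """(T, S, A, E) latencies of a log.

    T = total item time (end minus start); S = latency from start to the
    first interior action; A = span from first to last interior action;
    E = tail from last interior action to end.  With no interior action
    S = A = 0 and E = T; by construction S + A + E = T.
    """
    t_start = log.events[0][1]
    t_end = log.events[-1][1]
    total = t_end - t_start
    interior = [t for _, t in log.events[1:-1]]
    if not interior:
        return total, 0.0, 0.0, total
    s = interior[0] - t_start
    a = interior[-1] - interior[0]
    e = t_end - interior[-1]
    return total, s, a, e


def extract_features(
    logs: Sequence[EventLog],
    dictionary: FeatureDictionary | None = None,
) -> FeatureMatrix:
    """Build the examinee x feature matrix from event logs.

    Counts are over the full label sequence including the start/end markers
    (so marker-anchored bigrams like ``S_city`` are countable); n-gram
    windows are strictly adjacent and overlapping.  Dictionary labels
    outside the task alphabet produce a warning but the (all-zero) column
    is still emitted.
    """
    if dictionary is None:
        dictionary = default_ticket_dictionary()
    if not logs:
        raise ValueError("no event logs supplied")
    alphabet = set(TICKET_ALPHABET)
    mentioned = set(dictionary.unigrams)
    for gram in list(dictionary.bigrams) + list(dictionary.fourgrams):
        mentioned.update(gram)
    unknown = sorted(mentioned - alphabet)
    if unknown:
        logger.warning(
            "dictionary labels outside the task alphabet (columns will be zero): %s",
            unknown,
        )

    rows = []
    for log in logs:
        labels = log.labels
        t, s, a, e = time_summary(log)
        row = [t, s, a, e]
        row += _ngram_counts(labels, [(u,) for u in dictionary.unigrams])
        row += _ngram_counts(labels, dictionary.bigrams)
        row += _ngram_counts(labels, dictionary.fourgrams)
        rows.append(row)

    names = dictionary.feature_names()
    n_time = len(dictionary.time_features)
    col_kind = [KIND_TIME] * n_time + [KIND_COUNT] * (len(names) - n_time)
    return FeatureMatrix(
        values=np.asarray(rows, dtype=float),
        row_ids=[log.examinee_id for log in logs],
        col_ids=names,
        col_kind=col_kind,
    )


# ---------------------------------------------------------------------------
# Rubric scorer
# ---------------------------------------------------------------------------

_NETWORKS = {"city_subway", "country_trains"}
_FARES = {"concession", "full_fare"}
_TYPES = {"daily", "individual"}
_TRIPS = {"trip_1", "trip_2", "trip_3", "trip_4", "trip_5"}


@dataclass
class RubricResult:
    score: int
    purchased: dict | None
    compared: bool
    flagged: bool  # daily bought after seeing individual prices (credited 1)


def _purchase_state(labels: Sequence[str], buy_pos: int) -> dict:
    """Most recent selection in each slot before the buy press."""
    state: dict[str, str | None] = {
        "network": None,
        "fare": None,
        "type": None,
        "trips": None,
    }
    for lab in labels[:buy_pos]:
        if lab in _NETWORKS:
            state["network"] = lab
        elif lab in _FARES:
            state["fare"] = lab
        elif lab in _TYPES:
            state["type"] = lab
        elif lab in _TRIPS:
            state["trips"] = lab
    return state


def score_ticket_response(log: EventLog, detail: bool = False):
    """Score a ticket-task log polytomously (0/1/2).

    Full credit (2): the final purchase is four individual city-subway
    concession trips and the daily-concession price screen was opened
    before buying (the price comparison).  Partial credit (1): a
    correct-type concession ticket (individual x4 or daily, city subway)
    bought without opening the alternative's price screen; buying the
    daily ticket after comparing is also credited 1 but flagged, since the
    cheaper option was seen and not taken.  Anything else scores 0.
    """
    labels = log.labels
    buy_positions = [i for i, lab in enumerate(labels) if lab == "buy"]
    if not buy_positions:
        # EventLog construction guarantees the end marker; a log with no
        # purchase at all is an explicit non-completion scoring 0.
        result = RubricResult(score=0, purchased=None, compared=False, flagged=False)
        return result if detail else result.score
    buy = buy_positions[-1]
    state = _purchase_state(labels, buy)
    seen = set(labels[:buy])
    compared = "daily" in seen and "individual" in seen

    correct_base = state["network"] == "city_subway" and state["fare"] == "concession"
    score = 0
    flagged = False
    if correct_base and state["type"] == "individual" and state["trips"] == "trip_4":
        score = 2 if "daily" in seen else 1
    elif correct_base and state["type"] == "daily":
        if "individual" in seen:
            score, flagged = 1, True
        else:
            score = 1
    result = RubricResult(score=score, purchased=state, compared=compared, flagged=flagged)
    return result if detail else result.score


def score_cohort(logs: Sequence[EventLog]) -> ScoreVector:
    return ScoreVector(
        ids=[log.examinee_id for log in logs],
        scores=np.asarray([score_ticket_response(log) for log in logs]),
    )
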