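"""Treatment-log data model and event-log I/O.

A treatment log is a set of *treatment processes* (one per patient stay),
each a time-ordered sequence of *treatment days*; a treatment day is the
non-empty bag of *treatment activities* (orders, drugs, tests, nursing
grades) recorded on one hospital day.  The day index within the stay
(1-based, admission day = 1) is the day's *timestamp* and is shared by all
of that day's activity tokens.

The canonical on-disk format is UTF-8 delimited text with a header row and
columns ``patient_id``, ``day``, ``activity`` (comma or tab separated; a
JSON-lines dialect with the same fields is also accepted).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ActivityVocabulary",
    "TreatmentDay",
    "TreatmentProcess",
    "Corpus",
    "CorpusError",
    "SchemaError",
    "EventLogParseError",
    "EmptyLogError",
    "read_event_log",
    "write_event_log",
    "validate_corpus",
]


class CorpusError(ValueError):
    """Base class for treatment-log errors."""


class SchemaError(CorpusError):
    """A required column is missing or the schema config is invalid."""


class EventLogParseError(CorpusError):
    """A row failed to parse (e.g. non-positive or non-integer timestamp)."""


class EmptyLogError(CorpusError):
    """The event log contains no rows / the corpus no processes."""


@dataclass(frozen=True)
class ActivityVocabulary:
    """Dense 0-based mapping between activity codes and integer ids.

    Insertion order is deterministic: first-seen order when built from a
    stream, explicit order when constructed from a code list.
    """

    codes: tuple[str, ...]
    _index: Mapping[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        index = {c: i for i, c in enumerate(self.codes)}
        if len(index) != len(self.codes):
            raise CorpusError("duplicate activity codes in vocabulary")
        object.__setattr__(self, "_index", index)

    def __len__(self) -> int:
        return len(self.codes)

    def __contains__(self, code: str) -> bool:
        return code in self._index

    def id(self, code: str) -> int:
        return self._index[code]

    def code(self, activity_id: int) -> str:
        return self.codes[activity_id]


@dataclass(frozen=True)
class TreatmentDay:
    """One hospital day of one patient: a non-empty bag of activity ids.

    ``timestamp`` is the 1-based day index within the stay.  Repeated
    identical activities on the same day are kept as separate tokens
    (bag-of-activities semantics, mirroring bag-of-words LDA).
    """

    patient_id: str
    timestamp: int
    tokens: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.timestamp < 1:
            raise CorpusError(
                f"day timestamp must be >= 1, got {self.timestamp} "
                f"(patient {self.patient_id!r})"
            )
        if len(self.tokens) == 0:
            raise CorpusError(
                f"treatment day must be non-empty "
                f"(patient {self.patient_id!r}, day {self.timestamp})"
            )

    @property
    def n_tokens(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class TreatmentProcess:
    """The full stay of one patient: a non-empty, time-ordered day sequence."""

    patient_id: str
    days: tuple[TreatmentDay, ...]

    def __post_init__(self) -> None:
        if len(self.days) == 0:
            raise CorpusError(f"process {self.patient_id!r} has no days")
        for day in self.days:
            if day.patient_id != self.patient_id:
                raise CorpusError(
                    f"day patient {day.patient_id!r} != process patient "
                    f"{self.patient_id!r}"
                )
        ts = [d.timestamp for d in self.days]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise CorpusError(
                f"days of process {self.patient_id!r} not sorted by timestamp"
            )

    @property
    def length_of_stay(self) -> int:
        """LOS in days = the largest day index of the stay."""
        return self.days[-1].timestamp


@dataclass(frozen=True)
class Corpus:
    """A full treatment log: processes, shared vocabulary, timestamp universe.

    ``n_timestamps`` (|T|) defaults to the maximum observed timestamp; it may
    be configured larger (never smaller than observed).
    """

    processes: tuple[TreatmentProcess, ...]
    vocabulary: ActivityVocabulary
    n_timestamps: int = 0  # 0 -> inferred as max observed timestamp

    def __post_init__(self) -> None:
        if len(self.processes) == 0:
            raise EmptyLogError("corpus has no treatment processes")
        max_ts = max(d.timestamp for p in self.processes for d in p.days)
        if self.n_timestamps == 0:
            object.__setattr__(self, "n_timestamps", max_ts)
        elif self.n_timestamps < max_ts:
            raise CorpusError(
                f"n_timestamps={self.n_timestamps} < max observed timestamp {max_ts}"
            )

    @property
    def days(self) -> tuple[TreatmentDay, ...]:
        """Flat view of all treatment days across processes (the set D)."""
        return tuple(d for p in self.processes for d in p.days)

    @property
    def n_days(self) -> int:
        return sum(len(p.days) for p in self.processes)

    @property
    def n_tokens(self) -> int:
        return sum(d.n_tokens for p in self.processes for d in p.days)

    @property
    def n_activities(self) -> int:
        return len(self.vocabulary)

    @property
    def mean_length_of_stay(self) -> float:
        return sum(p.length_of_stay for p in self.processes) / len(self.processes)


_DEFAULT_COLUMNS = {"patient_id": "patient_id", "day": "day", "activity": "activity"}


def _read_table(source, delimiter: str | None, jsonl: bool) -> pd.DataFrame:
    if jsonl:
        return pd.read_json(source, lines=True, dtype=False)
    # sep=None triggers python-engine sniffing (handles comma and tab)
    return pd.read_csv(
        source,
        sep=delimiter,
        engine="python" if delimiter is None else "c",
        dtype=str,
        skipinitialspace=True,
    )


def read_event_log(
    source,
    *,
    columns: Mapping[str, str] | None = None,
    delimiter: str | None = None,
    jsonl: bool = False,
    n_timestamps: int | None = None,
    max_timestamp: int | None = None,
    strict_order: bool = False,
) -> Corpus:
    """Read a delimited-text (or JSON-lines) event log into a :class:`Corpus`.

    Parameters
    ----------
    source:
        Path or readable text stream.
    columns:
        Optional renaming of the logical columns ``patient_id``, ``day``,
        ``activity`` to the names used in the file.
    delimiter:
        Field delimiter; auto-detected (comma/tab) when ``None``.
    jsonl:
        Parse the source as JSON lines with the same logical fields.
    n_timestamps:
        Override for |T| (must be >= the maximum observed timestamp).
    max_timestamp:
        Optional cap: timestamps above the cap are bucketed into the cap
        (long-stay tail control).  Default: no cap.
    strict_order:
        If True, reject patients whose days appear out of timestamp order
        instead of sorting them.

    Returns
    -------
    Corpus
        One :class:`TreatmentDay` per distinct (patient, timestamp) pair,
        tokens in row order within a day, vocabulary in first-seen order.
    """
    if isinstance(source, (str, Path)) and not jsonl:
        jsonl = str(source).endswith((".jsonl", ".ndjson"))
    colmap = dict(_DEFAULT_COLUMNS)
    if columns:
        unknown = set(columns) - set(colmap)
        if unknown:
            raise SchemaError(f"unknown logical column(s): {sorted(unknown)}")
        colmap.update(columns)

    try:
        df = _read_table(source, delimiter, jsonl)
    except pd.errors.EmptyDataError as exc:
        raise EmptyLogError("event log has no rows") from exc

    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise SchemaError(
            f"missing column(s) {missing}; found {list(df.columns)}"
        )
    if len(df) == 0:
        raise EmptyLogError("event log has no rows")

    pid = df[colmap["patient_id"]].astype(str)
    act = df[colmap["activity"]].astype(str)
    raw_day = df[colmap["day"]]

    day = pd.to_numeric(raw_day, errors="coerce")
    bad = day.isna() | (day % 1 != 0) | (day < 1)
    if bad.any():
        row = int(bad.idxmax())
        raise EventLogParseError(
            f"row {row}: day timestamp {raw_day.iloc[row]!r} is not a "
            "positive integer"
        )
    day = day.astype(int)
    if max_timestamp is not None:
        day = day.clip(upper=max_timestamp)

    # vocabulary in first-seen row order
    codes: list[str] = list(dict.fromkeys(act))
    vocab = ActivityVocabulary(tuple(codes))
    ids = act.map(vocab.id)

    # group rows by patient (first-seen order), then by timestamp
    days_by_patient: dict[str, dict[int, list[int]]] = {}
    order_ok: dict[str, bool] = {}
    last_ts: dict[str, int] = {}
    for p, t, a in zip(pid, day, ids):
        per = days_by_patient.setdefault(p, {})
        per.setdefault(t, []).append(a)
        if p in last_ts and t < last_ts[p]:
            order_ok[p] = False
        last_ts[p] = max(t, last_ts.get(p, t))

    if strict_order:
        bad_patients = sorted(p for p, ok in order_ok.items() if not ok)
        if bad_patients:
            raise EventLogParseError(
                f"days out of timestamp order for patient(s) {bad_patients} "
                "(strict_order=True)"
            )

    processes = tuple(
        TreatmentProcess(
            patient_id=p,
            days=tuple(
                TreatmentDay(p, t, tuple(per[t])) for t in sorted(per)
            ),
        )
        for p, per in days_by_patient.items()
    )
    return Corpus(processes, vocab, n_timestamps or 0)


def write_event_log(corpus: Corpus, sink, *, delimiter: str = ",") -> int:
    """Write a corpus in the canonical event-log format; returns row count.

    One row per activity token, in (process, day, token position) order, so
    ``read_event_log(write_event_log(c)) == c``.
    """
    n = 0
    close = False
    if isinstance(sink, (str, Path)):
        sink = open(sink, "w", encoding="utf-8", newline="")
        close = True
    try:
        sink.write(delimiter.join(("patient_id", "day", "activity")) + "\n")
        for proc in corpus.processes:
            for day in proc.days:
                for tok in day.tokens:
                    sink.write(
                        delimiter.join(
                            (proc.patient_id, str(day.timestamp),
                             corpus.vocabulary.code(tok))
                        )
                        + "\n"
                    )
                    n += 1
    finally:
        if close:
            sink.close()
    return n


def validate_corpus(corpus: Corpus) -> list[str]:
    """Check every corpus invariant; return human-readable violations.

    Violations are data, not exceptions: an empty list means the corpus is
    valid.  (Construction already rejects most malformed inputs; this guards
    corpora assembled or mutated by hand.)
    """
    violations: list[str] = []
    n_act = len(corpus.vocabulary)
    max_ts = 0
    for proc in corpus.processes:
        prev_ts = 0
        for day in proc.days:
            where = f"patient {proc.patient_id!r} day {day.timestamp}"
            if day.patient_id != proc.patient_id:
                violations.append(f"{where}: patient_id mismatch with process")
            if len(day.tokens) == 0:
                violations.append(f"{where}: empty treatment day (days must be non-empty)")
            if day.timestamp < 1:
                violations.append(f"{where}: timestamp < 1")
            if day.timestamp < prev_ts:
                violations.append(f"{where}: days out of timestamp order")
            prev_ts = day.timestamp
            max_ts = max(max_ts, day.timestamp)
            for tok in day.tokens:
                if not (0 <= tok < n_act):
                    violations.append(
                        f"{where}: token id {tok} outside vocabulary of size {n_act}"
                    )
    if corpus.n_timestamps < max_ts:
        violations.append(
            f"n_timestamps={corpus.n_timestamps} < max observed timestamp {max_ts}"
        )
    return violations


def corpus_from_token_lists(
    token_lists: Sequence[Sequence[Sequence[int]]],
    n_activities: int,
    *,
    timestamps: Sequence[Sequence[int]] | None = None,
    n_timestamps: int | None = None,
    codes: Sequence[str] | None = None,
) -> Corpus:
    """Build a corpus directly from nested token-id lists (test/sim helper).

    ``token_lists[p][d]`` are the token ids of day ``d`` of process ``p``;
    timestamps default to 1..len(days) per process.
    """
    if codes is None:
        codes = [f"A{i}" for i in range(n_activities)]
    vocab = ActivityVocabulary(tuple(codes))
    processes = []
    for p, days in enumerate(token_lists):
        pid = f"p{p}"
        ts = timestamps[p] if timestamps is not None else range(1, len(days) + 1)
        processes.append(
            TreatmentProcess(
                pid,
                tuple(
                    TreatmentDay(pid, int(t), tuple(int(a) for a in d))
                    for t, d in zip(ts, days)
                ),
            )
        )
    return Corpus(tuple(processes), vocab, n_timestamps or 0)
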