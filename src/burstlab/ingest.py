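"""Reading raw event records and turning them into clean per-user event streams.

Two input dialects are supported: bare timestamp lists (one Unix time per
line, ``#`` comment lines skipped) and delimited edit-log tables (editor id,
timestamp, optional page id and bot flag, columns resolved through an
:class:`EditLogDialect`). Unidentified accounts (textual IP addresses) and
bots are filtered out before analysis, since only logged-in editors can be
attributed unambiguously to a single person.

Timestamps are treated as server/UTC time throughout; no per-user time-zone
correction is attempted because editor time zones are unknown. Exact
duplicate timestamps within one user are collapsed to a single event — two
saves cannot be distinguished at one-second resolution — which guarantees
strictly positive inter-event times downstream.
"""

from __future__ import annotations

import ipaddress
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    ConsistencyError,
    EmptyInputError,
    FormatError,
)

logger = logging.getLogger(__name__)

SOURCE_TIMESTAMP_LIST = "timestamp-list"
SOURCE_WIKIPEDIA_LOG = "wikipedia-log"
SOURCE_SYNTHETIC = "synthetic"


@dataclass(frozen=True)
class EventRecord:
    """One edit-log row: who saved what, when."""

    editor_id: str
    timestamp: int
    page_id: str | None = None
    is_bot: bool | None = None


@dataclass(frozen=True)
class EventStream:
    """One user's event timestamps, strictly increasing, in epoch seconds.

    ``dataset_end`` is the last day of the surrounding corpus (needed for
    activity-span normalization), not the user's last event.
    """

    user_id: str
    times: np.ndarray
    source: str = SOURCE_TIMESTAMP_LIST
    dataset_end: int | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=np.int64)
        object.__setattr__(self, "times", times)
        if times.size and np.any(np.diff(times) <= 0):
            raise ConsistencyError(
                f"stream {self.user_id!r}: timestamps must be strictly increasing"
            )
        if self.dataset_end is not None and times.size and times[-1] > self.dataset_end:
            raise ConsistencyError(
                f"stream {self.user_id!r}: events after declared dataset end"
            )

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class EditLogDialect:
    """Column mapping and CSV options for a delimited edit-log table."""

    editor_col: str
    time_col: str
    page_col: str | None = None
    bot_col: str | None = None
    sep: str = "\t"
    comment: str | None = "#"


@dataclass
class FilterCounts:
    """Per-category removal counts from :func:`filter_identified_editors`."""

    ip: int = 0
    bot_list: int = 0
    bot_suffix: int = 0
    bot_flag: int = 0
    kept: int = 0

    @property
    def removed(self) -> int:
        return self.ip + self.bot_list + self.bot_suffix + self.bot_flag


def _dedupe_sorted(times: np.ndarray) -> tuple[np.ndarray, int]:
    uniq = np.unique(times)
    return uniq, int(times.size - uniq.size)


def read_timestamp_list(
    path: str | Path,
    user_id: str,
    source: str = SOURCE_TIMESTAMP_LIST,
    dataset_end: int | None = None,
) -> EventStream:
    """Read a bare timestamp list (one Unix time per line) into an EventStream.

    Lines starting with ``#`` and blank lines are skipped. Out-of-order
    timestamps are sorted; exact duplicates are collapsed (count logged).
    """
    path = Path(path)
    values: list[float] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            try:
                values.append(float(text))
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: {text!r} is not a Unix timestamp"
                ) from None
    if not values:
        raise EmptyInputError(f"{path}: no timestamps found")
    times = np.sort(np.asarray(values, dtype=float)).round().astype(np.int64)
    times, n_dup = _dedupe_sorted(times)
    if n_dup:
        logger.info("%s: collapsed %d duplicate timestamps for %s", path, n_dup, user_id)
    return EventStream(user_id=user_id, times=times, source=source, dataset_end=dataset_end)


def read_edit_log(path: str | Path, dialect: EditLogDialect) -> list[EventRecord]:
    """Read a delimited edit-log table into EventRecords.

    Rows with a missing editor id or timestamp are dropped (count logged).
    A timestamp that does not parse as a number (e.g. ISO-8601 text when the
    dialect declares epoch seconds) raises :class:`FormatError`.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep=dialect.sep, comment=dialect.comment, dtype=str,
        skip_blank_lines=True,
    )
    for col in (dialect.editor_col, dialect.time_col):
        if col not in df.columns:
            raise ConfigurationError(f"{path}: required column {col!r} not found")
    for col in (dialect.page_col, dialect.bot_col):
        if col is not None and col not in df.columns:
            raise ConfigurationError(f"{path}: configured column {col!r} not found")

    editor = df[dialect.editor_col].str.strip()
    raw_time = df[dialect.time_col].str.strip()
    missing = editor.isna() | (editor == "") | raw_time.isna() | (raw_time == "")
    n_dropped = int(missing.sum())
    if n_dropped:
        logger.info("%s: dropped %d rows with missing editor id or timestamp", path, n_dropped)
    df = df[~missing]
    editor = editor[~missing]
    raw_time = raw_time[~missing]

    time_num = pd.to_numeric(raw_time, errors="coerce")
    bad = time_num.isna()
    if bad.any():
        first = raw_time[bad].index[0]
        raise FormatError(
            f"{path}: row {first}: timestamp {raw_time[bad].iloc[0]!r} "
            "is not epoch seconds (check the dialect)"
        )

    pages = df[dialect.page_col].where(df[dialect.page_col].notna(), None) if dialect.page_col else None
    bots = None
    if dialect.bot_col:
        bots = df[dialect.bot_col].str.strip().str.lower().isin({"1", "true", "yes", "bot"})

    records = []
    for i, (eid, ts) in enumerate(zip(editor.tolist(), time_num.tolist())):
        records.append(
            EventRecord(
                editor_id=eid,
                timestamp=int(round(ts)),
                page_id=None if pages is None else pages.iloc[i],
                is_bot=None if bots is None else bool(bots.iloc[i]),
            )
        )
    return records


def _is_ip(editor_id: str) -> bool:
    try:
        ipaddress.ip_address(editor_id)
        return True
    except ValueError:
        return False


def filter_identified_editors(
    records: list[EventRecord],
    bot_list: frozenset[str] | set[str] = frozenset(),
) -> tuple[list[EventRecord], FilterCounts]:
    """Drop records from IPs and bots, keeping only identified human editors.

    Removal categories (reported in :class:`FilterCounts`): textual IPv4/IPv6
    editor ids; ids in ``bot_list`` (exact match); ids with a case-insensitive
    ``bot`` suffix; records carrying an ``is_bot`` flag.
    """
    counts = FilterCounts()
    kept: list[EventRecord] = []
    bot_list = {b for b in bot_list}
    for rec in records:
        if _is_ip(rec.editor_id):
            counts.ip += 1
        elif rec.editor_id in bot_list:
            counts.bot_list += 1
        elif rec.is_bot:
            counts.bot_flag += 1
        elif rec.editor_id.lower().endswith("bot"):
            counts.bot_suffix += 1
        else:
            kept.append(rec)
    counts.kept = len(kept)
    logger.info(
        "filter_identified_editors: kept %d, removed %d (ip=%d bot_list=%d suffix=%d flag=%d)",
        counts.kept, counts.removed, counts.ip, counts.bot_list, counts.bot_suffix, counts.bot_flag,
    )
    return kept, counts


def to_streams(
    records: list[EventRecord],
    dataset_end: int,
    source: str = SOURCE_WIKIPEDIA_LOG,
) -> list[EventStream]:
    """Group records by editor into sorted, deduplicated EventStreams.

    Streams are returned in deterministic order (ascending ``user_id``).
    """
    if records:
        latest = max(r.timestamp for r in records)
        if dataset_end < latest:
            raise ConsistencyError(
                f"dataset_end {dataset_end} precedes latest record timestamp {latest}"
            )
    by_user: dict[str, list[int]] = {}
    for rec in records:
        by_user.setdefault(rec.editor_id, []).append(rec.timestamp)
    streams = []
    for user_id in sorted(by_user):
        times = np.sort(np.asarray(by_user[user_id], dtype=np.int64))
        times, n_dup = _dedupe_sorted(times)
        if n_dup:
            logger.info("collapsed %d duplicate timestamps for %s", n_dup, user_id)
        streams.append(
            EventStream(user_id=user_id, times=times, source=source, dataset_end=dataset_end)
        )
    return streams


def write_timestamp_list(stream: EventStream, path: str | Path) -> None:
    """Write a stream in the bare one-Unix-time-per-line format."""
    path = Path(path)
    with path.open("w") as fh:
        for t in stream.times:
            fh.write(f"{int(t)}\n")
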