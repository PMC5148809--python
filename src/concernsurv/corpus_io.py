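"""Reading and writing the tweet-log and dose-series CSV dialects.

Both dialects are plain RFC-4180 CSV.  The tweet log has one row per tweet
with columns ``tweet_id, user_id, username, created_at, text, is_retweet``
(extra columns are tolerated and ignored; real exports carry hundreds).  The
dose-series file has columns ``post_id, timestamp, dose`` with one row per
10-minute tick per monitoring post.

All timestamps are normalized to Japan Standard Time (UTC+9) on read, since
every downstream hourly or calendar-day aggregation is meant in local time.
Readers stream in chunks so multi-gigabyte logs never have to fit in memory.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Japan Standard Time; the corpus and all derived aggregations live in it.
JST = timezone(timedelta(hours=9), name="JST")

#: Required tweet-log columns (canonical names).
TWEET_COLUMNS = ("tweet_id", "user_id", "username", "created_at", "text", "is_retweet")

SECONDS_PER_DAY = 86_400.0


class SchemaError(ValueError):
    """A required column is missing from an input file."""


class CorruptInputError(ValueError):
    """Too many malformed rows, or an invariant of the dialect is violated."""


@dataclass(frozen=True)
class TweetRecord:
    """One tweet: identifier, author, JST timestamp, text and retweet flag."""

    tweet_id: str
    user_id: str
    username: str | None
    timestamp: datetime
    text: str
    is_retweet: bool


@dataclass(frozen=True)
class StudyWindow:
    """Half-open observation window [start, end) in JST.

    The default window runs from 2011-03-11 00:00 JST to 2012-03-10 24:00 JST,
    i.e. 366 whole calendar days.
    """

    start: datetime = field(
        default_factory=lambda: datetime(2011, 3, 11, 0, 0, 0, tzinfo=JST)
    )
    end: datetime = field(
        default_factory=lambda: datetime(2012, 3, 11, 0, 0, 0, tzinfo=JST)
    )

    def __post_init__(self) -> None:
        if self.start.tzinfo is None or self.end.tzinfo is None:
            raise ValueError("StudyWindow datetimes must be timezone-aware")
        if self.end <= self.start:
            raise ValueError("StudyWindow: end must be after start")

    @property
    def n_days(self) -> int:
        """Whole calendar days spanned by the window (366 for the default)."""
        return int(round((self.end - self.start).total_seconds() / SECONDS_PER_DAY))

    @property
    def length_days(self) -> float:
        """Window length in (possibly fractional) days."""
        return (self.end - self.start).total_seconds() / SECONDS_PER_DAY

    def contains(self, ts: datetime) -> bool:
        return self.start <= ts < self.end

    def days_from_start(self, ts: datetime) -> float:
        return (ts - self.start).total_seconds() / SECONDS_PER_DAY


@dataclass
class DoseSeries:
    """Air-dose-rate series for one monitoring post.

    ``ticks`` is a pandas Series of dose rate (µSv/h, nonnegative) indexed by
    strictly increasing JST timestamps at a nominal 10-minute cadence.
    """

    post_id: str
    ticks: pd.Series

    def __post_init__(self) -> None:
        idx = pd.DatetimeIndex(self.ticks.index)
        if idx.tz is None:
            idx = idx.tz_localize(JST)
        else:
            idx = idx.tz_convert(JST)
        idx.name = None
        self.ticks = pd.Series(
            np.asarray(self.ticks, dtype=float), index=idx
        ).sort_index()
        if self.ticks.index.has_duplicates:
            raise CorruptInputError(
                f"DoseSeries {self.post_id}: duplicate timestamps"
            )
        if (self.ticks < 0).any():
            raise CorruptInputError(f"DoseSeries {self.post_id}: negative dose")

    def __len__(self) -> int:
        return len(self.ticks)


# ---------------------------------------------------------------------------
# Tweet log
# ---------------------------------------------------------------------------

_TRUE_TOKENS = {"true", "1", "t", "yes"}
_FALSE_TOKENS = {"false", "0", "f", "no", ""}


def _parse_bool(col: pd.Series) -> pd.Series:
    low = col.astype("string").str.strip().str.lower()
    out = pd.Series(pd.NA, index=col.index, dtype="boolean")
    out[low.isin(_TRUE_TOKENS)] = True
    out[low.isin(_FALSE_TOKENS)] = False
    return out


def read_tweet_frames(
    path: str | Path,
    window: StudyWindow | None = None,
    chunk_size: int = 100_000,
    max_error_rate: float = 0.01,
    column_map: Mapping[str, str] | None = None,
) -> Iterator[pd.DataFrame]:
    """Stream the tweet log as validated DataFrame chunks.

    Each yielded frame has the canonical columns of :data:`TWEET_COLUMNS` with
    ``created_at`` parsed to tz-aware JST datetimes and ``is_retweet`` boolean.
    Malformed rows (unparseable timestamp or retweet flag, missing tweet/user
    id) are dropped and counted; once the whole file has been read, an overall
    malformed-row rate above ``max_error_rate`` raises
    :class:`CorruptInputError`.  ``window`` is carried for downstream use only;
    no row is filtered by it here.

    ``column_map`` maps canonical names to the file's actual header names for
    corpora with a different schema.
    """
    path = Path(path)
    colmap = dict(column_map or {})
    rename = {colmap.get(c, c): c for c in TWEET_COLUMNS}

    n_bad = 0
    n_total = 0
    with pd.read_csv(
        path,
        dtype=str,
        chunksize=chunk_size,
        keep_default_na=False,
        na_values=[],
    ) as reader:
        for i, chunk in enumerate(reader):
            if i == 0:
                missing = [
                    c for c in TWEET_COLUMNS if colmap.get(c, c) not in chunk.columns
                ]
                if missing:
                    raise SchemaError(
                        f"{path}: missing required column(s) {missing}"
                    )
            chunk = chunk.rename(columns=rename)[list(TWEET_COLUMNS)]
            n_total += len(chunk)

            ts = pd.to_datetime(chunk["created_at"], errors="coerce", utc=True)
            rt = _parse_bool(chunk["is_retweet"])
            ok = (
                ts.notna()
                & rt.notna()
                & (chunk["tweet_id"].str.len() > 0)
                & (chunk["user_id"].str.len() > 0)
            )
            n_bad += int((~ok).sum())

            frame = chunk.loc[ok].copy()
            frame["created_at"] = ts[ok].dt.tz_convert(JST)
            frame["is_retweet"] = rt[ok].astype(bool)
            frame["username"] = frame["username"].where(
                frame["username"].str.len() > 0, None
            )
            yield frame

    if n_bad:
        logger.info("read_tweet_frames(%s): dropped %d malformed rows", path, n_bad)
    if n_total and n_bad / n_total > max_error_rate:
        raise CorruptInputError(
            f"{path}: {n_bad}/{n_total} malformed rows exceeds "
            f"max_error_rate={max_error_rate}"
        )


def read_tweets(
    path: str | Path,
    window: StudyWindow | None = None,
    chunk_size: int = 100_000,
    max_error_rate: float = 0.01,
    column_map: Mapping[str, str] | None = None,
) -> Iterator[TweetRecord]:
    """Stream the tweet log record by record (see :func:`read_tweet_frames`)."""
    for frame in read_tweet_frames(
        path, window, chunk_size, max_error_rate, column_map
    ):
        for row in frame.itertuples(index=False):
            yield TweetRecord(
                tweet_id=row.tweet_id,
                user_id=row.user_id,
                username=row.username,
                timestamp=row.created_at.to_pydatetime(),
                text=row.text,
                is_retweet=row.is_retweet,
            )


TweetStream = Union[
    pd.DataFrame, Iterable[TweetRecord], Iterable[pd.DataFrame]
]


def as_tweet_frames(stream: TweetStream, batch: int = 100_000) -> Iterator[pd.DataFrame]:
    """Normalize any accepted tweet stream into canonical DataFrame chunks.

    Accepts a single DataFrame, an iterable of DataFrames (as produced by
    :func:`read_tweet_frames`) or an iterable of :class:`TweetRecord`.
    """
    if isinstance(stream, pd.DataFrame):
        if len(stream):
            yield stream
        return
    it = iter(stream)
    try:
        first = next(it)
    except StopIteration:
        return
    if isinstance(first, pd.DataFrame):
        if len(first):
            yield first
        for frame in it:
            if len(frame):
                yield frame
        return

    def records():
        yield first
        yield from it

    buf: list[TweetRecord] = []
    for rec in records():
        buf.append(rec)
        if len(buf) >= batch:
            yield _records_to_frame(buf)
            buf = []
    if buf:
        yield _records_to_frame(buf)


def _records_to_frame(records: list[TweetRecord]) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "tweet_id": [r.tweet_id for r in records],
            "user_id": [r.user_id for r in records],
            "username": [r.username for r in records],
            "created_at": pd.DatetimeIndex(
                [r.timestamp for r in records]
            ).tz_convert(JST),
            "text": [r.text for r in records],
            "is_retweet": [r.is_retweet for r in records],
        }
    )
    return frame


def write_tweets(stream: TweetStream, path: str | Path) -> int:
    """Write a tweet stream to CSV; returns the number of data rows written.

    Timestamps are formatted ISO-8601 with the +09:00 offset, so a write/read
    cycle is lossless and a second cycle is byte-identical.
    """
    path = Path(path)
    n = 0
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(TWEET_COLUMNS)
        for frame in as_tweet_frames(stream):
            out = frame.copy()
            out["created_at"] = out["created_at"].dt.strftime("%Y-%m-%dT%H:%M:%S.%f%z")
            # strftime %z has no colon; insert it for ISO-8601
            out["created_at"] = out["created_at"].str[:-2] + ":" + out["created_at"].str[-2:]
            out["is_retweet"] = np.where(out["is_retweet"], "true", "false")
            out["username"] = out["username"].fillna("")
            for row in out[list(TWEET_COLUMNS)].itertuples(index=False):
                writer.writerow(row)
            n += len(out)
    return n


# ---------------------------------------------------------------------------
# Dose series
# ---------------------------------------------------------------------------


def read_dose(path: str | Path) -> list[DoseSeries]:
    """Read a monitoring-post dose CSV into one :class:`DoseSeries` per post.

    Columns: ``post_id, timestamp, dose``.  Ticks are sorted per post;
    a negative dose or a duplicate timestamp within a post is fatal.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"post_id": str})
    missing = [c for c in ("post_id", "timestamp", "dose") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    ts = pd.to_datetime(df["timestamp"], errors="raise", utc=True).dt.tz_convert(JST)
    dose = pd.to_numeric(df["dose"], errors="raise")
    if (dose < 0).any():
        raise CorruptInputError(f"{path}: negative dose value")
    out = []
    for post_id, grp in df.assign(_ts=ts, _dose=dose).groupby("post_id", sort=True):
        out.append(
            DoseSeries(post_id=post_id, ticks=pd.Series(grp["_dose"].values, index=grp["_ts"]))
        )
    return out


def write_dose(series: Iterable[DoseSeries], path: str | Path) -> int:
    """Write dose series to the ``post_id, timestamp, dose`` CSV dialect."""
    path = Path(path)
    frames = []
    for s in series:
        stamps = pd.Index(s.ticks.index.strftime("%Y-%m-%dT%H:%M:%S%z"))
        frames.append(
            pd.DataFrame(
                {
                    "post_id": s.post_id,
                    "timestamp": stamps.str[:-2] + ":" + stamps.str[-2:],
                    "dose": [f"{v:.6g}" for v in s.ticks.values],
                }
            )
        )
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["post_id", "timestamp", "dose"]
    )
    out.to_csv(path, index=False)
    return len(out)
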