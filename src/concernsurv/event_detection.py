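"""Keyword matching, first-occurrence event tables, and bot flagging.

An *event* for a (user, keyword) pair is the first tweet by that user whose
text contains the keyword as a case-sensitive substring (after Unicode NFC
normalization).  Users who never post the keyword inside the study window are
censored at the window's end.  The table of per-(user, keyword) event/censor
times is the input to the survival module.

Matching is deliberately literal: the SI-prefixed unit strings "mSv" or
"µSv" must count as mentions of "Sv", so no word-boundary tokenization is
applied.  Keyword concepts are never merged; each keyword is analyzed as its
own endpoint.
"""

from __future__ import annotations

import logging
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .corpus_io import SECONDS_PER_DAY, StudyWindow, TweetStream, as_tweet_frames

logger = logging.getLogger(__name__)

#: Default detection keywords: "radiation" and "radioactive" in Japanese plus
#: the radiation units Sievert, Becquerel and Gray.
DEFAULT_KEYWORDS = ("放射線", "放射能", "Sv", "Bq", "Gy")


@dataclass(frozen=True)
class KeywordSet:
    """Ordered, duplicate-free keyword list matched as case-sensitive substrings."""

    keywords: tuple[str, ...] = DEFAULT_KEYWORDS

    def __post_init__(self) -> None:
        kws = tuple(unicodedata.normalize("NFC", k) for k in self.keywords)
        if not kws:
            raise ValueError("KeywordSet: keywords must be nonempty")
        if len(set(kws)) != len(kws):
            raise ValueError("KeywordSet: duplicate keywords")
        if any(not k for k in kws):
            raise ValueError("KeywordSet: empty keyword")
        object.__setattr__(self, "keywords", kws)

    def __iter__(self):
        return iter(self.keywords)

    def __len__(self) -> int:
        return len(self.keywords)


def match_keywords(text: str, ks: KeywordSet) -> set[str]:
    """Return the keywords occurring in ``text`` as case-sensitive substrings.

    Both text and keywords are NFC-normalized before comparison; no other
    normalization (case folding, tokenization) is applied.
    """
    norm = unicodedata.normalize("NFC", text)
    return {k for k in ks if k in norm}


@dataclass
class EventTable:
    """Per-(user, keyword) first-occurrence event/censor table.

    ``df`` columns: ``user_id, keyword, time_days, status`` with exactly one
    row per (user, keyword); ``status`` is ``"event"`` or ``"censored"`` and
    censored rows carry ``time_days`` equal to the window length.  Times are
    measured in fractional days from ``origin`` (internally computed in
    seconds and divided by 86,400).
    """

    df: pd.DataFrame
    origin: pd.Timestamp
    window_days: float
    n_ids: int
    n_dropped_outside: int = 0

    def counts(self) -> pd.DataFrame:
        """Events / censored / % censored per keyword (one row per keyword)."""
        rows = []
        for kw, grp in self.df.groupby("keyword", sort=False):
            ev = int((grp["status"] == "event").sum())
            rows.append(
                {
                    "keyword": kw,
                    "n_ids": self.n_ids,
                    "events": ev,
                    "censored": self.n_ids - ev,
                    "pct_censored": round(100.0 * (self.n_ids - ev) / self.n_ids, 2)
                    if self.n_ids
                    else float("nan"),
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        out = self.df.copy()
        out["time_days"] = out["time_days"].map(lambda v: f"{v:.6f}")
        out.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, origin, window_days: float) -> "EventTable":
        df = pd.read_csv(path, dtype={"user_id": str, "keyword": str, "status": str})
        df["time_days"] = df["time_days"].astype(float)
        n_ids = df["user_id"].nunique()
        return cls(df=df, origin=pd.Timestamp(origin), window_days=window_days, n_ids=n_ids)


@dataclass
class BotFlags:
    """Keyword-tweet counts per user with a frequency-threshold bot flag.

    ``df`` columns: ``user_id, keyword_tweet_count, flagged``; a user is
    flagged iff their count of keyword-bearing tweets over the window exceeds
    ``threshold``.  Flags are annotations only — nothing is removed.
    """

    df: pd.DataFrame
    threshold: int

    @property
    def flagged_ids(self) -> set[str]:
        return set(self.df.loc[self.df["flagged"], "user_id"])

    @property
    def flagged_fraction(self) -> float:
        return float(self.df["flagged"].mean()) if len(self.df) else 0.0

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


def _keyword_masks(text: pd.Series, ks: KeywordSet) -> dict[str, pd.Series]:
    norm = text.map(lambda s: unicodedata.normalize("NFC", s))
    return {k: norm.str.contains(k, regex=False) for k in ks}


def build_event_table(
    stream: TweetStream, ks: KeywordSet, window: StudyWindow
) -> EventTable:
    """Single-pass construction of the first-occurrence event/censor table.

    For every distinct user ID in the corpus and every keyword, the table
    holds either an event row at the earliest matching tweet (ties at equal
    timestamps broken by tweet_id) or a censored row at the window length.
    Rows with timestamps outside the window are dropped and counted.  Memory
    is proportional to (#users × #keywords), not corpus size.
    """
    origin = pd.Timestamp(window.start)
    window_days = window.length_days

    users: set[str] = set()
    n_dropped = 0
    # best[kw]: DataFrame(user_id, t_sec, tweet_id) of earliest match so far
    best: dict[str, pd.DataFrame] = {k: None for k in ks}

    for frame in as_tweet_frames(stream):
        inside = (frame["created_at"] >= window.start) & (
            frame["created_at"] < window.end
        )
        n_dropped += int((~inside).sum())
        frame = frame.loc[inside]
        if not len(frame):
            continue
        users.update(frame["user_id"])
        t_sec = (frame["created_at"] - origin).dt.total_seconds()
        masks = _keyword_masks(frame["text"], ks)
        for kw in ks:
            hits = masks[kw]
            if not hits.any():
                continue
            cand = pd.DataFrame(
                {
                    "user_id": frame.loc[hits, "user_id"],
                    "t_sec": t_sec[hits],
                    "tweet_id": frame.loc[hits, "tweet_id"],
                }
            )
            if best[kw] is not None:
                cand = pd.concat([best[kw], cand], ignore_index=True)
            cand = cand.sort_values(
                ["t_sec", "tweet_id"], kind="mergesort"
            ).drop_duplicates("user_id", keep="first")
            best[kw] = cand.reset_index(drop=True)

    if n_dropped:
        logger.info("build_event_table: dropped %d out-of-window rows", n_dropped)

    user_ids = sorted(users)
    n_ids = len(user_ids)
    pieces = []
    for kw in ks:
        events = best[kw]
        if events is None:
            events = pd.DataFrame({"user_id": [], "t_sec": []})
        ev_map = pd.Series(
            events["t_sec"].values / SECONDS_PER_DAY, index=events["user_id"].values
        )
        time_days = ev_map.reindex(user_ids)
        status = np.where(time_days.notna(), "event", "censored")
        pieces.append(
            pd.DataFrame(
                {
                    "user_id": user_ids,
                    "keyword": kw,
                    "time_days": time_days.fillna(window_days).values,
                    "status": status,
                }
            )
        )
    df = (
        pd.concat(pieces, ignore_index=True)
        if pieces
        else pd.DataFrame(columns=["user_id", "keyword", "time_days", "status"])
    )
    return EventTable(
        df=df,
        origin=origin,
        window_days=window_days,
        n_ids=n_ids,
        n_dropped_outside=n_dropped,
    )


def flag_bots(
    stream: TweetStream,
    ks: KeywordSet,
    threshold: int = 200,
    window: StudyWindow | None = None,
) -> BotFlags:
    """Count keyword-bearing tweets per user; flag users with count > threshold.

    The default threshold of 200 keyword tweets per study year marks the
    auto-posting accounts (e.g. daily radiation-report feeds) that dominate
    the first days of the survival curves.  Flags annotate; they drop nothing.
    """
    if threshold < 1:
        raise ValueError("flag_bots: threshold must be >= 1")
    counts: pd.Series | None = None
    all_users: set[str] = set()
    for frame in as_tweet_frames(stream):
        if window is not None:
            inside = (frame["created_at"] >= window.start) & (
                frame["created_at"] < window.end
            )
            frame = frame.loc[inside]
        if not len(frame):
            continue
        all_users.update(frame["user_id"])
        masks = _keyword_masks(frame["text"], ks)
        any_kw = np.logical_or.reduce([m.values for m in masks.values()])
        chunk_counts = frame.loc[any_kw].groupby("user_id").size()
        counts = chunk_counts if counts is None else counts.add(chunk_counts, fill_value=0)

    users = sorted(all_users)
    if counts is None:
        counts = pd.Series(dtype=float)
    full = counts.reindex(users).fillna(0).astype(int)
    df = pd.DataFrame(
        {
            "user_id": users,
            "keyword_tweet_count": full.values,
            "flagged": full.values > threshold,
        }
    )
    return BotFlags(df=df, threshold=threshold)


def brute_force_event_table(
    records: Sequence, ks: KeywordSet, window: StudyWindow
) -> pd.DataFrame:
    """Reference per-user scan used to cross-check :func:`build_event_table`.

    Quadratic-ish and record-at-a-time on purpose; only for small corpora.
    """
    rows = []
    recs = [
        r
        for r in records
        if window.start <= r.timestamp < window.end
    ]
    users = sorted({r.user_id for r in recs})
    for u in users:
        mine = sorted(
            (r for r in recs if r.user_id == u),
            key=lambda r: (r.timestamp, r.tweet_id),
        )
        for kw in ks:
            hit = next(
                (r for r in mine if kw in unicodedata.normalize("NFC", r.text)), None
            )
            if hit is None:
                rows.append((u, kw, window.length_days, "censored"))
            else:
                rows.append(
                    (u, kw, window.days_from_start(hit.timestamp), "event")
                )
    return pd.DataFrame(rows, columns=["user_id", "keyword", "time_days", "status"])
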