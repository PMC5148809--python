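"""Corpus descriptives, activity profiles, and dose-surrogacy SSD.

Daily tweet counts and distinct-ID counts are bucketed by JST calendar day.
Descriptives follow the SAS/JMP conventions of the reference tables: t-based
95% CI for the mean, bias-corrected sample skewness and *excess* kurtosis,
and linear interpolation between order statistics for percentiles.

"Normalized" series are z-scores; the sum of squared differences (SSD)
between the normalized daily tweet count and each monitoring post's
normalized daily dose mean ranks the posts by how well the environmental
signal tracks the social one (smaller = better fit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus_io import DoseSeries, StudyWindow, TweetStream, as_tweet_frames
from .event_detection import KeywordSet, _keyword_masks


def percentage(part: float, whole: float, ndigits: int = 2) -> float:
    """100·part/whole rounded to ``ndigits`` — the table-percentage helper."""
    if whole == 0:
        raise ValueError("percentage: whole must be nonzero")
    return round(100.0 * part / whole, ndigits)


def event_censor_percentages(n_total: int, n_events: int, ndigits: int = 2) -> tuple[float, float]:
    """(% with event, % censored) from a risk-set total and an event count."""
    if not (0 <= n_events <= n_total):
        raise ValueError("event_censor_percentages: need 0 <= n_events <= n_total")
    return (
        percentage(n_events, n_total, ndigits),
        percentage(n_total - n_events, n_total, ndigits),
    )


def t_confidence_interval(
    mean: float, sd: float, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Student-t CI for a mean from summary statistics: mean ± t·sd/√n."""
    if n < 2:
        raise ValueError("t_confidence_interval: need n >= 2")
    tcrit = stats.t.ppf(0.5 + level / 2.0, df=n - 1)
    half = tcrit * sd / math.sqrt(n)
    return (mean - half, mean + half)


def daily_counts(stream: TweetStream, window: StudyWindow) -> pd.DataFrame:
    """Per-JST-calendar-day tweet count and distinct user-ID count.

    Every day of the window appears, zero-filled; out-of-window rows are
    ignored.  Columns: ``date, n_tweets, n_users``.
    """
    days = pd.date_range(window.start, periods=window.n_days, freq="D").date
    counts = pd.Series(0, index=days, dtype=int)
    user_sets: dict = {d: set() for d in days}
    for frame in as_tweet_frames(stream):
        inside = (frame["created_at"] >= window.start) & (frame["created_at"] < window.end)
        frame = frame.loc[inside]
        if not len(frame):
            continue
        d = frame["created_at"].dt.date
        counts = counts.add(d.value_counts(), fill_value=0).astype(int)
        for day, grp in frame.groupby(d):
            user_sets[day].update(grp["user_id"])
    out = pd.DataFrame(
        {
            "date": days,
            "n_tweets": counts.reindex(days).fillna(0).astype(int).values,
            "n_users": [len(user_sets[d]) for d in days],
        }
    )
    return out


@dataclass
class DescriptiveStats:
    """Summary of a daily-count series in the layout of the reference table."""

    total: float
    n: int
    mean: float
    ci95: tuple[float, float]
    sd: float
    skewness: float
    excess_kurtosis: float
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    degenerate: bool = False
    percentile_rule: str = "linear interpolation between order statistics"

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "total": self.total,
                "mean_per_day": self.mean,
                "ci95_lower": self.ci95[0],
                "ci95_upper": self.ci95[1],
                "sd": self.sd,
                "skewness": self.skewness,
                "kurtosis_excess": self.excess_kurtosis,
                "min": self.minimum,
                "p25": self.q1,
                "median": self.median,
                "p75": self.q3,
                "max": self.maximum,
            }
        )


def descriptive_stats(values: Sequence[float]) -> DescriptiveStats:
    """SAS/JMP-convention descriptives of a daily series.

    Bias-corrected sample skewness and excess kurtosis; for a constant series
    (SD 0) they are undefined and reported as 0 with ``degenerate=True``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("descriptive_stats: need at least 2 values")
    sd = float(np.std(x, ddof=1))
    mean = float(np.mean(x))
    degenerate = sd == 0.0
    if degenerate:
        skew = kurt = 0.0
        ci = (mean, mean)
    else:
        skew = float(stats.skew(x, bias=False))
        kurt = float(stats.kurtosis(x, fisher=True, bias=False))
        ci = t_confidence_interval(mean, sd, x.size)
    q1, med, q3 = np.percentile(x, [25, 50, 75], method="linear")
    return DescriptiveStats(
        total=float(x.sum()),
        n=int(x.size),
        mean=mean,
        ci95=ci,
        sd=sd,
        skewness=skew,
        excess_kurtosis=kurt,
        minimum=float(x.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        maximum=float(x.max()),
        degenerate=degenerate,
    )


def per_id_percentiles(stream: TweetStream) -> pd.Series:
    """Percentiles of tweets per distinct user ID (heavy-tail summary).

    Index: max, p99, p95, p90, p75, median, p25, p10, p5, p1, min.  Linear
    interpolation between order statistics.
    """
    counts: pd.Series | None = None
    for frame in as_tweet_frames(stream):
        c = frame.groupby("user_id").size()
        counts = c if counts is None else counts.add(c, fill_value=0)
    if counts is None or not len(counts):
        raise ValueError("per_id_percentiles: empty corpus")
    x = counts.to_numpy(dtype=float)
    qs = [100, 99, 95, 90, 75, 50, 25, 10, 5, 1, 0]
    vals = np.percentile(x, qs, method="linear")
    return pd.Series(
        vals,
        index=["max", "p99", "p95", "p90", "p75", "median", "p25", "p10", "p5", "p1", "min"],
        name="tweets_per_id",
    )


def hourly_weekday_profile(stream: TweetStream) -> pd.DataFrame:
    """7×24 matrix of mean tweets per hour for each weekday (JST).

    Cell (w, h) is the mean, over all distinct calendar dates of weekday w in
    the data, of the tweet count in hour h.  Rows Monday..Sunday.
    """
    cells: pd.Series | None = None
    dates_per_weekday: dict[int, set] = {w: set() for w in range(7)}
    for frame in as_tweet_frames(stream):
        if not len(frame):
            continue
        dt = frame["created_at"].dt
        key = pd.MultiIndex.from_arrays([dt.weekday, dt.hour])
        c = pd.Series(1, index=key).groupby(level=[0, 1]).sum()
        cells = c if cells is None else cells.add(c, fill_value=0)
        for w, d in zip(dt.weekday, dt.date):
            dates_per_weekday[w].add(d)
    if cells is None:
        raise ValueError("hourly_weekday_profile: empty corpus")
    mat = np.zeros((7, 24))
    for (w, h), v in cells.items():
        n_dates = max(len(dates_per_weekday[w]), 1)
        mat[int(w), int(h)] = v / n_dates
    return pd.DataFrame(
        mat,
        index=["Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun"],
        columns=range(24),
    )


def keyword_proportion_profile(
    stream: TweetStream,
    ks: KeywordSet,
    by: Sequence[str] = ("month", "weekday", "hour"),
) -> pd.DataFrame:
    """Proportion of keyword-bearing tweets per (month, weekday, hour) cell.

    One column per keyword plus ``any_keyword`` and ``n_tweets``; cells with
    no tweets are absent (undefined proportion).  ``by`` may be any subset of
    {"month", "weekday", "hour"}.
    """
    allowed = {"month", "weekday", "hour"}
    if not by or not set(by) <= allowed:
        raise ValueError(f"keyword_proportion_profile: by must be a subset of {allowed}")
    num: pd.DataFrame | None = None
    for frame in as_tweet_frames(stream):
        if not len(frame):
            continue
        dt = frame["created_at"].dt
        keys = {"month": dt.month, "weekday": dt.weekday, "hour": dt.hour}
        masks = _keyword_masks(frame["text"], ks)
        df = pd.DataFrame({b: keys[b].values for b in by})
        for kw in ks:
            df[kw] = masks[kw].values
        df["any_keyword"] = np.logical_or.reduce([masks[k].values for k in ks])
        df["n_tweets"] = 1
        agg = df.groupby(list(by)).sum()
        num = agg if num is None else num.add(agg, fill_value=0)
    if num is None:
        raise ValueError("keyword_proportion_profile: empty corpus")
    out = num.div(num["n_tweets"], axis=0)
    out["n_tweets"] = num["n_tweets"].astype(int)
    return out


def normalize(series: Sequence[float], method: str = "zscore") -> np.ndarray:
    """Normalize a daily series: z-score (default) or min-max to [0, 1]."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("normalize: need at least 2 values")
    if method == "zscore":
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError("normalize: zero variance")
        return (x - x.mean()) / sd
    if method == "minmax":
        rng = x.max() - x.min()
        if rng == 0:
            raise ValueError("normalize: zero variance")
        return (x - x.min()) / rng
    raise ValueError(f"normalize: unknown method {method!r}")


def daily_dose_means(series: DoseSeries | Iterable[DoseSeries]) -> pd.DataFrame:
    """Mean dose per JST calendar day per post, ignoring missing ticks.

    Returns a frame indexed by date with one column per post_id.
    """
    if isinstance(series, DoseSeries):
        series = [series]
    cols = {}
    for s in series:
        by_day = s.ticks.groupby(s.ticks.index.date).mean()
        cols[s.post_id] = by_day
    if not cols:
        raise ValueError("daily_dose_means: no series")
    return pd.DataFrame(cols)


@dataclass
class SSDResult:
    """Sum of squared differences between normalized daily series, per post."""

    ssd: pd.Series  # index post_id, ascending SSD = better fit
    best_post: str
    n_days: int
    method: str = "zscore"

    def to_frame(self) -> pd.DataFrame:
        out = self.ssd.sort_values().rename("ssd").to_frame()
        out["rank"] = range(1, len(out) + 1)
        return out.reset_index(names="post_id")


def ssd(
    tweet_daily: pd.DataFrame | pd.Series | Mapping,
    dose_daily: pd.DataFrame,
    method: str = "zscore",
) -> SSDResult:
    """SSD between normalized tweet counts and each post's normalized dose.

    ``tweet_daily`` is the frame from :func:`daily_counts` (or a Series of
    counts indexed by date); ``dose_daily`` the frame from
    :func:`daily_dose_means`.  Days missing on either side are dropped
    pairwise per post; fewer than 2 overlapping days is an error.
    """
    if isinstance(tweet_daily, pd.DataFrame):
        tweets = pd.Series(
            tweet_daily["n_tweets"].to_numpy(dtype=float),
            index=pd.Index(tweet_daily["date"]),
        )
    else:
        tweets = pd.Series(tweet_daily, dtype=float)

    ssd_vals = {}
    n_used = 0
    for post in dose_daily.columns:
        pair = pd.DataFrame({"t": tweets, "d": dose_daily[post]}).dropna()
        if len(pair) < 2:
            raise ValueError(f"ssd: fewer than 2 overlapping days for {post}")
        zt = normalize(pair["t"].values, method)
        zd = normalize(pair["d"].values, method)
        ssd_vals[post] = float(np.sum((zt - zd) ** 2))
        n_used = max(n_used, len(pair))
    s = pd.Series(ssd_vals).sort_index()
    return SSDResult(ssd=s, best_post=str(s.idxmin()), n_days=n_used, method=method)
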