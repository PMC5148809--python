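"""Synthetic tweet corpus and dose-series generator with known ground truth.

The generator emulates the post-accident corpus the pipeline was built for:

* a fixed population of users whose per-user tweet rates are gamma-distributed
  (heavy-tailed per-ID tweet counts, median a couple of tweets per year);
* per-keyword adoption: each user draws a first-mention time from an
  exponential (optionally Weibull) hazard; the user's first keyword tweet is
  emitted *exactly* at that time, and later tweets include the keyword with a
  configurable probability — so the downstream survival estimates have an
  analytic target;
* a diurnal activity profile (4-5 a.m. trough, noon peak, evening bump) and
  weekday weights;
* a corpus-level volume trend: a surge at day 0 decaying to a stable
  baseline, plus multiplicative news-day spikes;
* a small bot subpopulation that auto-posts a daily radiation report (with
  keywords) at a fixed clock time from day 0;
* a retweet flag drawn with fixed probability;
* monitoring-post dose-rate series decaying as 2^(−t/halflife) with
  lognormal noise at a 10-minute cadence.

Defaults are calibrated so a full-scale run matches the headline descriptives
of the 2011-03-11 — 2012-03-10 Japanese radiation corpus: 16.2 tweets per
user-year, 51.21% retweets, adopter fractions of 75.32%/60.84%/9.20%/4.54%/
1.46% for 放射能/放射線/Sv/Bq/Gy, ~1% bots, and a ~7.5× day-0 volume surge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus_io import JST, SECONDS_PER_DAY, DoseSeries, StudyWindow, TweetRecord

# Adoption hazards (per day) solving 1 − exp(−λ·366) = observed adopter share.
DEFAULT_HAZARDS: dict[str, float] = {
    "放射能": -math.log(1 - 0.7532) / 366.0,
    "放射線": -math.log(1 - 0.6084) / 366.0,
    "Sv": -math.log(1 - 0.0920) / 366.0,
    "Bq": -math.log(1 - 0.0454) / 366.0,
    "Gy": -math.log(1 - 0.0146) / 366.0,
}


def _default_diurnal() -> tuple[float, ...]:
    # trough 4-5 a.m., main peak at noon, secondary bump ~8-9 p.m.
    w = np.array(
        [
            2.0, 1.2, 0.8, 0.6, 0.5, 0.6,  # 0-5
            1.0, 2.0, 3.5, 4.0, 4.5, 5.0,  # 6-11
            6.5, 5.5, 4.5, 4.2, 4.5, 5.0,  # 12-17
            5.5, 6.0, 6.2, 5.8, 5.0, 3.5,  # 18-23
        ]
    )
    return tuple(w / w.sum())


@dataclass
class SynthConfig:
    """Data-generating conditions for a synthetic corpus.

    ``keyword_hazards`` maps keyword → adoption hazard λ (per day); optional
    ``keyword_shapes`` gives a Weibull shape ρ per keyword (1 = exponential,
    adoption CDF 1 − exp(−(λt)^ρ)).  ``trend_surge``/``trend_halflife_days``
    shape the day-0 volume surge 1 + A·2^(−d/h); ``daily_trend`` overrides the
    whole per-day relative-volume curve when given.
    """

    n_users: int = 10_000
    study_start: datetime = field(
        default_factory=lambda: datetime(2011, 3, 11, 0, 0, 0, tzinfo=JST)
    )
    study_end: datetime = field(
        default_factory=lambda: datetime(2012, 3, 11, 0, 0, 0, tzinfo=JST)
    )
    base_rate: float = 16.2 / 366.0  # mean tweets/user/day
    rate_dispersion: float = 0.1  # gamma shape of per-user rate heterogeneity
    keyword_hazards: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HAZARDS)
    )
    keyword_shapes: Mapping[str, float] = field(default_factory=dict)
    keyword_prob: float = 0.2  # post-adoption keyword inclusion probability
    diurnal_profile: Sequence[float] = field(default_factory=_default_diurnal)
    weekday_weights: Sequence[float] = (1.0,) * 7
    retweet_prob: float = 0.5121
    bot_fraction: float = 0.01
    bot_keyword_rate: float = 1.0  # auto-posts per day per bot
    spikes: Sequence[tuple[str, float]] = (
        ("2011-09-10", 3.0),
        ("2011-10-13", 3.0),
    )
    trend_surge: float = 6.5
    trend_halflife_days: float = 10.0
    daily_trend: Sequence[float] | None = None
    missing_username_prob: float = 0.107
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_users < 0:
            raise ValueError("SynthConfig.n_users: must be >= 0")
        if self.study_end <= self.study_start:
            raise ValueError("SynthConfig.study_end: must be after study_start")
        if self.base_rate <= 0:
            raise ValueError("SynthConfig.base_rate: must be > 0")
        if self.rate_dispersion <= 0:
            raise ValueError("SynthConfig.rate_dispersion: must be > 0")
        for k, lam in self.keyword_hazards.items():
            if not (np.isfinite(lam) and lam >= 0):
                raise ValueError(f"SynthConfig.keyword_hazards[{k!r}]: must be finite and >= 0")
        for k, rho in self.keyword_shapes.items():
            if rho <= 0:
                raise ValueError(f"SynthConfig.keyword_shapes[{k!r}]: must be > 0")
        if not (0 <= self.keyword_prob <= 1):
            raise ValueError("SynthConfig.keyword_prob: must be in [0, 1]")
        dp = np.asarray(self.diurnal_profile, dtype=float)
        if dp.shape != (24,) or (dp < 0).any() or dp.sum() <= 0:
            raise ValueError("SynthConfig.diurnal_profile: 24 nonnegative weights")
        ww = np.asarray(self.weekday_weights, dtype=float)
        if ww.shape != (7,) or (ww < 0).any() or ww.sum() <= 0:
            raise ValueError("SynthConfig.weekday_weights: 7 nonnegative weights")
        if not (0 <= self.retweet_prob <= 1):
            raise ValueError("SynthConfig.retweet_prob: must be in [0, 1]")
        if not (0 <= self.bot_fraction < 1):
            raise ValueError("SynthConfig.bot_fraction: must be in [0, 1)")
        if self.bot_keyword_rate <= 0:
            raise ValueError("SynthConfig.bot_keyword_rate: must be > 0")
        for d, mult in self.spikes:
            if mult <= 1:
                raise ValueError("SynthConfig.spikes: multiplier must be > 1")
        if self.daily_trend is not None and np.asarray(self.daily_trend).min() < 0:
            raise ValueError("SynthConfig.daily_trend: must be nonnegative")

    @property
    def window(self) -> StudyWindow:
        return StudyWindow(start=self.study_start, end=self.study_end)

    def day_weights(self) -> np.ndarray:
        """Relative expected volume per calendar day (mean 1 over the window)."""
        n_days = self.window.n_days
        days = pd.date_range(
            self.study_start, periods=n_days, freq="D", tz=JST
        )
        if self.daily_trend is not None:
            trend = np.asarray(self.daily_trend, dtype=float)
            if trend.shape != (n_days,):
                raise ValueError("SynthConfig.daily_trend: length must equal n_days")
        else:
            d = np.arange(n_days, dtype=float)
            trend = 1.0 + self.trend_surge * 2.0 ** (-d / self.trend_halflife_days)
        ww = np.asarray(self.weekday_weights, dtype=float)
        ww = ww / ww.mean()
        w = trend * ww[days.weekday]
        spike_mult = np.ones(n_days)
        for date_str, mult in self.spikes:
            ts = pd.Timestamp(date_str, tz=JST)
            idx = int((ts - days[0]).days)
            if 0 <= idx < n_days:
                spike_mult[idx] = mult
        w = w * spike_mult
        return w / w.mean()


@dataclass
class GroundTruth:
    """What the generator actually did, for parameter-recovery tests.

    ``adoption``: DataFrame(user_id, keyword, adoption_day) with NaN for
    "never adopted within the window"; adoption_day is the exact time (days
    from window start) of the user's first keyword tweet.  ``bots``: the set
    of bot user IDs.  ``day_multiplier``: expected relative volume per day.
    """

    adoption: pd.DataFrame
    bots: set[str]
    day_multiplier: pd.Series

    def to_csv(self, path: str | Path) -> None:
        out = self.adoption.copy()
        out["is_bot"] = out["user_id"].isin(self.bots)
        out.to_csv(path, index=False)


_KW_TEMPLATES = [
    "今日の話題は{kws}のニュースでした",
    "{kws}について調べている",
    "ニュースで{kws}の特集を見た",
]
_PLAIN_TEMPLATES = [
    "今日もいい天気ですね",
    "お昼ごはんなう",
    "電車が混んでいて大変だった",
    "週末は出かける予定です",
    "眠い、もう寝ます",
]
_BOT_TEMPLATE = "【自動配信】本日の放射線量レポート 毎時{dose:.2f}マイクロSv 放射能測定値は平常範囲です"


def _sample_adoptions(cfg: SynthConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per keyword: adoption time (days) per user, inf when beyond any horizon."""
    out = {}
    for kw, lam in cfg.keyword_hazards.items():
        if lam == 0:
            out[kw] = np.full(cfg.n_users, np.inf)
            continue
        u = rng.random(cfg.n_users)
        rho = float(cfg.keyword_shapes.get(kw, 1.0))
        # inverse CDF of 1 − exp(−(λt)^ρ)
        out[kw] = (-np.log1p(-u)) ** (1.0 / rho) / lam
    return out


def generate_corpus_frame(cfg: SynthConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the corpus as a single canonical DataFrame plus ground truth.

    Deterministic given ``cfg.rng_seed``; rows sorted by (timestamp, tweet_id).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    window = cfg.window
    n_days = window.n_days
    window_days = window.length_days
    keywords = list(cfg.keyword_hazards)

    user_ids = np.array([f"u{(i + 1):07d}" for i in range(cfg.n_users)])
    day_w = cfg.day_weights()
    gt_multiplier = pd.Series(
        day_w,
        index=pd.date_range(cfg.study_start, periods=n_days, freq="D", tz=JST).date,
    )

    if cfg.n_users == 0:
        empty = pd.DataFrame(
            columns=["tweet_id", "user_id", "username", "created_at", "text", "is_retweet"]
        )
        gt = GroundTruth(
            adoption=pd.DataFrame(columns=["user_id", "keyword", "adoption_day"]),
            bots=set(),
            day_multiplier=gt_multiplier,
        )
        return empty, gt

    n_bots = int(round(cfg.bot_fraction * cfg.n_users))
    bot_idx = rng.choice(cfg.n_users, size=n_bots, replace=False) if n_bots else np.array([], int)
    is_bot = np.zeros(cfg.n_users, dtype=bool)
    is_bot[bot_idx] = True

    rates = rng.gamma(
        cfg.rate_dispersion, cfg.base_rate / cfg.rate_dispersion, size=cfg.n_users
    )
    adoptions = _sample_adoptions(cfg, rng)

    diurnal = np.asarray(cfg.diurnal_profile, float)
    diurnal = diurnal / diurnal.sum()
    day_p = day_w / day_w.sum()

    # --- background tweets -------------------------------------------------
    n_bg = rng.poisson(rates * n_days)
    total_bg = int(n_bg.sum())
    bg_user = np.repeat(np.arange(cfg.n_users), n_bg)
    bg_day = rng.choice(n_days, size=total_bg, p=day_p)
    bg_hour = rng.choice(24, size=total_bg, p=diurnal)
    bg_sec = rng.uniform(0, 3600.0, size=total_bg)
    bg_t = bg_day * SECONDS_PER_DAY + bg_hour * 3600.0 + bg_sec

    # keyword inclusion strictly after adoption
    bg_kw_mask = {}
    t_days = bg_t / SECONDS_PER_DAY
    for kw in keywords:
        adopted = t_days > adoptions[kw][bg_user]
        bg_kw_mask[kw] = adopted & (rng.random(total_bg) < cfg.keyword_prob)

    # --- adoption tweets (first keyword tweet exactly at adoption time) ----
    ad_user_l, ad_t_l, ad_kw_l = [], [], []
    for kw in keywords:
        a = adoptions[kw]
        inside = a < window_days
        ad_user_l.append(np.nonzero(inside)[0])
        ad_t_l.append(a[inside] * SECONDS_PER_DAY)
        ad_kw_l.append(np.full(int(inside.sum()), kw, dtype=object))
    ad_user = np.concatenate(ad_user_l) if ad_user_l else np.array([], int)
    ad_t = np.concatenate(ad_t_l) if ad_t_l else np.array([])
    ad_kw = np.concatenate(ad_kw_l) if ad_kw_l else np.array([], object)

    # --- bot auto-posts: one fixed clock time per bot, periodic from day 0 -
    bot_user_l, bot_t_l = [], []
    period = 1.0 / cfg.bot_keyword_rate
    for u in bot_idx:
        phase = rng.uniform(0, period)
        times = np.arange(phase, window_days, period)
        bot_user_l.append(np.full(times.size, u))
        bot_t_l.append(times * SECONDS_PER_DAY)
    bot_user = np.concatenate(bot_user_l) if bot_user_l else np.array([], int)
    bot_t = np.concatenate(bot_t_l) if bot_t_l else np.array([])

    # --- assemble ----------------------------------------------------------
    parts_user = np.concatenate([bg_user, ad_user, bot_user.astype(int)])
    parts_t = np.concatenate([bg_t, ad_t, bot_t])
    kind = np.concatenate(
        [
            np.zeros(total_bg, dtype=np.int8),
            np.ones(ad_user.size, dtype=np.int8),
            np.full(bot_user.size, 2, dtype=np.int8),
        ]
    )
    n_all = parts_t.size

    texts = np.empty(n_all, dtype=object)
    # background: join included keywords, else a plain template
    bg_templates = rng.integers(0, len(_PLAIN_TEMPLATES), size=total_bg)
    bg_kw_templates = rng.integers(0, len(_KW_TEMPLATES), size=total_bg)
    kw_arrays = np.array(keywords, dtype=object)
    if keywords:
        inc_matrix = np.column_stack([bg_kw_mask[kw] for kw in keywords])
    else:
        inc_matrix = np.zeros((total_bg, 0), dtype=bool)
    any_kw = inc_matrix.any(axis=1)
    plain_idx = np.nonzero(~any_kw)[0]
    texts[plain_idx] = [
        _PLAIN_TEMPLATES[j] for j in bg_templates[plain_idx]
    ]
    for i in np.nonzero(any_kw)[0]:
        kws = "と".join(kw_arrays[inc_matrix[i]])
        texts[i] = _KW_TEMPLATES[bg_kw_templates[i]].format(kws=kws)
    texts[total_bg : total_bg + ad_user.size] = [
        _KW_TEMPLATES[0].format(kws=k) for k in ad_kw
    ]
    bot_doses = rng.uniform(0.03, 0.3, size=bot_user.size)
    texts[total_bg + ad_user.size :] = [
        _BOT_TEMPLATE.format(dose=d) for d in bot_doses
    ]

    retweet = rng.random(n_all) < cfg.retweet_prob
    retweet[kind == 2] = False  # auto-posts are originals

    order = np.lexsort((kind, parts_t))  # stable within equal timestamps
    parts_user = parts_user[order]
    parts_t = parts_t[order]
    texts = texts[order]
    retweet = retweet[order]

    run_tag = f"{rng.integers(0, 2**32):08x}"
    tweet_ids = np.array([f"t{run_tag}-{i:09d}" for i in range(n_all)])

    has_name = rng.random(cfg.n_users) >= cfg.missing_username_prob
    usernames = np.where(has_name, np.char.add("name_", user_ids.astype(str)), None)

    start = pd.Timestamp(cfg.study_start)
    created = start + pd.to_timedelta(np.round(parts_t, 3), unit="s")
    frame = pd.DataFrame(
        {
            "tweet_id": tweet_ids,
            "user_id": user_ids[parts_user],
            "username": usernames[parts_user],
            "created_at": created,
            "text": texts,
            "is_retweet": retweet,
        }
    )

    # ground truth: first keyword tweet per (user, keyword)
    gt_rows = []
    bot_first = {}
    if bot_user.size:
        bf = pd.Series(bot_t / SECONDS_PER_DAY).groupby(bot_user).min()
        bot_first = bf.to_dict()
    for kw in keywords:
        a = adoptions[kw].copy()
        if kw in ("放射線", "Sv", "放射能"):
            # the bot report text contains 放射線, 放射能 and Sv
            for u, t0 in bot_first.items():
                a[int(u)] = min(a[int(u)], t0)
        a = np.where(a < window_days, a, np.nan)
        gt_rows.append(
            pd.DataFrame({"user_id": user_ids, "keyword": kw, "adoption_day": a})
        )
    gt = GroundTruth(
        adoption=pd.concat(gt_rows, ignore_index=True)
        if gt_rows
        else pd.DataFrame(columns=["user_id", "keyword", "adoption_day"]),
        bots=set(user_ids[bot_idx]),
        day_multiplier=gt_multiplier,
    )
    return frame, gt


def generate_corpus(cfg: SynthConfig) -> tuple[Iterator[TweetRecord], GroundTruth]:
    """Stream-of-records view of :func:`generate_corpus_frame`."""
    frame, gt = generate_corpus_frame(cfg)

    def records() -> Iterator[TweetRecord]:
        for row in frame.itertuples(index=False):
            yield TweetRecord(
                tweet_id=row.tweet_id,
                user_id=row.user_id,
                username=row.username,
                timestamp=row.created_at.to_pydatetime(),
                text=row.text,
                is_retweet=bool(row.is_retweet),
            )

    return records(), gt


def generate_dose_series(
    cfg: SynthConfig,
    n_posts: int = 8,
    decay_halflife_days: float | Sequence[float] = 30.0,
    noise_sd: float = 0.0,
    initial_levels: Sequence[float] | None = None,
) -> list[DoseSeries]:
    """Simulate monitoring-post dose-rate series at 10-minute cadence.

    Each post decays as ``level · 2^(−t/halflife)`` with multiplicative
    lognormal noise exp(noise_sd·Z).  ``decay_halflife_days`` may be a scalar
    (shared) or one value per post; ``initial_levels`` default to a geometric
    spread across posts (µSv/h), emulating sensors at different distances.
    """
    cfg.validate()
    if n_posts < 1:
        raise ValueError("generate_dose_series: n_posts must be >= 1")
    half = np.asarray(decay_halflife_days, dtype=float)
    if half.ndim == 0:
        half = np.full(n_posts, float(half))
    if half.shape != (n_posts,):
        raise ValueError("generate_dose_series: one halflife or one per post")
    if (half <= 0).any():
        raise ValueError("generate_dose_series: decay_halflife_days must be > 0")
    if noise_sd < 0:
        raise ValueError("generate_dose_series: noise_sd must be >= 0")
    if initial_levels is None:
        initial_levels = 60.0 * 0.5 ** np.arange(n_posts)
    levels = np.asarray(initial_levels, dtype=float)
    if levels.shape != (n_posts,):
        raise ValueError("generate_dose_series: one initial level per post")

    rng = np.random.default_rng(cfg.rng_seed + 1_000_003)
    window = cfg.window
    idx = pd.date_range(window.start, window.end, freq="10min", tz=JST, inclusive="left")
    t_days = (idx - idx[0]).total_seconds() / SECONDS_PER_DAY
    out = []
    for p in range(n_posts):
        base = levels[p] * 2.0 ** (-t_days / half[p])
        if noise_sd > 0:
            base = base * np.exp(noise_sd * rng.standard_normal(len(idx)))
        out.append(DoseSeries(post_id=f"MP-{p + 1}", ticks=pd.Series(base, index=idx)))
    return out
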