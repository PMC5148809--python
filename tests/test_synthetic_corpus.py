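"""Ground-truth recovery and determinism of the synthetic corpus generator."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from concernsurv import (
    KeywordSet,
    SynthConfig,
    build_event_table,
    generate_corpus,
    generate_corpus_frame,
    generate_dose_series,
    write_tweets,
)


def small_config(**kw):
    defaults = dict(n_users=300, rng_seed=123)
    defaults.update(kw)
    return SynthConfig(**defaults)


def test_zero_users_gives_empty_corpus_and_ground_truth():
    frame, gt = generate_corpus_frame(small_config(n_users=0))
    assert len(frame) == 0
    assert len(gt.adoption) == 0
    assert gt.bots == set()


def test_same_seed_byte_identical_csv(tmp_path):
    cfg = small_config()
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    frame1, _ = generate_corpus_frame(cfg)
    frame2, _ = generate_corpus_frame(dataclasses.replace(cfg))
    write_tweets(frame1, p1)
    write_tweets(frame2, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_different_seeds_differ_in_tweet_ids():
    f1, _ = generate_corpus_frame(small_config(rng_seed=1))
    f2, _ = generate_corpus_frame(small_config(rng_seed=2))
    assert set(f1["tweet_id"]).isdisjoint(set(f2["tweet_id"]))


def test_validation_errors_name_the_field():
    with pytest.raises(ValueError, match="base_rate"):
        SynthConfig(base_rate=0.0).validate()
    with pytest.raises(ValueError, match="retweet_prob"):
        SynthConfig(retweet_prob=1.5).validate()
    with pytest.raises(ValueError, match="keyword_hazards"):
        SynthConfig(keyword_hazards={"Sv": -0.1}).validate()
    with pytest.raises(ValueError, match="diurnal_profile"):
        SynthConfig(diurnal_profile=[1.0] * 23).validate()
    with pytest.raises(ValueError, match="study_end"):
        cfg = SynthConfig()
        dataclasses.replace(cfg, study_end=cfg.study_start).validate()


def test_timestamps_fall_inside_the_study_window():
    cfg = small_config()
    frame, _ = generate_corpus_frame(cfg)
    assert (frame["created_at"] >= cfg.window.start).all()
    assert (frame["created_at"] < cfg.window.end).all()
    assert frame["created_at"].is_monotonic_increasing


def test_first_keyword_tweet_occurs_at_sampled_adoption_time():
    cfg = small_config(n_users=400, bot_fraction=0.0, rng_seed=5)
    frame, gt = generate_corpus_frame(cfg)
    ks = KeywordSet(tuple(cfg.keyword_hazards))
    table = build_event_table(frame, ks, cfg.window)
    ev = table.df[table.df["status"] == "event"].set_index(["user_id", "keyword"])
    ad = gt.adoption.dropna().set_index(["user_id", "keyword"])["adoption_day"]
    # every adoption inside the window appears as an event at that exact time
    joined = ev.join(ad, how="outer")
    present = joined.dropna()
    # users absent from the corpus entirely (no tweets at all) cannot appear
    observed_users = set(frame["user_id"])
    missing = joined[joined["time_days"].isna()]
    assert set(missing.index.get_level_values(0)).isdisjoint(observed_users) or len(
        missing
    ) == 0
    assert (present["time_days"] - present["adoption_day"]).abs().max() < 1e-7


def test_adoption_fraction_recovers_exponential_cdf():
    # hazard calibrated so 1 - exp(-lambda*366) = 0.7532
    lam = -math.log(1 - 0.7532) / 366.0
    cfg = SynthConfig(
        n_users=10_000,
        keyword_hazards={"放射能": lam},
        bot_fraction=0.0,
        rng_seed=2011,
    )
    _, gt = generate_corpus_frame(cfg)
    frac = gt.adoption["adoption_day"].notna().mean()
    p = 0.7532
    se = math.sqrt(p * (1 - p) / cfg.n_users)
    assert abs(frac - p) <= 3 * se


def test_weibull_shape_changes_adoption_profile():
    lam = 1 / 50
    early = SynthConfig(
        n_users=4000,
        keyword_hazards={"Sv": lam},
        keyword_shapes={"Sv": 0.5},
        bot_fraction=0.0,
        rng_seed=3,
    )
    _, gt = generate_corpus_frame(early)
    t = gt.adoption["adoption_day"].dropna()
    # Weibull(rho=0.5) with the same lambda front-loads adoptions:
    # CDF at 10 days = 1-exp(-sqrt(10/50)) ~ 0.36 vs exponential 0.18
    frac10 = (t <= 10).sum() / len(gt.adoption)
    expected = 1 - math.exp(-math.sqrt(10 * lam))
    assert abs(frac10 - expected) < 0.03


def test_hourly_histogram_follows_diurnal_profile():
    # background activity only: no adoption tweets, no bots
    cfg = SynthConfig(
        n_users=7000,
        keyword_hazards={},
        bot_fraction=0.0,
        rng_seed=8,
    )
    frame, _ = generate_corpus_frame(cfg)
    assert len(frame) >= 100_000
    observed = frame["created_at"].dt.hour.value_counts().reindex(range(24), fill_value=0)
    expected = np.asarray(cfg.diurnal_profile) * len(frame)
    chi2 = stats.chisquare(observed.values, expected)
    assert chi2.pvalue > 0.01


def test_retweet_fraction_within_three_ses():
    cfg = small_config(n_users=2000, rng_seed=17)
    frame, _ = generate_corpus_frame(cfg)
    n = len(frame)
    p = cfg.retweet_prob
    se = math.sqrt(p * (1 - p) / n)
    # bots never carry the retweet flag, so compare on non-bot tweets
    frac = frame["is_retweet"].mean()
    n_bot_tweets = frame["text"].str.startswith("【自動配信】").sum()
    frac_nonbot = frame["is_retweet"].sum() / (n - n_bot_tweets)
    assert abs(frac_nonbot - p) <= 3 * se


def test_bot_population_matches_configured_fraction():
    cfg = small_config(n_users=1000, bot_fraction=0.013, rng_seed=4)
    _, gt = generate_corpus_frame(cfg)
    assert len(gt.bots) == round(0.013 * 1000)


def test_spike_day_multiplier_in_ground_truth():
    # flat base trend isolates the spike's effect on the day multiplier
    cfg = small_config(spikes=(("2011-09-10", 5.0),), daily_trend=np.ones(366))
    _, gt = generate_corpus_frame(cfg)
    mult = gt.day_multiplier
    spike_day = pd.Timestamp("2011-09-10").date()
    neighbor = pd.Timestamp("2011-09-09").date()
    assert mult[spike_day] / mult[neighbor] == pytest.approx(5.0, rel=1e-9)


def test_generate_corpus_streams_records():
    cfg = small_config(n_users=20)
    records, gt = generate_corpus(cfg)
    recs = list(records)
    frame, _ = generate_corpus_frame(cfg)
    assert len(recs) == len(frame)
    assert recs[0].tweet_id == frame.iloc[0]["tweet_id"]


# --- dose series -------------------------------------------------------------


def test_noise_free_decay_halves_at_halflife():
    cfg = small_config()
    (series,) = generate_dose_series(cfg, n_posts=1, decay_halflife_days=30.0, noise_sd=0.0)
    v0 = series.ticks.iloc[0]
    t30 = series.ticks.index[0] + pd.Timedelta(days=30)
    assert series.ticks[t30] == pytest.approx(v0 / 2, rel=1e-12)


def test_eight_posts_have_distinct_ids():
    cfg = small_config()
    series = generate_dose_series(cfg, n_posts=8, decay_halflife_days=30.0)
    assert [s.post_id for s in series] == [f"MP-{i}" for i in range(1, 9)]


def test_daily_mean_matches_bruteforce_average_of_144_ticks():
    cfg = small_config()
    (series,) = generate_dose_series(cfg, n_posts=1, decay_halflife_days=12.0, noise_sd=0.0)
    # brute force: average the 144 tick values of day 5 directly
    day5 = series.ticks[
        (series.ticks.index >= cfg.window.start + pd.Timedelta(days=5))
        & (series.ticks.index < cfg.window.start + pd.Timedelta(days=6))
    ]
    assert len(day5) == 144
    from concernsurv import daily_dose_means

    dd = daily_dose_means(series)
    got = dd.iloc[5, 0]
    assert got == pytest.approx(day5.mean(), rel=1e-12)


def test_dose_series_cadence_is_ten_minutes():
    cfg = small_config()
    (series,) = generate_dose_series(cfg, n_posts=1, decay_halflife_days=30.0)
    deltas = np.diff(series.ticks.index.values).astype("timedelta64[s]").astype(int)
    assert (deltas == 600).all()
    assert len(series.ticks) == 366 * 144


def test_nonpositive_halflife_rejected():
    with pytest.raises(ValueError):
        generate_dose_series(small_config(), n_posts=2, decay_halflife_days=0.0)
    with pytest.raises(ValueError):
        generate_dose_series(small_config(), n_posts=0, decay_halflife_days=30.0)


def test_dose_series_deterministic_given_seed():
    cfg = small_config(rng_seed=99)
    s1 = generate_dose_series(cfg, n_posts=2, decay_halflife_days=20.0, noise_sd=0.2)
    s2 = generate_dose_series(cfg, n_posts=2, decay_halflife_days=20.0, noise_sd=0.2)
    for a, b in zip(s1, s2):
        pd.testing.assert_series_equal(a.ticks, b.ticks)
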