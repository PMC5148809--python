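"""Daily counts, descriptives, profiles, normalization and SSD."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from concernsurv import (
    DoseSeries,
    KeywordSet,
    daily_counts,
    daily_dose_means,
    descriptive_stats,
    hourly_weekday_profile,
    keyword_proportion_profile,
    normalize,
    per_id_percentiles,
    percentage,
    ssd,
    t_confidence_interval,
)

KS = KeywordSet()


def test_daily_counts_zero_filled_over_window(window):
    out = daily_counts([], window)
    assert len(out) == 366
    assert (out["n_tweets"] == 0).all()
    assert (out["n_users"] == 0).all()


def test_daily_counts_tweets_and_distinct_users(window, make_tweet):
    tweets = [
        make_tweet(user="a", day=3.1),
        make_tweet(user="a", day=3.5),
        make_tweet(user="b", day=3.9),
    ]
    out = daily_counts(tweets, window)
    row = out.iloc[3]
    assert row["n_tweets"] == 3
    assert row["n_users"] == 2
    assert out["n_tweets"].sum() == 3  # conservation


def test_daily_counts_ignore_out_of_window(window, make_tweet):
    out = daily_counts([make_tweet(day=-0.5), make_tweet(day=366.5)], window)
    assert out["n_tweets"].sum() == 0


def test_descriptive_stats_constant_series_degenerate():
    d = descriptive_stats([7.0] * 10)
    assert d.sd == 0
    assert d.skewness == 0 and d.excess_kurtosis == 0
    assert d.degenerate


def test_descriptive_stats_needs_two_values():
    with pytest.raises(ValueError):
        descriptive_stats([1.0])


def test_descriptive_stats_order_invariants():
    rng = np.random.default_rng(0)
    x = rng.lognormal(3, 1, 200)
    d = descriptive_stats(x)
    assert d.minimum <= d.q1 <= d.median <= d.q3 <= d.maximum
    assert d.ci95[0] <= d.mean <= d.ci95[1]
    assert d.total == pytest.approx(x.sum())


def test_t_confidence_interval_closed_form():
    from scipy import stats

    mean, sd, n = 100.0, 10.0, 25
    lo, hi = t_confidence_interval(mean, sd, n)
    t = stats.t.ppf(0.975, 24)
    assert lo == pytest.approx(100 - t * 2.0)
    assert hi == pytest.approx(100 + t * 2.0)


def test_percentage_helper_rounding():
    assert percentage(880_108, 1_168_542) == 75.32
    with pytest.raises(ValueError):
        percentage(1, 0)


def test_per_id_percentiles_all_singletons(window, make_tweet):
    tweets = [make_tweet(user=f"u{i}", day=i) for i in range(10)]
    p = per_id_percentiles(tweets)
    assert (p == 1).all()


def test_per_id_percentiles_linear_interpolation(window, make_tweet):
    tweets = []
    for u, n in enumerate([1, 2, 3, 4]):
        tweets += [make_tweet(user=f"u{u}", day=d) for d in range(n)]
    p = per_id_percentiles(tweets)
    assert p["median"] == pytest.approx(2.5)  # linear between order stats
    assert p["max"] == 4 and p["min"] == 1


def test_per_id_percentiles_heavy_tail_shape():
    from concernsurv import SynthConfig, generate_corpus_frame

    frame, _ = generate_corpus_frame(SynthConfig(n_users=2000, rng_seed=21))
    p = per_id_percentiles(frame)
    assert p["median"] <= 3  # most IDs tweet a handful of times
    assert p["max"] > 10 * p["p75"]  # a few bots/heavy users dominate


def test_hourly_weekday_profile_single_tweet(window, make_tweet):
    # 2011-03-15 was a Tuesday; make_tweet day offset 4 lands on it
    t = make_tweet(day=4 + 8 / 24.0)
    mat = hourly_weekday_profile([t])
    assert mat.loc["Tue", 8] == 1.0
    assert mat.values.sum() == 1.0


def test_hourly_profile_peak_recovers_generator_diurnal():
    from concernsurv import SynthConfig, generate_corpus_frame

    w = np.full(24, 0.01)
    w[12] = 1.0
    cfg = SynthConfig(
        n_users=1500,
        diurnal_profile=tuple(w / w.sum()),
        keyword_hazards={},
        bot_fraction=0.0,
        rng_seed=6,
    )
    frame, _ = generate_corpus_frame(cfg)
    mat = hourly_weekday_profile(frame)
    assert (mat.values.sum(axis=0).argmax()) == 12


def test_keyword_proportions_none_and_all(window, make_tweet):
    plain = [make_tweet(day=i, text="無関係") for i in range(5)]
    prof = keyword_proportion_profile(plain, KS)
    assert (prof["any_keyword"] == 0).all()
    hits = [make_tweet(day=i, text="Sv速報") for i in range(5)]
    prof = keyword_proportion_profile(hits, KS)
    assert (prof["any_keyword"] == 1).all()
    assert (prof["Sv"] == 1).all()


def test_keyword_proportions_recover_inclusion_probability(window, make_tweet):
    rng = np.random.default_rng(33)
    p_inc = 0.3
    tweets = [
        make_tweet(day=float(rng.uniform(0, 28)), text="Svあり" if rng.random() < p_inc else "なし")
        for _ in range(4000)
    ]
    prof = keyword_proportion_profile(tweets, KeywordSet(("Sv",)), by=("month",))
    n = prof["n_tweets"].sum()
    pooled = (prof["Sv"] * prof["n_tweets"]).sum() / n
    assert abs(pooled - p_inc) <= 3 * math.sqrt(p_inc * (1 - p_inc) / n)


def test_normalize_zscore_properties():
    z = normalize([1.0, 2.0, 3.0])
    assert z == pytest.approx([-1.0, 0.0, 1.0])
    x = np.random.default_rng(1).normal(5, 3, 50)
    z = normalize(x)
    assert z.mean() == pytest.approx(0.0, abs=1e-12)
    assert z.std(ddof=1) == pytest.approx(1.0, rel=1e-12)


@given(
    st.lists(st.floats(-1e4, 1e4), min_size=3, max_size=40).filter(
        lambda xs: np.std(xs) > 1e-6
    ),
    st.floats(0.1, 10),
    st.floats(-100, 100),
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_normalize_affine_invariance_and_idempotence(xs, a, b):
    x = np.asarray(xs)
    z1 = normalize(x)
    z2 = normalize(a * x + b)
    assert np.allclose(z1, z2, atol=1e-8)
    assert np.allclose(normalize(z1), z1, atol=1e-12)  # idempotent


def test_normalize_rejects_constant():
    with pytest.raises(ValueError):
        normalize([2.0, 2.0, 2.0])


def test_normalize_minmax_range():
    z = normalize([1.0, 2.0, 5.0], method="minmax")
    assert z.min() == 0.0 and z.max() == 1.0


def _dose_from_daily(values, window, post="MP-1"):
    idx = pd.date_range(window.start, periods=len(values), freq="D")
    return DoseSeries(post, pd.Series(np.asarray(values, float), index=idx))


def test_ssd_zero_for_identical_series(window, make_tweet):
    tweets = []
    counts = [5, 8, 2, 9, 4]
    for d, c in enumerate(counts):
        tweets += [make_tweet(day=d + 0.5) for _ in range(c)]
    dc = daily_counts(tweets, window).iloc[: len(counts)]
    dd = daily_dose_means(_dose_from_daily(counts, window))
    res = ssd(dc, dd)
    assert res.ssd["MP-1"] == pytest.approx(0.0, abs=1e-20)
    assert res.best_post == "MP-1"


def test_ssd_is_symmetric_and_scale_offset_invariant(window):
    rng = np.random.default_rng(2)
    a = rng.normal(0, 1, 60)
    b = rng.normal(0, 1, 60)
    idx = pd.date_range(window.start, periods=60, freq="D").date
    sa = pd.Series(a, index=idx)
    sb_raw = pd.Series(3.5 * b + 10, index=idx)
    dd_b = pd.DataFrame({"MP-1": pd.Series(b, index=idx)})
    dd_a = pd.DataFrame({"MP-1": sa})
    forward = ssd(sa, dd_b).ssd["MP-1"]
    backward = ssd(pd.Series(b, index=idx), dd_a).ssd["MP-1"]
    scaled = ssd(sb_raw, dd_a).ssd["MP-1"]
    assert forward == pytest.approx(backward, rel=1e-12)
    assert scaled == pytest.approx(backward, rel=1e-12)


def test_ssd_identity_two_n_minus_one_times_one_minus_r(window):
    # for z-scored series, SSD = 2(n-1)(1-r) exactly; for independent series
    # E[SSD] is therefore 2(n-1)
    rng = np.random.default_rng(3)
    n = 80
    idx = pd.date_range(window.start, periods=n, freq="D").date
    vals = []
    for _ in range(200):
        x, y = rng.normal(size=n), rng.normal(size=n)
        r = np.corrcoef(x, y)[0, 1]
        got = ssd(pd.Series(x, index=idx), pd.DataFrame({"MP-1": pd.Series(y, index=idx)})).ssd[
            "MP-1"
        ]
        assert got == pytest.approx(2 * (n - 1) * (1 - r), rel=1e-10)
        vals.append(got)
    assert np.mean(vals) == pytest.approx(2 * (n - 1), rel=0.05)


def test_ssd_requires_two_overlapping_days(window):
    idx1 = pd.date_range(window.start, periods=5, freq="D").date
    idx2 = pd.date_range(window.start + pd.Timedelta(days=100), periods=5, freq="D").date
    with pytest.raises(ValueError):
        ssd(
            pd.Series(range(5), index=idx1, dtype=float),
            pd.DataFrame({"MP-1": pd.Series(range(5), index=idx2, dtype=float)}),
        )


def test_ssd_drops_missing_days_pairwise(window):
    idx = pd.date_range(window.start, periods=10, freq="D").date
    x = pd.Series(np.arange(10, dtype=float) ** 1.5, index=idx)
    y = x.copy()
    y.iloc[4] = np.nan  # missing dose day
    res = ssd(x, pd.DataFrame({"MP-1": y}))
    assert res.ssd["MP-1"] == pytest.approx(0.0, abs=1e-20)
    assert res.n_days == 9
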