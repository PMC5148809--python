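# Methods

## Event construction

A tweet log is reduced to one row per (user ID, keyword): the time of the
user's earliest keyword-bearing tweet ("event") or the window length
("censored"). Times are accumulated in seconds from the window origin and
reported in days (seconds/86,400). Conventions, all configurable:

* **Origin** is midnight JST of the window start (2011-03-11 00:00 by
  default). Every user's observation is assumed to start there — a pseudo
  time origin, since true exposure onset per user is unobservable in a
  public tweet stream.
* **Matching** is case-sensitive substring search after Unicode NFC
  normalization, no tokenization: unit keywords must match inside `mSv`,
  `μSv/h` etc. The false-positive risk of substring matching in Japanese
  text is judged low for these strings.
* **Retweets count.** About half the corpus volume is retweets and a retweet
  does expose the keyword under the user's ID; nothing excludes them.
* **Ties** at identical timestamps are broken by tweet ID, making the table
  invariant to input order.
* **Risk set** N is the number of distinct user IDs observed in the corpus;
  published summaries alternate between 1,168,542 and 1,168,543 IDs, so N is
  never hard-coded.
* **Bots** are flagged (never removed) when a user posts more than 200
  keyword tweets over the window — the frequency trait of auto-posted daily
  radiation reports. Removing them would bias the non-tweeting rate upward,
  so flags are annotations for sensitivity analyses.

## Survival estimation

`kaplan_meier` pools tied event times; censored observations at an event
time leave the risk set after the events (the standard, SAS-compatible
convention). Greenwood's formula gives Var Ŝ(t_j) = Ŝ² Σ_{i≤j}
d_i/(n_i(n_i−d_i)); once Ŝ reaches 0 the variance is reported as 0.

The **mean attenuation period** is the restricted mean survival time
∫₀^τ Ŝ(t) dt, computed exactly as the area of the step function. τ defaults
to the largest *event* time; when the largest observation is censored (the
usual case here) the restricted mean underestimates the unrestricted mean —
documented, and τ is overridable. The variance is
[Σ_j A_j² d_j/(n_j(n_j−d_j))] · m/(m−1) with A_j = ∫_{t_j}^τ Ŝ dt and m the
event count; the m/(m−1) bias-correction factor matches SAS PROC LIFETEST,
which produced the reference estimates this pipeline mirrors, and can be
switched off to compare against R's `survival::survfit`, whose `se(rmean)`
omits it (the test suite checks both routes, lifelines for Ŝ/Greenwood/RMST
and R for the SE). The median is reported as NaN ("not reached") when Ŝ
never crosses 0.5. 95% limits are mean ± 1.96·SE; the reference table's
printed control limits are mildly inconsistent with its own SEs, and no
attempt is made to reverse-engineer them.

## Descriptives, profiles, SSD

Daily counts are bucketed by JST calendar day with zero-filled missing days.
Descriptives follow the conventions of the tools behind the reference tables:
t-based 95% CI for the mean; bias-corrected sample skewness and *excess*
kurtosis; percentiles by linear interpolation between order statistics (the
rule is recorded in the output). Constant series get skewness/kurtosis 0 with
a `degenerate` flag rather than NaNs.

"Normalized" series are z-scores (sample SD, ddof=1); min-max is available as
an alternative. The SSD between two z-scored series of length n equals
2(n−1)(1−r) with r the Pearson correlation, so the ranking of monitoring
posts by SSD is exactly a ranking by correlation with tweet volume —
scale-free and comparable across posts with very different absolute dose
levels. Dose daily means average whatever 10-minute ticks exist (missing
ticks are ignored, not imputed); days missing on either side are dropped
pairwise, and the full pairwise-complete overlap is used.

## Synthetic corpus: what it emulates

The generator is the package's test bed; its defaults are calibrated to the
published corpus summaries so that scaled-down runs reproduce their shape.

| parameter | default | rationale |
|---|---|---|
| `base_rate` | 16.2/366 tweets/user/day | published tweets-per-ID over the year |
| `rate_dispersion` | gamma shape 0.1 | reproduces the per-ID percentile table (median 2, p75 ≈ 6–8, p99 ≈ 250) |
| `keyword_hazards` | λ solving 1−e^(−366λ) = published adopter share | 75.32% (放射能), 60.84% (放射線), 9.20% (Sv), 4.54% (Bq), 1.46% (Gy) |
| `keyword_prob` | 0.2 | post-adoption keyword-inclusion probability; unpublished, exposed in config |
| `retweet_prob` | 0.5121 | published retweet share |
| `bot_fraction` / `bot_keyword_rate` | 1% / 1 per day | ≈1% of IDs auto-posted >200 keyword tweets/year |
| `trend_surge`, `trend_halflife_days` | 6.5, 10 d | day-0 volume ≈7.5× the yearly mean, decaying to a stable baseline within ~2 months |
| `spikes` | 2011-09-10, 2011-10-13, ×3 | news-driven count spikes |
| diurnal profile | 4–5 a.m. trough, noon peak, evening bump | hourly activity pattern |
| dose series | level·2^(−t/halflife)·e^(σZ), 10-min ticks | exponentially decaying air dose rate per post |

Mechanics that make ground truth analytic: each user draws a per-keyword
adoption time from the hazard (exponential by default, Weibull shape
optional) and emits a keyword tweet *exactly* at that time; background tweets
include the keyword only strictly after it. First-occurrence times in the
event table therefore equal the sampled adoption times, so the estimated
attenuation period can be checked against the closed-form
∫₀^τ e^(−λt) dt = (1−e^(−λτ))/λ. Bots post a fixed-clock-time daily report
containing 放射線/放射能/Sv from day 0; ground-truth adoption for those
keywords is the minimum of the sampled time and the first auto-post.

What the generator does **not** emulate — and hence what passing tests do not
establish about real data: natural Japanese text (tweets are template
strings); follower/retweet network structure; geographic heterogeneity;
media-driven *adoption* dynamics. The last point matters: real first-tweet
incidence was strongly front-loaded by the accident coverage, so the real
mean attenuation period for 放射能 (≈1 month) is far shorter than the
constant-hazard value implied by the same adopter share (≈190 days). The
generator reproduces adopter shares, volume shape and censoring structure,
not the published means themselves, which is why the acceptance checks are
arithmetic identities plus parameter recovery rather than replication of the
headline means — the raw corpus is proprietary and not deposited.

Users whose sampled activity is zero and who never adopt a keyword emit no
tweet and are invisible to the pipeline, exactly as a silent account is
invisible in a real corpus; population-level adopter shares are therefore
checked against generator ground truth, not against the event table.

## Problem sizes and numerics

Default synthetic runs use 10,000 users (≈170k tweets), the scale at which
binomial/Greenwood standard errors make 3-SE recovery checks informative;
the SSD experiment uses 100 replicates of 1,000 users against 8 posts with
half-lives geometrically spaced over 8–120 days and 10% lognormal noise.
The full-scale Kaplan-Meier identity check runs at the real risk-set size
(1,168,542) with 500 distinct event times, which leaves the identity exact
to ~1e−13 while keeping the sort cheap. Oracle equivalence against lifelines
uses 1,000 random small instances (n ≤ 25, rounded times to force ties) at
1e−10 relative tolerance.

Degenerate inputs: empty corpora yield empty tables (N=0); all-censored
curves are flat at 1 and have no restricted mean; zero-variance series cannot
be z-scored and raise; malformed tweet rows are dropped and counted, fatal
only above a 1% error rate.
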