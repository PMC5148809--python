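# concernsurv

Survival-analysis pipeline for estimating how long public concern about a
topic persists on social media, built for the corpus of Japanese tweets
posted in the year after the 2011-03-11 Fukushima Dai-ichi nuclear accident.

## The problem and the method

After a radiological emergency, the duration of public concern matters for
risk communication, but it is hard to measure directly. This package
operationalizes it as a time-to-event problem over a tweet log:

* **Event**: the *first* tweet by a given user ID whose text contains a
  radiation keyword (defaults: 放射線 "radiation", 放射能 "radioactive", and
  the units `Sv`, `Bq`, `Gy`, matched as case-sensitive substrings so `mSv`
  and `μSv` count as `Sv` mentions). Each keyword is its own endpoint.
* **Censoring**: a user who never posts the keyword inside the study window
  (default 2011-03-11 to 2012-03-10 JST, 366 days) is censored at the
  window's end. Observation starts at the window origin for every user.
* **Estimator**: the Kaplan-Meier survival function S(t) of first keyword
  occurrence, S(t) = ∏_{t_j ≤ t} (1 − d_j/n_j), with Greenwood variance, and
  the **restricted mean survival time** ∫₀^τ S(t) dt (τ defaulting to the
  largest event time) reported as the **mean attenuation period** of concern,
  with the PROC-LIFETEST-style standard error
  √( [Σ_j A_j² d_j/(n_j(n_j−d_j))] · m/(m−1) ), A_j = ∫_{t_j}^τ S dt.

Around the estimator the package provides: chunked CSV readers for tweet logs
and monitoring-post dose series, corpus descriptives (daily counts, t-based
CIs, skewness/excess kurtosis, per-ID percentiles), hourly-by-weekday and
keyword-proportion activity profiles, a frequency-threshold bot flagger
(> 200 keyword tweets per year), a z-score sum-of-squared-differences (SSD)
comparison of daily tweet volume against air-dose-rate series from
monitoring posts, and a synthetic corpus generator with analytically known
ground truth (exponential/Weibull keyword-adoption hazards, diurnal and
weekday profiles, volume surge and news-day spikes, heavy-tailed per-user
rates, a bot subpopulation, lognormal-noise dose decay).

## Worked example

Simulate a 2,000-user corpus under the default (calibrated) conditions, build
the event table, and estimate the per-keyword attenuation periods:

```python
import pandas as pd
from concernsurv import SynthConfig
from concernsurv.pipeline import PipelineConfig, run

cfg = PipelineConfig(output_dir="demo", synth=SynthConfig(n_users=2000), seed=42)
run(cfg, ["simulate", "detect", "survive"])
print(pd.read_csv("demo/attenuation.csv").round(3).to_string(index=False))
```

Output:

```
keyword  n_ids  events  censored  pct_censored  mean_days  se_days  ci_lower  ci_upper
    放射線   1895    1215       680         35.88    231.856    3.012   225.953   237.760
    放射能   1895    1553       342         18.05    176.960    2.915   171.247   182.674
     Sv   1895     212      1683         88.81    337.837    1.760   334.387   341.287
     Bq   1895      73      1822         96.15    353.908    0.922   352.101   355.715
     Gy   1895      32      1863         98.31    357.043    0.610   355.849   358.238
```

Each row is one keyword endpoint: of the 1,895 user IDs observed in this
synthetic corpus, 1,553 (82.0%) eventually tweeted 放射能 and 342 were
censored at day 366; the restricted-mean time to a user's first 放射能 tweet
is 177.0 days (SE 2.9). Under the generator's exponential-adoption defaults
the common keywords (放射線, 放射能) attenuate much faster than the rare
radiation units — the qualitative ordering seen in the real corpus. (The
real corpus showed even shorter means for the common keywords because early
volume there was front-loaded far more strongly than a constant hazard
implies; see `docs/methods.md`.)

The same run from a shell:

```sh
concernsurv simulate detect survive --out demo --seed 42
concernsurv timeseries report --out demo   # descriptives, SSD, plots
concernsurv --show-config                  # all defaults
```

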