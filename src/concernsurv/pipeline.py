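"""Staged pipeline orchestration: simulate → detect → survive → timeseries → report.

Each stage reads its inputs from the output directory (or the configured
corpus paths), writes CSV artifacts, and records row counts and timings in a
JSON run manifest.  Reruns with the same config and seed reproduce identical
artifacts byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .corpus_io import JST, StudyWindow, read_dose, read_tweet_frames, write_dose, write_tweets
from .event_detection import (
    DEFAULT_KEYWORDS,
    EventTable,
    KeywordSet,
    build_event_table,
    flag_bots,
)
from .survival import compare_curves, kaplan_meier, restricted_mean
from .synthetic_corpus import SynthConfig, generate_corpus_frame, generate_dose_series
from .timeseries import (
    daily_counts,
    daily_dose_means,
    descriptive_stats,
    hourly_weekday_profile,
    keyword_proportion_profile,
    per_id_percentiles,
    ssd,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "detect", "survive", "timeseries", "report")


class StageDependencyError(RuntimeError):
    """A stage's input artifact is missing."""


@dataclass
class PipelineConfig:
    """Everything a full run needs; loadable from YAML."""

    output_dir: Path = Path("concernsurv_out")
    tweets_path: Path | None = None
    dose_path: Path | None = None
    window: StudyWindow = field(default_factory=StudyWindow)
    keywords: tuple[str, ...] = DEFAULT_KEYWORDS
    synth: SynthConfig | None = None
    bot_threshold: int = 200
    normalization: str = "zscore"
    tau: float | None = None
    seed: int = 0

    def keyword_set(self) -> KeywordSet:
        return KeywordSet(tuple(self.keywords))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: Mapping) -> "PipelineConfig":
        errors: list[str] = []
        kwargs: dict = {}
        if "output_dir" in raw:
            kwargs["output_dir"] = Path(raw["output_dir"])
        for key in ("tweets_path", "dose_path"):
            if raw.get(key):
                kwargs[key] = Path(raw[key])
        if "window" in raw:
            w = raw["window"]
            try:
                kwargs["window"] = StudyWindow(
                    start=_parse_dt(w["start"]), end=_parse_dt(w["end"])
                )
            except (KeyError, ValueError) as exc:
                errors.append(f"window: {exc}")
        if "keywords" in raw:
            kwargs["keywords"] = tuple(raw["keywords"])
        if "synth" in raw and raw["synth"] is not None:
            try:
                kwargs["synth"] = _synth_from_mapping(raw["synth"])
            except (TypeError, ValueError) as exc:
                errors.append(f"synth: {exc}")
        for key in ("bot_threshold", "seed"):
            if key in raw:
                kwargs[key] = int(raw[key])
        if "normalization" in raw:
            if raw["normalization"] not in ("zscore", "minmax"):
                errors.append("normalization: must be zscore or minmax")
            else:
                kwargs["normalization"] = raw["normalization"]
        if raw.get("tau") is not None:
            kwargs["tau"] = float(raw["tau"])
        if errors:
            raise ValueError("invalid pipeline config: " + "; ".join(errors))
        return cls(**kwargs)

    def show(self) -> str:
        d = dataclasses.asdict(self)
        d["window"] = {"start": str(self.window.start), "end": str(self.window.end)}
        d["output_dir"] = str(self.output_dir)
        for k in ("tweets_path", "dose_path"):
            if d[k] is not None:
                d[k] = str(d[k])
        if self.synth is not None:
            s = dataclasses.asdict(self.synth)
            s["study_start"] = str(self.synth.study_start)
            s["study_end"] = str(self.synth.study_end)
            s["diurnal_profile"] = [round(float(x), 6) for x in s["diurnal_profile"]]
            d["synth"] = s
        return yaml.safe_dump(d, allow_unicode=True, sort_keys=False)


def _parse_dt(value) -> datetime:
    ts = pd.Timestamp(value)
    if ts.tz is None:
        ts = ts.tz_localize(JST)
    return ts.to_pydatetime()


def _synth_from_mapping(raw: Mapping) -> SynthConfig:
    kwargs = dict(raw)
    for key in ("study_start", "study_end"):
        if key in kwargs:
            kwargs[key] = _parse_dt(kwargs[key])
    if "spikes" in kwargs:
        kwargs["spikes"] = [tuple(s) for s in kwargs["spikes"]]
    cfg = SynthConfig(**kwargs)
    cfg.validate()
    return cfg


def run(config: PipelineConfig, stages: Sequence[str]) -> dict:
    """Run the requested stages in order; returns the run manifest."""
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}")
    stages = [s for s in STAGES if s in stages]
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "stages": {},
        "artifacts": {},
    }
    manifest_path = out / "run_manifest.json"
    if manifest_path.exists():
        with open(manifest_path, encoding="utf-8") as fh:
            prev = json.load(fh)
        manifest["artifacts"] = prev.get("artifacts", {})
        manifest["stages"] = prev.get("stages", {})

    for stage in stages:
        t0 = time.perf_counter()
        counts = _STAGE_FUNCS[stage](config, out, manifest)
        manifest["stages"][stage] = {
            "elapsed_s": round(time.perf_counter() - t0, 3),
            "rows": counts,
        }
        logger.info("stage %s done in %.2fs", stage, manifest["stages"][stage]["elapsed_s"])

    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _tweets_source(config: PipelineConfig, out: Path) -> Path:
    if config.tweets_path is not None:
        return Path(config.tweets_path)
    cand = out / "tweets.csv"
    if not cand.exists():
        raise StageDependencyError(
            "tweet log not found: run the simulate stage or set tweets_path"
        )
    return cand


def _dose_source(config: PipelineConfig, out: Path) -> Path:
    if config.dose_path is not None:
        return Path(config.dose_path)
    cand = out / "dose.csv"
    if not cand.exists():
        raise StageDependencyError(
            "dose series not found: run the simulate stage or set dose_path"
        )
    return cand


def _stage_simulate(config: PipelineConfig, out: Path, manifest: dict) -> dict:
    synth = config.synth or SynthConfig()
    synth = dataclasses.replace(synth, rng_seed=config.seed)
    frame, gt = generate_corpus_frame(synth)
    n = write_tweets(frame, out / "tweets.csv")
    gt.to_csv(out / "ground_truth.csv")
    # posts at different distances show different apparent decay and noise
    doses = generate_dose_series(
        synth,
        n_posts=8,
        decay_halflife_days=np.geomspace(8.0, 120.0, 8),
        noise_sd=0.1,
    )
    n_dose = write_dose(doses, out / "dose.csv")
    manifest["artifacts"]["tweets"] = str(out / "tweets.csv")
    manifest["artifacts"]["ground_truth"] = str(out / "ground_truth.csv")
    manifest["artifacts"]["dose"] = str(out / "dose.csv")
    return {"tweets": n, "dose_ticks": n_dose, "users": synth.n_users}


def _stage_detect(config: PipelineConfig, out: Path, manifest: dict) -> dict:
    src = _tweets_source(config, out)
    ks = config.keyword_set()
    table = build_event_table(read_tweet_frames(src), ks, config.window)
    table.to_csv(out / "event_table.csv")
    flags = flag_bots(read_tweet_frames(src), ks, config.bot_threshold, config.window)
    flags.to_csv(out / "bot_flags.csv")
    manifest["artifacts"]["event_table"] = str(out / "event_table.csv")
    manifest["artifacts"]["bot_flags"] = str(out / "bot_flags.csv")
    return {
        "event_rows": len(table.df),
        "n_ids": table.n_ids,
        "flagged_bots": int(flags.df["flagged"].sum()),
    }


def _stage_survive(config: PipelineConfig, out: Path, manifest: dict) -> dict:
    path = out / "event_table.csv"
    if not path.exists():
        raise StageDependencyError("survive requires the detect stage's event_table.csv")
    table = EventTable.read_csv(
        path, origin=config.window.start, window_days=config.window.length_days
    )
    curves = []
    estimates = []
    for kw in config.keywords:
        sub = table.df.loc[table.df["keyword"] == kw]
        if not len(sub) or not (sub["status"] == "event").any():
            logger.warning("survive: no events for keyword %s; skipped", kw)
            continue
        curve = kaplan_meier(table, kw)
        curves.append(curve)
        estimates.append(restricted_mean(curve, tau=config.tau).to_row())
    if not curves:
        raise StageDependencyError("survive: no keyword had any event")
    compare_curves(curves).to_csv(out / "survival_curves.csv", index=False)
    pd.DataFrame(estimates).to_csv(out / "attenuation.csv", index=False)
    manifest["artifacts"]["survival_curves"] = str(out / "survival_curves.csv")
    manifest["artifacts"]["attenuation"] = str(out / "attenuation.csv")
    return {"curves": len(curves)}


def _stage_timeseries(config: PipelineConfig, out: Path, manifest: dict) -> dict:
    src = _tweets_source(config, out)
    ks = config.keyword_set()
    window = config.window

    dc = daily_counts(read_tweet_frames(src), window)
    dc.to_csv(out / "daily_counts.csv", index=False)
    desc = pd.DataFrame(
        {
            "tweets": descriptive_stats(dc["n_tweets"]).to_series(),
            "ids": descriptive_stats(dc["n_users"]).to_series(),
        }
    )
    desc.to_csv(out / "descriptives.csv")
    per_id_percentiles(read_tweet_frames(src)).to_csv(out / "per_id_percentiles.csv")
    hourly_weekday_profile(read_tweet_frames(src)).to_csv(out / "hourly_weekday_profile.csv")
    keyword_proportion_profile(read_tweet_frames(src), ks).to_csv(
        out / "keyword_proportions.csv"
    )
    rows = {"days": len(dc), "total_tweets": int(dc["n_tweets"].sum())}

    try:
        dose_path = _dose_source(config, out)
    except StageDependencyError:
        dose_path = None
    if dose_path is not None:
        doses = read_dose(dose_path)
        dd = daily_dose_means(doses)
        result = ssd(dc, dd, method=config.normalization)
        result.to_frame().to_csv(out / "ssd.csv", index=False)
        manifest["artifacts"]["ssd"] = str(out / "ssd.csv")
        rows["ssd_posts"] = len(result.ssd)
        rows["best_post"] = result.best_post
    for name in (
        "daily_counts",
        "descriptives",
        "per_id_percentiles",
        "hourly_weekday_profile",
        "keyword_proportions",
    ):
        manifest["artifacts"][name] = str(out / f"{name}.csv")
    return rows


def _stage_report(config: PipelineConfig, out: Path, manifest: dict) -> dict:
    needed = ["daily_counts.csv", "survival_curves.csv"]
    missing = [n for n in needed if not (out / n).exists()]
    if missing:
        raise StageDependencyError(
            f"report requires artifacts from earlier stages: missing {missing}"
        )
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dc = pd.read_csv(out / "daily_counts.csv", parse_dates=["date"])
    fig, ax = plt.subplots(figsize=(9, 4))
    ax.plot(dc["date"], dc["n_tweets"], lw=0.8)
    ax.set_xlabel("date")
    ax.set_ylabel("tweets/day")
    ax.set_title("Daily tweet count")
    fig.autofmt_xdate()
    fig.savefig(out / "daily_counts.png", dpi=120)
    plt.close(fig)

    curves = pd.read_csv(out / "survival_curves.csv")
    fig, ax = plt.subplots(figsize=(7, 5))
    for kw, grp in curves.groupby("keyword"):
        ax.step(
            np.r_[0, grp["time_days"].values],
            np.r_[1.0, grp["survival"].values],
            where="post",
            label=str(kw),
        )
    ax.set_xlabel("days since study origin")
    ax.set_ylabel("S(t): not yet posted keyword")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.savefig(out / "km_curves.png", dpi=120)
    plt.close(fig)

    manifest["artifacts"]["daily_counts_plot"] = str(out / "daily_counts.png")
    manifest["artifacts"]["km_plot"] = str(out / "km_curves.png")
    return {"plots": 2}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "detect": _stage_detect,
    "survive": _stage_survive,
    "timeseries": _stage_timeseries,
    "report": _stage_report,
}
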