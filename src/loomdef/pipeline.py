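"""End-to-end orchestration: stimulus -> simulate/score -> link, as one run.

A run is fully specified by a :class:`RunConfig` (serializable to YAML/JSON;
round-trips unchanged) and a seed.  ``run_pipeline`` executes the requested
stages in order and writes a machine-readable ``summary.json`` containing the
cohort behavioral statistics and outcome probabilities, per-bank adaptation
profiles and evoked-rate comparisons, and the linking statistics (adaptation
vs. escape-latency CDF and freezing-probability curve).  Identical config and
seed give byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import behavior, ephys, stats, synth
from .behavior import ArenaConfig
from .stimulus import StimulusSpec, synth_crescendo_train, stimulus_windows
from .synth import BehaviorGenParams, EphysGenParams

__all__ = ["RunConfig", "run_pipeline", "ConfigError", "DataError"]


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Missing or inconsistent stage inputs (CLI exit code 3)."""


@dataclass
class RunConfig:
    """All thresholds and stage toggles of one pipeline run.

    Threshold defaults equal the published criteria where one exists:
    freezing < 2 cm/s for >= 1 s, escape margin 10% over the 5-s baseline top
    speed, 15-s nest-time window.
    """

    seed: int = 1
    run_behavior: bool = True
    run_ephys: bool = True
    run_link: bool = True
    # stimulus
    stimulus: dict[str, Any] = field(default_factory=dict)
    # behavior thresholds
    freezing_threshold_cm_s: float = 2.0
    freezing_min_s: float = 1.0
    escape_margin: float = 0.10
    baseline_window_s: float = 5.0
    nest_window_s: float = 15.0
    smooth_window_s: float = 0.15
    stop_tolerance_s: float = 0.5
    # analysis
    psth_bin_s: float = 0.010
    tone_psth_bin_s: float = 0.005
    ephys_n_trials: int = 5
    # generators
    behavior_gen: dict[str, Any] = field(default_factory=dict)
    ephys_ts: dict[str, Any] = field(default_factory=dict)
    ephys_sc: dict[str, Any] = field(default_factory=dict)
    arena: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def paper_defaults(cls, seed: int = 1) -> "RunConfig":
        """The frozen default profile: published thresholds, calibrated generators."""
        return cls(seed=seed)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def _behavior_stage(config: RunConfig, summary: dict) -> dict:
    arena = ArenaConfig(**config.arena)
    params = BehaviorGenParams(**{"seed": config.seed, **config.behavior_gen})
    cohort = synth.simulate_cohort(params, arena)
    trials = []
    for traj, truth in cohort:
        trials.append(behavior.score_trial(
            traj, arena, truth.stim_onset_s,
            stim_duration_s=params.stim_duration_s,
            smooth_window_s=config.smooth_window_s,
            freezing_threshold_cm_s=config.freezing_threshold_cm_s,
            freezing_min_s=config.freezing_min_s,
            baseline_window_s=config.baseline_window_s,
            escape_margin=config.escape_margin,
            stop_tolerance_s=config.stop_tolerance_s,
            nest_window_s=config.nest_window_s))
    cohort_stats = behavior.summarize_cohort(trials)
    summary["behavior"] = {
        "n_animals": cohort_stats.n,
        "means": cohort_stats.means,
        "sems": cohort_stats.sems,
        "counts": cohort_stats.counts,
        "outcome_counts": cohort_stats.outcome_counts,
        "outcome_percent": cohort_stats.outcome_percent,
        "trials": [dataclasses.asdict(t) for t in trials],
        "truth": [dataclasses.asdict(t) for _, t in cohort],
    }
    return {"trials": trials, "cohort": cohort}


def _ephys_stage(config: RunConfig, summary: dict) -> dict:
    spec = StimulusSpec(**config.stimulus)
    train = synth_crescendo_train(spec, seed=config.seed)
    windows = stimulus_windows(train)
    banks = {}
    for name, overrides, offset in (("TS", config.ephys_ts, 11),
                                    ("SC", config.ephys_sc, 22)):
        params = EphysGenParams.defaults(name, **overrides)
        recs, truths = synth.simulate_unit_bank(params, train,
                                                n_trials=config.ephys_n_trials,
                                                seed=config.seed + offset)
        profiles = [ephys.evoked_rates(rec, windows) for rec in recs]
        rates = np.array([p.evoked_rate_hz for p in profiles])
        first_two = rates[:, :2].mean(axis=1)
        mean_profile = rates.mean(axis=0)
        banks[name] = {
            "recs": recs, "profiles": profiles, "first_two": first_two,
            "params": params,
        }
        summary.setdefault("ephys", {})[name] = {
            "n_units": len(recs),
            "mean_evoked_first_two_hz": float(first_two.mean()),
            "sem_evoked_first_two_hz": float(first_two.std(ddof=1) / np.sqrt(len(recs))),
            "target_hz": params.target_rate_mean_hz,
            "mean_profile_hz": mean_profile,
            "adaptation_profile": ephys.adaptation_profile(mean_profile),
        }
    t_res = stats.group_tests([banks["TS"]["first_two"], banks["SC"]["first_two"]],
                              "two_sample_t")
    summary["ephys"]["ts_vs_sc_t_test"] = dataclasses.asdict(t_res)
    summary["ephys"]["windows"] = windows
    return banks


def _link_stage(config: RunConfig, summary: dict, banks: dict,
                behavior_out: dict | None) -> None:
    windows = summary["ephys"]["windows"]
    mids = [(a + b) / 2.0 for a, b in windows]
    ts_profile = np.asarray(summary["ephys"]["TS"]["adaptation_profile"], dtype=float)
    latencies, censored = synth.simulate_coupled_escape_latencies(
        ts_profile, mids, n_animals=32, seed=config.seed + 7)
    ecdf = stats.escape_latency_cdf(latencies, mids)
    corr = stats.pearson_corr(ts_profile, ecdf.cdf)
    link = {
        "ts_adaptation_vs_escape_cdf": dataclasses.asdict(corr),
        "escape_cdf": ecdf.cdf,
        "n_censored": censored,
        "window_midpoints_s": mids,
    }
    if behavior_out is not None:
        episodes = []
        for t, truth in zip(behavior_out["trials"],
                            summary["behavior"]["truth"]):
            eps = [(on - truth["stim_onset_s"], off - truth["stim_onset_s"])
                   for on, off in t.freezing_episodes]
            episodes.append(eps)
        freeze_curve = stats.freezing_probability_curve(episodes, mids)
        if np.std(freeze_curve) > 0:
            link["ts_adaptation_vs_freezing_prob"] = dataclasses.asdict(
                stats.pearson_corr(ts_profile, freeze_curve))
        link["freezing_probability"] = freeze_curve
    summary["link"] = link


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the requested stages and write ``summary.json`` in ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    spec = StimulusSpec(**config.stimulus)
    train = synth_crescendo_train(spec, seed=config.seed)
    summary["stimulus"] = {
        "total_duration_s": train.total_duration_s,
        "n_windows": len(train.windows),
        "windows": train.windows,
    }
    behavior_out = None
    banks = None
    if config.run_behavior:
        behavior_out = _behavior_stage(config, summary)
    if config.run_ephys:
        banks = _ephys_stage(config, summary)
    if config.run_link:
        if banks is None:
            raise DataError("link stage requires the ephys stage")
        _link_stage(config, summary, banks, behavior_out)
    payload = _jsonable(summary)
    (out_dir / "summary.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    return payload
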