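"""Rule-based scoring of freezing, escape and nest time from open-field trajectories.

Conventions (all configurable):

* freezing: smoothed locomotion speed consistently below 2 cm/s for >= 1 s;
* escape: an uninterrupted post-stimulus run terminating in the nest or a
  corner zone whose peak speed exceeds the pre-stimulus 5-s top speed by >=10%;
* normalized top speed: peak speed during the stimulus train divided by the
  peak speed in the 5 s before it;
* nest time: dwell time in nest-or-corner during the 15 s after the train.

Escape onset is marked in real data at the head-turn video frame; from centroid
data we use the last sub-threshold sample before the qualifying run as a
surrogate and record it as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

__all__ = [
    "ArenaConfig",
    "Trajectory",
    "SpeedTrace",
    "TrialSummary",
    "EscapeEvent",
    "CohortSummary",
    "compute_speed",
    "detect_freezing",
    "detect_escape",
    "normalized_top_speed",
    "nest_time",
    "classify_outcome",
    "score_trial",
    "summarize_cohort",
    "adaptation_across_trials",
]

FREEZING_ESCAPE = "freezing_escape"
ESCAPE_ONLY = "escape_only"
FREEZING_ONLY = "freezing_only"
NONE = "none"
OUTCOMES = (FREEZING_ESCAPE, ESCAPE_ONLY, FREEZING_ONLY, NONE)


@dataclass(frozen=True)
class ArenaConfig:
    """Open-field geometry: a 48 x 48 cm box with a corner nest.

    The nest is a disc; each corner additionally carries a square "corner
    zone" of side ``corner_margin_cm`` (the paper counts shelter-or-corner for
    nest time).  ``center_zone`` is the stimulus trigger rectangle
    ``(x0, y0, x1, y1)``.  Origin at the lower-left corner, cm units.
    """

    width_cm: float = 48.0
    height_cm: float = 48.0
    nest_center: tuple[float, float] = (6.0, 6.0)
    nest_radius_cm: float = 5.0
    corner_margin_cm: float = 8.0
    center_zone: tuple[float, float, float, float] = (16.0, 16.0, 32.0, 32.0)

    def __post_init__(self) -> None:
        if min(self.width_cm, self.height_cm, self.nest_radius_cm,
               self.corner_margin_cm) <= 0:
            raise ValueError("arena lengths must be > 0")
        nx, ny = self.nest_center
        if not (0 <= nx <= self.width_cm and 0 <= ny <= self.height_cm):
            raise ValueError("nest must lie inside the arena")
        x0, y0, x1, y1 = self.center_zone
        if not (0 <= x0 < x1 <= self.width_cm and 0 <= y0 < y1 <= self.height_cm):
            raise ValueError("center zone must lie inside the arena")

    def in_nest(self, x, y) -> np.ndarray:
        nx, ny = self.nest_center
        return (np.asarray(x) - nx) ** 2 + (np.asarray(y) - ny) ** 2 <= self.nest_radius_cm ** 2

    def in_corner(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        m = self.corner_margin_cm
        near_x = (x <= m) | (x >= self.width_cm - m)
        near_y = (y <= m) | (y >= self.height_cm - m)
        return near_x & near_y

    def in_refuge(self, x, y) -> np.ndarray:
        """Nest-or-corner membership (the nest-time zone)."""
        return self.in_nest(x, y) | self.in_corner(x, y)

    def in_center_zone(self, x, y) -> np.ndarray:
        x0, y0, x1, y1 = self.center_zone
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)


@dataclass
class Trajectory:
    """Timestamped 2-D positions in cm."""

    times_s: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray
    frame_rate_hz: float = 20.0

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.x_cm = np.asarray(self.x_cm, dtype=float)
        self.y_cm = np.asarray(self.y_cm, dtype=float)
        if not (len(self.times_s) == len(self.x_cm) == len(self.y_cm)):
            raise ValueError("times, x and y must have equal length")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def position_at(self, t: float) -> tuple[float, float]:
        return (float(np.interp(t, self.times_s, self.x_cm)),
                float(np.interp(t, self.times_s, self.y_cm)))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.times_s, "x_cm": self.x_cm,
                      "y_cm": self.y_cm}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, frame_rate_hz: float | None = None) -> "Trajectory":
        df = pd.read_csv(path)
        fr = frame_rate_hz or 1.0 / float(np.median(np.diff(df["time_s"])))
        return cls(df["time_s"].to_numpy(), df["x_cm"].to_numpy(),
                   df["y_cm"].to_numpy(), frame_rate_hz=fr)


@dataclass
class SpeedTrace:
    """Instantaneous speed (cm/s) at frame-interval midpoints."""

    times_s: np.ndarray
    speed_cm_s: np.ndarray
    smoothing: str = "none"

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.times_s)))


@dataclass
class EscapeEvent:
    onset_s: float
    latency_s: float
    top_speed_cm_s: float
    onset_definition: str = "surrogate:last-subthreshold-sample"


@dataclass
class TrialSummary:
    """Per-trial behavioral metrics; missing metrics are ``None``."""

    freezing_duration_s: Optional[float]
    freezing_onset_s: Optional[float]
    escape_latency_s: Optional[float]
    normalized_top_speed: Optional[float]
    nest_time_s: float
    outcome: str
    freezing_episodes: list[tuple[float, float]] = field(default_factory=list)


def compute_speed(traj: Trajectory, smooth_window_s: float = 0.15) -> SpeedTrace:
    """Finite-difference speed, moving-average smoothed over ``smooth_window_s``.

    Speeds live at frame-interval midpoints; ``smooth_window_s = 0`` returns
    the raw pairwise-displacement speeds.
    """
    if len(traj.times_s) < 2:
        raise ValueError("need at least 2 samples")
    dt = np.diff(traj.times_s)
    disp = np.hypot(np.diff(traj.x_cm), np.diff(traj.y_cm))
    speed = disp / dt
    mid = traj.times_s[:-1] + dt / 2.0
    desc = "none"
    if smooth_window_s > 0:
        n = max(1, int(round(smooth_window_s * traj.frame_rate_hz)))
        if n > 1:
            speed = uniform_filter1d(speed, size=n, mode="nearest")
            desc = f"moving-average:{smooth_window_s}s({n} frames)"
    return SpeedTrace(times_s=mid, speed_cm_s=np.maximum(speed, 0.0), smoothing=desc)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open index pairs ``[i, j)``."""
    if mask.size == 0:
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


def detect_freezing(speed: SpeedTrace, stim_onset_s: float,
                    threshold_cm_s: float = 2.0,
                    min_duration_s: float = 1.0) -> list[tuple[float, float]]:
    """Freezing episodes: maximal sub-threshold runs at/after stimulus onset.

    An episode is kept if its duration (first sub-threshold sample to the
    first supra-threshold sample after it) is at least ``min_duration_s``.
    Returned as ordered, non-overlapping ``(onset_s, offset_s)`` pairs.
    """
    if speed.times_s.size == 0:
        raise ValueError("empty speed trace")
    t = speed.times_s
    v = speed.speed_cm_s
    sel = t >= stim_onset_s
    t = t[sel]
    v = v[sel]
    if t.size == 0:
        return []
    dt = speed.dt
    episodes = []
    for i, j in _runs(v < threshold_cm_s):
        onset = t[i]
        offset = t[j] if j < t.size else t[-1] + dt
        if offset - onset >= min_duration_s - 1e-9:
            episodes.append((float(onset), float(offset)))
    return episodes


def _movement_runs(t: np.ndarray, v: np.ndarray, threshold: float,
                   stop_tolerance_s: float) -> list[tuple[int, int]]:
    """Supra-threshold runs, merged across sub-threshold gaps < stop_tolerance_s."""
    raw = _runs(v >= threshold)
    merged: list[list[int]] = []
    for i, j in raw:
        if merged and t[i] - t[merged[-1][1] - 1] < stop_tolerance_s:
            merged[-1][1] = j
        else:
            merged.append([i, j])
    return [(i, j) for i, j in merged]


def detect_escape(speed: SpeedTrace, traj: Trajectory, arena: ArenaConfig,
                  stim_onset_s: float, baseline_window_s: float = 5.0,
                  margin: float = 0.10, threshold_cm_s: float = 2.0,
                  stop_tolerance_s: float = 0.5) -> Optional[EscapeEvent]:
    """First qualifying escape run after stimulus onset, or ``None``.

    A qualifying run (i) terminates inside the nest or a corner zone, (ii)
    contains no sub-threshold interruption of >= ``stop_tolerance_s``, and
    (iii) peaks at >= ``(1 + margin)`` times the pre-stimulus
    ``baseline_window_s`` top speed.  Latency is measured from stimulus onset
    to the last sub-threshold sample before the run (head-turn surrogate).
    """
    t = speed.times_s
    v = speed.speed_cm_s
    base_sel = (t >= stim_onset_s - baseline_window_s) & (t < stim_onset_s)
    if t.size == 0 or t[0] > stim_onset_s - baseline_window_s + speed.dt:
        raise ValueError("insufficient pre-stimulus baseline coverage")
    baseline_top = float(np.max(v[base_sel]))
    required = (1.0 + margin) * baseline_top

    post = t >= stim_onset_s
    tp = t[post]
    vp = v[post]
    for i, j in _movement_runs(tp, vp, threshold_cm_s, stop_tolerance_s):
        end_t = tp[j - 1]
        x, y = traj.position_at(end_t)
        if not arena.in_refuge(x, y):
            continue
        top = float(np.max(vp[i:j]))
        if top < required:
            continue
        below_before = np.flatnonzero(vp[:i] < threshold_cm_s)
        onset = float(tp[below_before[-1]]) if below_before.size else float(tp[i])
        return EscapeEvent(onset_s=onset,
                           latency_s=max(onset - stim_onset_s, 0.0),
                           top_speed_cm_s=top)
    return None


def normalized_top_speed(speed: SpeedTrace, stim_window: tuple[float, float],
                         baseline_window_s: float = 5.0) -> float:
    """Peak speed during the stimulus train over the pre-stimulus 5-s peak."""
    on, off = stim_window
    t = speed.times_s
    v = speed.speed_cm_s
    stim_sel = (t >= on) & (t < off)
    base_sel = (t >= on - baseline_window_s) & (t < on)
    if not stim_sel.any() or not base_sel.any():
        raise ValueError("speed trace does not cover both windows")
    base_peak = float(np.max(v[base_sel]))
    if base_peak == 0:
        raise ValueError("undefined baseline: animal immobile before stimulus")
    return float(np.max(v[stim_sel])) / base_peak


def nest_time(traj: Trajectory, arena: ArenaConfig, window_start_s: float,
              window_s: float = 15.0) -> float:
    """Dwell time (s) in nest-or-corner within ``[start, start + window_s)``.

    If the trajectory does not cover the full window the result is computed on
    the covered part and a warning is issued.
    """
    t = traj.times_s
    end = window_start_s + window_s
    if t[-1] < end - 1e-9:
        warnings.warn("trajectory does not cover the full nest-time window; truncated")
    inside = arena.in_refuge(traj.x_cm, traj.y_cm)
    # attribute each inter-frame interval to its starting frame
    dt = np.diff(t)
    seg_start = t[:-1]
    seg_end = t[1:]
    overlap = np.clip(np.minimum(seg_end, end) - np.maximum(seg_start, window_start_s), 0.0, None)
    return float(np.sum(overlap * inside[:-1]))


def classify_outcome(episodes: Sequence[tuple[float, float]],
                     escape_event: Optional[EscapeEvent],
                     boundary_tol_s: float = 0.12) -> str:
    """Outcome class from freezing episodes and the escape event.

    The escape-onset surrogate (last sub-threshold sample) sits one frame
    inside the freezing episode it terminates, so onsets within
    ``boundary_tol_s`` of an episode's end count as the boundary; an onset
    deeper inside an episode is a contradiction and raises.
    """
    if escape_event is not None:
        for on, off in episodes:
            if on < escape_event.onset_s < off - boundary_tol_s:
                raise ValueError("escape onset falls inside a freezing episode")
        prior = [e for e in episodes if e[0] <= escape_event.onset_s]
        return FREEZING_ESCAPE if prior else ESCAPE_ONLY
    return FREEZING_ONLY if episodes else NONE


def score_trial(traj: Trajectory, arena: ArenaConfig, stim_onset_s: float,
                stim_duration_s: float = 10.0, smooth_window_s: float = 0.15,
                freezing_threshold_cm_s: float = 2.0, freezing_min_s: float = 1.0,
                baseline_window_s: float = 5.0, escape_margin: float = 0.10,
                stop_tolerance_s: float = 0.5, nest_window_s: float = 15.0,
                analysis_horizon_s: float = 10.0) -> TrialSummary:
    """Full per-trial scoring: freezing, escape, normalized top speed, nest time.

    Freezing duration sums all episodes that begin before the escape onset (or
    all episodes within ``stim_duration_s + analysis_horizon_s`` when there is
    no escape).  The nest-time window starts at stimulus-train offset.
    """
    speed = compute_speed(traj, smooth_window_s)
    episodes = detect_freezing(speed, stim_onset_s, freezing_threshold_cm_s, freezing_min_s)
    horizon = stim_onset_s + stim_duration_s + analysis_horizon_s
    episodes = [e for e in episodes if e[0] < horizon]
    escape = detect_escape(speed, traj, arena, stim_onset_s, baseline_window_s,
                           escape_margin, freezing_threshold_cm_s, stop_tolerance_s)
    if escape is not None:
        episodes = [e for e in episodes if e[0] <= escape.onset_s]
    outcome = classify_outcome(episodes, escape)
    freeze_dur = sum(off - on for on, off in episodes) if episodes else None
    freeze_onset = episodes[0][0] - stim_onset_s if episodes else None
    try:
        nts = normalized_top_speed(speed, (stim_onset_s, stim_onset_s + stim_duration_s),
                                   baseline_window_s)
    except ValueError:
        nts = None
    ntime = nest_time(traj, arena, stim_onset_s + stim_duration_s, nest_window_s)
    return TrialSummary(
        freezing_duration_s=freeze_dur,
        freezing_onset_s=freeze_onset,
        escape_latency_s=escape.latency_s if escape else None,
        normalized_top_speed=nts,
        nest_time_s=ntime,
        outcome=outcome,
        freezing_episodes=episodes,
    )


@dataclass
class CohortSummary:
    n: int
    means: dict[str, float]
    sems: dict[str, float]
    counts: dict[str, int]
    outcome_counts: dict[str, int]
    outcome_percent: dict[str, int]


def _mean_sem(values: list[float]) -> tuple[float, float, int]:
    arr = np.asarray(values, dtype=float)
    n = arr.size
    mean = float(arr.mean()) if n else float("nan")
    sem = float(arr.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return mean, sem, n


def summarize_cohort(trials: Sequence[TrialSummary]) -> CohortSummary:
    """Cohort means ± s.e.m. over non-missing values, plus outcome percentages.

    Outcome probabilities are reported to the nearest percent
    (5/9 -> 56%, 4/9 -> 44%).
    """
    if not trials:
        raise ValueError("empty cohort")
    n = len(trials)
    fields = ["freezing_duration_s", "escape_latency_s", "normalized_top_speed", "nest_time_s"]
    means, sems, counts = {}, {}, {}
    for f in fields:
        vals = [getattr(t, f) for t in trials if getattr(t, f) is not None]
        means[f], sems[f], counts[f] = _mean_sem(vals)
    oc = {o: sum(t.outcome == o for t in trials) for o in OUTCOMES}
    pct = {o: int(round(100.0 * c / n)) for o, c in oc.items()}
    return CohortSummary(n=n, means=means, sems=sems, counts=counts,
                         outcome_counts=oc, outcome_percent=pct)


def adaptation_across_trials(trial_sequences: Sequence[Sequence[TrialSummary]]) -> pd.DataFrame:
    """Per-trial-index outcome probabilities across repeated presentations.

    ``trial_sequences`` holds one ordered list of trial summaries per animal;
    ragged lists are allowed (the denominator at each index is the number of
    animals tested at that index).
    """
    n_trials = max((len(s) for s in trial_sequences), default=0)
    rows = []
    for k in range(n_trials):
        at_k = [s[k] for s in trial_sequences if len(s) > k]
        n = len(at_k)
        row = {"trial": k + 1, "n": n}
        row["p_freezing"] = sum(t.outcome in (FREEZING_ESCAPE, FREEZING_ONLY) for t in at_k) / n
        row["p_escape"] = sum(t.outcome in (FREEZING_ESCAPE, ESCAPE_ONLY) for t in at_k) / n
        for o in OUTCOMES:
            row[f"p_{o}"] = sum(t.outcome == o for t in at_k) / n
        rows.append(row)
    return pd.DataFrame(rows)
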