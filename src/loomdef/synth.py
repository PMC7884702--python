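"""Synthetic trajectories and spike trains with ground-truth labels.

The generator emulates the study conditions every analysis stage assumes:

* open-field exploration at 20 frames/s in a 48 x 48 cm box with a corner
  nest, modeled as a correlated random walk with Ornstein-Uhlenbeck speed
  modulation and reflecting walls;
* a stimulus-triggered freeze-then-escape motor program with cohort-level
  variability calibrated to the reported cohort statistics (freezing duration
  3.0 s, escape latency 3.5 s, normalized top speed 1.6, outcome proportions
  27:4:1:0 out of 32);
* inhomogeneous-Poisson spike trains for five response archetypes (TS
  fast-adapting, SC slow-adapting, cortical On / Sustained / Off) driven by a
  10-repeat crescendo train, with first-two-stimulus evoked-rate targets of
  34.5 Hz (TS) and 16.3 Hz (SC).

Tracking noise is a stationary AR(1) jitter (SD 0.2 cm, per-frame correlation
0.99): centroid jitter in video trackers is strongly temporally correlated,
and an i.i.d. jitter of that amplitude would alias into apparent speeds above
the 2 cm/s freezing criterion, which no usable tracker output does.

Every function is deterministic given (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .behavior import ArenaConfig, Trajectory, compute_speed
from .ephys import TRF, UnitRecording
from .stimulus import StimulusTrain, stimulus_windows

__all__ = [
    "BehaviorGenParams",
    "EphysGenParams",
    "TrialTruth",
    "simulate_trial",
    "simulate_cohort",
    "simulate_unit",
    "simulate_unit_bank",
    "simulate_coupled_escape_latencies",
    "intensity_gain",
    "make_synthetic_trf",
]

OUTCOME_CLASSES = ("freezing_escape", "escape_only", "freezing_only", "none")


# ---------------------------------------------------------------------------
# behavior


@dataclass(frozen=True)
class BehaviorGenParams:
    """Cohort-level parameters of the synthetic freeze-then-escape program.

    Duration/latency scales are the reported cohort statistics; with n = 32
    animals the SDs give cohort s.e.m. of ~0.3 s (freezing) and ~0.4 s
    (latency).  In freezing->escape trials the escape latency is structural:
    freeze-onset delay + freeze duration, with the delay mean derived as
    ``escape_latency_mean_s - freeze_duration_mean_s`` so the two configured
    means are jointly consistent.
    """

    n_animals: int = 32
    freeze_duration_mean_s: float = 3.0
    freeze_duration_sd_s: float = 1.7
    escape_latency_mean_s: float = 3.5
    escape_latency_sd_s: float = 2.2
    escape_speed_gain: float = 1.6          # mean peak-run / baseline-top ratio
    escape_speed_gain_sd: float = 0.55
    escape_speed_gain_min: float = 1.15     # support floor, above the 1.10 detection margin
    p_outcome: tuple[float, float, float, float] = (27 / 32, 4 / 32, 1 / 32, 0.0)
    walk_speed_mean_cm_s: float = 8.0
    walk_speed_sd_cm_s: float = 4.0
    walk_speed_tau_s: float = 1.0
    heading_diffusion_rad_rt_s: float = 1.5
    frame_rate_hz: float = 20.0
    tracking_noise_sd_cm: float = 0.2
    tracking_noise_ar: float = 0.99
    stim_duration_s: float = 10.0
    pre_stim_s: float = 12.0
    post_stim_s: float = 30.0
    min_freeze_s: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.p_outcome) - 1.0) > 1e-9:
            raise ValueError("outcome probabilities must sum to 1")
        if min(self.freeze_duration_mean_s, self.escape_latency_mean_s,
               self.escape_speed_gain, self.frame_rate_hz) <= 0:
            raise ValueError("scales must be > 0")
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")


@dataclass
class TrialTruth:
    """Generator ground truth: sufficient to fill every trial metric without
    re-detection."""

    outcome: str
    stim_onset_s: float
    freeze_onset_s: Optional[float]       # relative to stimulus onset
    freeze_duration_s: Optional[float]
    escape_latency_s: Optional[float]     # relative to stimulus onset (head-turn instant)
    escape_speed_gain: Optional[float]
    baseline_top_speed_cm_s: float
    nest_time_s: float
    run_speed_cm_s: Optional[float]


def _lognormal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """One lognormal draw parameterized by its arithmetic mean and SD."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def _lognormal_at_least(rng: np.random.Generator, mean: float, sd: float,
                        lo: float) -> float:
    for _ in range(1000):
        v = _lognormal(rng, mean, sd)
        if v >= lo:
            return v
    return lo


def _stratified_lognormal(rng: np.random.Generator, mean: float, sd: float,
                          n: int, lo: float = 0.0) -> np.ndarray:
    """``n`` midpoint-quantile draws of the lognormal(mean, sd), permuted.

    Stratified (quantile-matched) sampling keeps the marginal distribution
    and its spread while making a finite cohort representative of the
    configured mean, so round-trip recovery probes the pipeline rather than
    Monte-Carlo luck.  Values are floored at ``lo``.
    """
    from scipy import stats as sps
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    q = sps.lognorm.ppf((np.arange(n) + 0.5) / n, math.sqrt(sigma2),
                        scale=math.exp(mu))
    return rng.permutation(np.maximum(q, lo))


def _stratified_gamma(rng: np.random.Generator, mean: float, sd: float,
                      n: int) -> np.ndarray:
    """``n`` midpoint-quantile draws of the Gamma(mean, sd), permuted."""
    from scipy import stats as sps
    shape = (mean / sd) ** 2
    q = sps.gamma.ppf((np.arange(n) + 0.5) / n, shape, scale=sd ** 2 / mean)
    return rng.permutation(q)


def _largest_remainder_counts(p: Sequence[float], n: int) -> list[int]:
    """Integer class counts allocating ``n`` by largest remainder."""
    raw = np.asarray(p, dtype=float) * n
    counts = np.floor(raw).astype(int)
    order = np.argsort(-(raw - counts))
    for i in range(n - counts.sum()):
        counts[order[i]] += 1
    return counts.tolist()


class _Walker:
    """Correlated random walk with OU speed modulation and reflecting walls."""

    def __init__(self, params: BehaviorGenParams, arena: ArenaConfig,
                 rng: np.random.Generator, x0: float, y0: float):
        self.p = params
        self.arena = arena
        self.rng = rng
        self.dt = 1.0 / params.frame_rate_hz
        self.x, self.y = x0, y0
        self.speed = max(rng.normal(params.walk_speed_mean_cm_s,
                                    params.walk_speed_sd_cm_s), 0.0)
        self.heading = rng.uniform(0, 2 * np.pi)
        self.xs: list[float] = [x0]
        self.ys: list[float] = [y0]

    def _advance(self, speed: float, heading: float) -> None:
        x = self.x + speed * self.dt * math.cos(heading)
        y = self.y + speed * self.dt * math.sin(heading)
        lo, hix, hiy = 1.0, self.arena.width_cm - 1.0, self.arena.height_cm - 1.0
        bounced = False
        if x < lo or x > hix:
            x = min(max(2 * lo - x if x < lo else 2 * hix - x, lo), hix)
            bounced = True
        if y < lo or y > hiy:
            y = min(max(2 * lo - y if y < lo else 2 * hiy - y, lo), hiy)
            bounced = True
        if bounced:
            self.heading = math.atan2(y - self.y, x - self.x)
        self.x, self.y = x, y
        self.xs.append(x)
        self.ys.append(y)

    def step_walk(self, speed_mean: float | None = None) -> None:
        p = self.p
        mu = speed_mean if speed_mean is not None else p.walk_speed_mean_cm_s
        sigma = p.walk_speed_sd_cm_s * math.sqrt(2.0 / p.walk_speed_tau_s)
        self.speed += ((mu - self.speed) * self.dt / p.walk_speed_tau_s
                       + sigma * math.sqrt(self.dt) * self.rng.standard_normal())
        self.speed = max(self.speed, 0.0)
        self.heading += (p.heading_diffusion_rad_rt_s * math.sqrt(self.dt)
                         * self.rng.standard_normal())
        self._advance(self.speed, self.heading)

    def step_toward(self, target: tuple[float, float], speed: float,
                    heading_jitter: float = 0.05) -> None:
        hx = math.atan2(target[1] - self.y, target[0] - self.x)
        self.heading = hx + heading_jitter * self.rng.standard_normal()
        self.speed = speed
        self._advance(speed, self.heading)

    def hold(self) -> None:
        self.speed = 0.0
        self.xs.append(self.x)
        self.ys.append(self.y)

    def n_frames(self) -> int:
        return len(self.xs)


def _smoothed_top_speed(xs: np.ndarray, ys: np.ndarray, fr: float,
                        window_frames: int, smooth_s: float = 0.15) -> float:
    t = np.arange(len(xs)) / fr
    traj = Trajectory(t, xs, ys, frame_rate_hz=fr)
    sp = compute_speed(traj, smooth_s)
    return float(np.max(sp.speed_cm_s[-window_frames:]))


def simulate_trial(params: BehaviorGenParams, outcome_class: str,
                   seed: int | np.random.Generator,
                   arena: ArenaConfig | None = None,
                   freeze_duration_s: float | None = None,
                   escape_latency_s: float | None = None,
                   escape_gain: float | None = None) -> tuple[Trajectory, TrialTruth]:
    """One open-field trial of the assigned outcome class, with ground truth.

    The animal explores, is steered into the center trigger zone (stimulus
    onset), and then executes the assigned motor program: freeze (true speed
    zero plus tracking jitter) for a drawn duration, a ballistic run to the
    nest at ``gain x`` the baseline smoothed top speed, and nest dwell.
    """
    if outcome_class not in OUTCOME_CLASSES:
        raise ValueError(f"unknown outcome class {outcome_class!r}")
    arena = arena or ArenaConfig()
    if not arena.in_refuge(*arena.nest_center):
        raise ValueError("nest/center-zone misconfiguration")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = params
    dt = 1.0 / p.frame_rate_hz
    fr = p.frame_rate_hz

    w = _Walker(p, arena, rng,
                x0=rng.uniform(14, arena.width_cm - 14),
                y0=rng.uniform(14, arena.height_cm - 14))
    for _ in range(int(round(p.pre_stim_s * fr))):
        w.step_walk()
    # steer into the trigger zone
    cz = arena.center_zone
    target = ((cz[0] + cz[2]) / 2.0, (cz[1] + cz[3]) / 2.0)
    for _ in range(int(round(10.0 * fr))):
        if arena.in_center_zone(w.x, w.y):
            break
        w.step_toward(target, max(w.speed, p.walk_speed_mean_cm_s), heading_jitter=0.2)
    stim_onset_idx = w.n_frames() - 1
    stim_onset = stim_onset_idx * dt

    baseline_top = _smoothed_top_speed(np.array(w.xs), np.array(w.ys), fr,
                                       window_frames=int(round(5.0 * fr)))

    freeze_onset = freeze_dur = latency = gain = run_speed = None
    nest_arrival = None
    end_idx = stim_onset_idx + int(round(p.post_stim_s * fr))

    def decelerate(duration_s: float) -> None:
        n = max(int(round(duration_s * fr)), 1)
        v0 = max(w.speed, 3.0)
        for i in range(n):
            v = v0 + (2.2 - v0) * (i + 1) / n
            w._advance(v, w.heading)

    def freeze(duration_s: float) -> None:
        for _ in range(int(round(duration_s * fr))):
            w.hold()

    def run_to_nest(speed: float) -> None:
        nonlocal nest_arrival
        for _ in range(int(round(8.0 * fr))):
            if math.hypot(w.x - arena.nest_center[0], w.y - arena.nest_center[1]) < 1.5:
                break
            w.step_toward(arena.nest_center, speed)
        nest_arrival = (w.n_frames() - 1) * dt

    def dwell_in_nest() -> None:
        while w.n_frames() <= end_idx:
            ang = rng.uniform(0, 2 * np.pi)
            w.step_toward((arena.nest_center[0] + 1.0 * math.cos(ang),
                           arena.nest_center[1] + 1.0 * math.sin(ang)), 0.8)

    if outcome_class in ("freezing_escape", "freezing_only"):
        delay = float(np.clip(rng.normal(p.escape_latency_mean_s - p.freeze_duration_mean_s,
                                         0.15), 0.2, 1.2))
        freeze_dur = (freeze_duration_s if freeze_duration_s is not None else
                      _lognormal_at_least(rng, p.freeze_duration_mean_s,
                                          p.freeze_duration_sd_s, p.min_freeze_s))
        decelerate(delay)
        freeze_onset = (w.n_frames() - 1) * dt - stim_onset
        freeze(freeze_dur)
        if outcome_class == "freezing_escape":
            latency = (w.n_frames() - 1) * dt - stim_onset
            gain = (escape_gain if escape_gain is not None else
                    p.escape_speed_gain_min + _lognormal(
                        rng, p.escape_speed_gain - p.escape_speed_gain_min,
                        p.escape_speed_gain_sd))
            run_speed = gain * baseline_top
            run_to_nest(run_speed)
            dwell_in_nest()
        else:
            # resume a slow exploratory walk away from refuge zones
            w.speed = 3.0
            while w.n_frames() <= end_idx:
                w.step_walk(speed_mean=6.0)
    elif outcome_class == "escape_only":
        lat_target = (max(escape_latency_s, 0.9) if escape_latency_s is not None
                      else _lognormal_at_least(rng, p.escape_latency_mean_s,
                                               p.escape_latency_sd_s, 0.9))
        # head-turn pause: long enough to separate the escape run from prior
        # walking (> stop tolerance) but below the freezing minimum duration
        pause_s = 0.75
        n_walk = max(int(round((lat_target - pause_s) * fr)), 0)
        for _ in range(n_walk):
            w.step_walk()
        decelerate(0.2)
        freeze(pause_s - 0.2)
        latency = (w.n_frames() - 1) * dt - stim_onset
        gain = (escape_gain if escape_gain is not None else
                p.escape_speed_gain_min + _lognormal(
                    rng, p.escape_speed_gain - p.escape_speed_gain_min,
                    p.escape_speed_gain_sd))
        run_speed = gain * baseline_top
        run_to_nest(run_speed)
        dwell_in_nest()
    else:  # none
        while w.n_frames() <= end_idx:
            w.step_walk()

    while w.n_frames() <= end_idx:
        if outcome_class in ("freezing_escape", "escape_only"):
            dwell_in_nest()
        else:
            w.step_walk(speed_mean=6.0)

    xs = np.asarray(w.xs)
    ys = np.asarray(w.ys)
    if p.tracking_noise_sd_cm > 0:
        rho = p.tracking_noise_ar
        innov_sd = p.tracking_noise_sd_cm * math.sqrt(1.0 - rho ** 2)
        noise = np.zeros((len(xs), 2))
        noise[0] = rng.normal(0, p.tracking_noise_sd_cm, 2)
        steps = rng.normal(0, innov_sd, (len(xs) - 1, 2))
        for i in range(1, len(xs)):
            noise[i] = rho * noise[i - 1] + steps[i - 1]
        xs = np.clip(xs + noise[:, 0], 0, arena.width_cm)
        ys = np.clip(ys + noise[:, 1], 0, arena.height_cm)

    times = np.arange(len(xs)) * dt
    traj = Trajectory(times, xs, ys, frame_rate_hz=fr)

    nest_win = (stim_onset + p.stim_duration_s, stim_onset + p.stim_duration_s + 15.0)
    if nest_arrival is not None:
        true_nest = max(0.0, min(nest_win[1], times[-1]) - max(nest_arrival, nest_win[0]))
    else:
        true_nest = 0.0
    truth = TrialTruth(outcome=outcome_class, stim_onset_s=stim_onset,
                       freeze_onset_s=freeze_onset, freeze_duration_s=freeze_dur,
                       escape_latency_s=latency, escape_speed_gain=gain,
                       baseline_top_speed_cm_s=baseline_top, nest_time_s=true_nest,
                       run_speed_cm_s=run_speed)
    return traj, truth


def simulate_cohort(params: BehaviorGenParams,
                    arena: ArenaConfig | None = None,
                    seed: int | None = None) -> list[tuple[Trajectory, TrialTruth]]:
    """A cohort of ``n_animals`` trials with outcome classes drawn from
    ``p_outcome``; per-trial seeds spawned from the cohort seed."""
    if params.n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    p = params
    n = p.n_animals
    root = np.random.SeedSequence(p.seed if seed is None else seed)
    draw_rng = np.random.default_rng(root.spawn(1)[0])
    counts = _largest_remainder_counts(p.p_outcome, n)
    classes = draw_rng.permutation(np.repeat(OUTCOME_CLASSES, counts))
    # stratified per-class draws: the cohort-level composition matches the
    # configured distributions at any n (see _stratified_lognormal)
    n_freeze = counts[0] + counts[2]
    n_escape = counts[0] + counts[1]
    freeze_vals = iter(_stratified_lognormal(draw_rng, p.freeze_duration_mean_s,
                                             p.freeze_duration_sd_s, n_freeze,
                                             lo=p.min_freeze_s)) if n_freeze else iter([])
    gain_vals = iter(p.escape_speed_gain_min + _stratified_lognormal(
        draw_rng, p.escape_speed_gain - p.escape_speed_gain_min,
        p.escape_speed_gain_sd, n_escape)) if n_escape else iter([])
    lat_vals = iter(_stratified_lognormal(draw_rng, p.escape_latency_mean_s,
                                          p.escape_latency_sd_s, counts[1],
                                          lo=0.9)) if counts[1] else iter([])
    out = []
    for cls, child in zip(classes, root.spawn(n + 1)[1:]):
        cls = str(cls)
        kwargs = {}
        if cls in ("freezing_escape", "freezing_only"):
            kwargs["freeze_duration_s"] = float(next(freeze_vals))
        if cls == "escape_only":
            kwargs["escape_latency_s"] = float(next(lat_vals))
        if cls in ("freezing_escape", "escape_only"):
            kwargs["escape_gain"] = float(next(gain_vals))
        out.append(simulate_trial(params, cls, np.random.default_rng(child),
                                  arena, **kwargs))
    return out


# ---------------------------------------------------------------------------
# ephys


_ARCHETYPE_DEFAULTS = {
    # archetype: (target, target_sd, adaptation, profile, latency_ms)
    "TS": (34.5, 26.0, 0.45, "ramp", 20.0),
    "SC": (16.3, 15.6, 0.97, "ramp", 20.0),
    "AC_on": (30.0, 10.0, 1.0, "onset", 21.6),
    "AC_sustained": (30.0, 10.0, 0.85, "ramp", 20.2),
    "AC_off": (25.0, 8.0, 1.0, "offset", 20.0),
}


@dataclass(frozen=True)
class EphysGenParams:
    """Archetype parameters for inhomogeneous-Poisson unit simulation.

    ``target_rate_mean_hz`` is the population-mean raw evoked rate over the
    first two response windows (the reported 34.5 Hz for TS, 16.3 Hz for SC);
    ``target_rate_sd_hz`` the across-unit SD (s.e.m. x sqrt(n) of the
    reported cohorts).  ``adaptation_factor`` multiplies the drive per
    stimulus repeat (geometric decline: 0.45 for fast-adapting TS, 0.97 for
    slow-adapting SC).
    """

    archetype: str = "TS"
    target_rate_mean_hz: float = 34.5
    target_rate_sd_hz: float = 26.0
    adaptation_factor: float = 0.45
    profile: str = "ramp"       # {"ramp", "onset", "offset"}
    onset_latency_ms: float = 20.0
    spontaneous_rate_hz: float = 2.0
    n_units: int = 55
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.adaptation_factor <= 1.5:
            raise ValueError("adaptation_factor must be in (0, 1.5]")
        if min(self.target_rate_mean_hz, self.target_rate_sd_hz) <= 0:
            raise ValueError("rates must be > 0")
        if self.spontaneous_rate_hz < 0:
            raise ValueError("spontaneous rate must be >= 0")

    @classmethod
    def defaults(cls, archetype: str, **overrides) -> "EphysGenParams":
        if archetype not in _ARCHETYPE_DEFAULTS:
            raise ValueError(f"unknown archetype {archetype!r}")
        target, sd, adapt, profile, lat = _ARCHETYPE_DEFAULTS[archetype]
        n_units = {"TS": 55, "SC": 46}.get(archetype, 50)
        base = cls(archetype=archetype, target_rate_mean_hz=target,
                   target_rate_sd_hz=sd, adaptation_factor=adapt, profile=profile,
                   onset_latency_ms=lat, n_units=n_units)
        return replace(base, **overrides) if overrides else base


def intensity_gain(archetype: str, peak_db: float) -> float:
    """Multiplicative drive gain vs. crescendo peak intensity.

    TS-like responses follow an inverted U peaking at 70 dB SPL; SC-like
    responses increase monotonically, saturating towards 90 dB.  Normalized
    to 1 at 70 dB.
    """
    if archetype == "SC":
        return float((1.0 / (1.0 + math.exp(-(peak_db - 70.0) / 8.0))) / 0.5)
    return float(math.exp(-((peak_db - 70.0) ** 2) / (2.0 * 15.0 ** 2)))


def _drive_profile(params: EphysGenParams, train: StimulusTrain,
                   grid: np.ndarray) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Normalized (peak-1 per repeat before adaptation) drive on the time grid,
    plus the response windows used for calibration."""
    lat = params.onset_latency_ms / 1000.0
    g = np.zeros_like(grid)
    windows = stimulus_windows(train)
    resp_windows = []
    for k, (on, off) in enumerate(windows):
        a = params.adaptation_factor ** k
        dur = off - on
        if params.profile == "ramp":
            # onset step + envelope-proportional rise: sustained units show a
            # clear response at latency, then firing grows with the dB ramp
            sel = (grid >= on + lat) & (grid < off + lat)
            u = (grid[sel] - on - lat) / dur
            g[sel] += a * (0.25 + 0.75 * u)
            resp_windows.append((on, off))
        elif params.profile == "onset":
            sel = (grid >= on + lat) & (grid < on + lat + 0.06)
            g[sel] += a * np.exp(-(grid[sel] - on - lat) / 0.015)
            resp_windows.append((on, off))
        elif params.profile == "offset":
            sel = (grid >= off + lat) & (grid < off + lat + 0.08)
            g[sel] += a * np.exp(-(grid[sel] - off - lat) / 0.020)
            resp_windows.append((off, off + 0.1))
        else:
            raise ValueError(f"unknown profile {params.profile!r}")
    return g, resp_windows


def simulate_unit(params: EphysGenParams, train: StimulusTrain, n_trials: int = 5,
                  seed: int | np.random.Generator = 0, deterministic: bool = False,
                  peak_db: float | None = None,
                  unit_target_hz: float | None = None,
                  dt_s: float = 0.001) -> tuple[UnitRecording, dict]:
    """One unit's spike trains across repeated train presentations.

    Intensity: ``spontaneous + drive * adaptation^k * profile(t)`` delayed by
    the onset latency.  The drive is calibrated numerically so the unit's
    expected raw evoked rate over its first two response windows equals the
    unit target (drawn from the archetype's Gamma across-unit distribution
    unless given).  ``deterministic`` replaces Poisson sampling with
    time-rescaled regular spiking (exact expected counts).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pre, post = 1.5, 1.0
    grid = np.arange(-pre, train.total_duration_s + post, dt_s)
    g, resp_windows = _drive_profile(params, train, grid)

    if unit_target_hz is None:
        m, s = params.target_rate_mean_hz, params.target_rate_sd_hz
        shape = (m / s) ** 2
        unit_target_hz = float(rng.gamma(shape, s ** 2 / m))
    # expected raw rate over first two response windows with drive = 1
    dur = sum(b - a for a, b in resp_windows[:2])
    mask = np.zeros_like(grid, dtype=bool)
    for a, b in resp_windows[:2]:
        mask |= (grid >= a) & (grid < b)
    unit_rate = float(np.sum(g[mask]) * dt_s / dur)
    drive = max(unit_target_hz - params.spontaneous_rate_hz, 0.0) / max(unit_rate, 1e-12)
    if peak_db is not None:
        drive *= intensity_gain(params.archetype, peak_db)
    lam = params.spontaneous_rate_hz + drive * g
    lam = np.clip(lam, 0.0, None)

    trial_gap = train.total_duration_s + pre + post + 1.0
    onsets = 2.0 + pre + np.arange(n_trials) * trial_gap
    spikes = []
    for onset in onsets:
        if deterministic:
            cum = np.cumsum(lam) * dt_s
            k = np.arange(1, int(np.floor(cum[-1])) + 1)
            st = np.interp(k - 0.5, cum, grid)
        else:
            counts = rng.poisson(lam * dt_s)
            idx = np.repeat(np.arange(grid.size), counts)
            st = grid[idx] + rng.uniform(0, dt_s, idx.size)
        spikes.append(st + onset)
    rec = UnitRecording(unit_id=f"{params.archetype}", region=params.archetype,
                        spike_times_s=np.concatenate(spikes) if spikes else np.array([]),
                        trial_onsets_s=onsets)
    truth = {"target_hz": unit_target_hz, "drive": drive,
             "adaptation_factor": params.adaptation_factor,
             "spontaneous_rate_hz": params.spontaneous_rate_hz,
             "onset_latency_ms": params.onset_latency_ms,
             "archetype": params.archetype}
    return rec, truth


def simulate_unit_bank(params: EphysGenParams, train: StimulusTrain,
                       n_trials: int = 5, seed: int | None = None
                       ) -> tuple[list[UnitRecording], list[dict]]:
    """A bank of ``params.n_units`` units with per-unit Gamma heterogeneity
    (stratified quantile draws, so the bank mean matches the configured
    target at any bank size)."""
    root = np.random.SeedSequence(params.seed if seed is None else seed)
    target_rng = np.random.default_rng(root.spawn(1)[0])
    targets = _stratified_gamma(target_rng, params.target_rate_mean_hz,
                                params.target_rate_sd_hz, params.n_units)
    recs, truths = [], []
    for i, (child, tgt) in enumerate(zip(root.spawn(params.n_units + 1)[1:], targets)):
        rec, truth = simulate_unit(params, train, n_trials,
                                   np.random.default_rng(child),
                                   unit_target_hz=float(tgt))
        rec.unit_id = f"{params.archetype}_{i:03d}"
        recs.append(rec)
        truths.append(truth)
    return recs, truths


def simulate_coupled_escape_latencies(adaptation: Sequence[float],
                                      window_midpoints_s: Sequence[float],
                                      n_animals: int, seed: int = 0
                                      ) -> tuple[list[Optional[float]], int]:
    """Escape latencies coupled to the decline of a neural adaptation profile.

    Each animal carries a release threshold theta ~ U(0, 1); it escapes at the
    first stimulus-window midpoint where the normalized neural drive has
    fallen below theta.  Animals whose threshold lies below the profile's
    minimum never escape (returned as ``None``; count is the second element).
    """
    prof = np.asarray(adaptation, dtype=float)
    mids = np.asarray(window_midpoints_s, dtype=float)
    if prof.size != mids.size:
        raise ValueError("profile and midpoints must have equal length")
    rng = np.random.default_rng(seed)
    thetas = rng.uniform(0.0, 1.0, n_animals)
    latencies: list[Optional[float]] = []
    censored = 0
    for th in thetas:
        below = np.flatnonzero(prof < th)
        if below.size:
            latencies.append(float(mids[below[0]]))
        else:
            latencies.append(None)
            censored += 1
    return latencies, censored


def make_synthetic_trf(bf_hz: float = 8000.0, threshold_db: float = 40.0,
                       widen_octaves_per_10db: float = 0.4,
                       peak_rate_hz: float = 40.0, spont_rate_hz: float = 2.0,
                       spont_sd_hz: float = 1.0) -> tuple[TRF, dict]:
    """A deterministic V-shaped tonal receptive field with known metrics.

    Frequencies 2-32 kHz in 0.2-octave steps, intensities 10-70 dB SPL in
    10-dB steps.  At threshold only the best-frequency column responds; the
    significant span widens by ``widen_octaves_per_10db`` per 10 dB.
    Returns the TRF and a truth dict with the expected metrics.
    """
    freqs = 2000.0 * 2 ** np.arange(0, 4.0 + 1e-9, 0.2)
    ints = np.arange(10.0, 71.0, 10.0)
    octs = np.log2(freqs / bf_hz)
    mat = np.zeros((ints.size, freqs.size))
    for i, level in enumerate(ints):
        if level < threshold_db:
            continue
        half = (widen_octaves_per_10db * (level - threshold_db) / 10.0) / 2.0
        sel = np.abs(octs) <= half + 1e-9
        mat[i, sel] = spont_rate_hz + peak_rate_hz * (1.0 - np.abs(octs[sel]) / (half + 0.2))
    trf = TRF(frequencies_hz=freqs, intensities_db=ints, matrix=mat,
              spont_rate_hz=spont_rate_hz, spont_sd_hz=spont_sd_hz)
    step = 0.2
    n_sig_at_20 = int(np.sum(np.abs(octs) <= widen_octaves_per_10db + 1e-9))
    truth = {"threshold_db": threshold_db,
             "best_frequency_hz": float(freqs[np.argmin(np.abs(octs))]),
             "bandwidth_octaves": n_sig_at_20 * step}
    return trf, truth
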