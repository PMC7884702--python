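"""Synthesis of looming (crescendo) and receding (decrescendo) sound-envelope trains.

A looming sound mimics an approaching object by a linear rise of its level in
dB SPL; the canonical train rises from 20 to 70 dB SPL in 0.4 s, drops back to
background within 5 ms, holds at background for 0.6 s, and repeats ten times
(10 s total).  Envelopes are linear *in dB SPL*, not in pressure.  The optional
waveform renders a single continuous stream of white Gaussian noise whose
instantaneous amplitude is scaled by the envelope.

The 5-ms return-to-background transition is folded into the hold interval, so
one repeat period is ``rise_time_s + hold_time_s`` (1 s for the defaults) and a
full train lasts exactly ``n_repeats`` periods.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

CRESCENDO = "crescendo"
DECRESCENDO = "decrescendo"

__all__ = [
    "StimulusSpec",
    "StimulusTrain",
    "db_to_amplitude",
    "synth_crescendo_train",
    "synth_decrescendo_train",
    "stimulus_windows",
    "write_train",
    "read_train",
]


class InvalidSpecError(ValueError):
    """Raised for stimulus specifications that violate their invariants."""


def db_to_amplitude(level_db: float, ref_db: float) -> float:
    """Amplitude ratio corresponding to ``level_db`` relative to ``ref_db``.

    A 20-dB increase is a tenfold amplitude increase:
    ``db_to_amplitude(40, 20) == 10``.
    """
    return 10.0 ** ((np.asarray(level_db, dtype=float) - ref_db) / 20.0)


@dataclass(frozen=True)
class StimulusSpec:
    """Parameters of one crescendo/decrescendo train.

    Defaults are the canonical looming train: background 20 dB SPL, peak
    70 dB SPL, 0.4-s rise, 5-ms fast transition, 0.6-s hold, 10 repeats.
    """

    background_db: float = 20.0
    peak_db: float = 70.0
    rise_time_s: float = 0.4
    transition_time_s: float = 0.005
    hold_time_s: float = 0.6
    n_repeats: int = 10
    envelope_rate_hz: float = 1000.0
    audio_rate_hz: float = 96000.0
    direction: str = CRESCENDO
    background_mode: str = "low"  # decrescendo only: {"low", "high"}

    def __post_init__(self) -> None:
        if not np.isfinite([self.background_db, self.peak_db]).all():
            raise InvalidSpecError("levels must be finite")
        if self.background_db > self.peak_db:
            raise InvalidSpecError("background_db must not exceed peak_db")
        if self.rise_time_s < 0:
            raise InvalidSpecError("rise_time_s must be >= 0")
        if self.n_repeats < 1:
            raise InvalidSpecError("n_repeats must be >= 1")
        if self.envelope_rate_hz <= 0:
            raise InvalidSpecError("envelope_rate_hz must be > 0")
        if self.direction not in (CRESCENDO, DECRESCENDO):
            raise InvalidSpecError(f"unknown direction {self.direction!r}")
        if self.background_mode not in ("low", "high"):
            raise InvalidSpecError(f"unknown background_mode {self.background_mode!r}")

    @property
    def period_s(self) -> float:
        """One repeat period; the 5-ms transition is folded into the hold."""
        return self.rise_time_s + self.hold_time_s


@dataclass
class StimulusTrain:
    """Sampled dB-SPL envelope of a stimulus train plus its analysis windows."""

    times: np.ndarray
    envelope_db: np.ndarray
    windows: list[tuple[float, float]]
    spec: StimulusSpec
    total_duration_s: float
    waveform: Optional[np.ndarray] = field(default=None, repr=False)

    def envelope_at(self, t) -> np.ndarray:
        """Envelope level (dB SPL) at arbitrary times, by interpolation."""
        return np.interp(t, self.times, self.envelope_db)

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "level_db": self.envelope_db})


def _sample_times(spec: StimulusSpec, total: float) -> np.ndarray:
    n = int(round(total * spec.envelope_rate_hz))
    return np.arange(n) / spec.envelope_rate_hz


def _render_waveform(spec: StimulusSpec, times: np.ndarray, env_db: np.ndarray,
                     total: float, seed: int) -> np.ndarray:
    """Continuous white-noise carrier, amplitude-modulated by the envelope.

    Amplitude is referenced to the background level, so a constant-envelope
    segment at level L has RMS ``db_to_amplitude(L, background)`` relative to a
    background segment.
    """
    rng = np.random.default_rng(seed)
    n = int(round(total * spec.audio_rate_hz))
    t_audio = np.arange(n) / spec.audio_rate_hz
    noise = rng.standard_normal(n)
    amp = db_to_amplitude(np.interp(t_audio, times, env_db), spec.background_db)
    return noise * amp


def synth_crescendo_train(spec: StimulusSpec, seed: int = 0,
                          render_waveform: bool = False) -> StimulusTrain:
    """Build a crescendo (looming) train.

    Each repeat rises linearly ``background -> peak`` in dB over
    ``rise_time_s``, falls back within ``transition_time_s`` and holds at
    background for the rest of the period.  ``rise_time_s == 0`` collapses the
    ramp to an instantaneous step.
    """
    if spec.direction != CRESCENDO:
        raise InvalidSpecError("spec.direction must be 'crescendo'")
    period = spec.period_s
    total = spec.n_repeats * period
    times = _sample_times(spec, total)
    phase = np.mod(times, period)

    bg, pk, rise, trans = spec.background_db, spec.peak_db, spec.rise_time_s, spec.transition_time_s
    env = np.full_like(times, bg)
    if rise > 0:
        in_rise = phase < rise
        env[in_rise] = bg + (pk - bg) * phase[in_rise] / rise
    in_trans = (phase >= rise) & (phase < rise + trans)
    if trans > 0:
        env[in_trans] = pk - (pk - bg) * (phase[in_trans] - rise) / trans
    elif rise == 0:
        # degenerate: instantaneous pulse train has zero on-time; keep the
        # first sample of each period at peak so the step is representable
        env[phase < 1.0 / spec.envelope_rate_hz] = pk
    env = np.clip(env, bg, pk)

    ramp = rise if rise > 0 else trans
    windows = [(k * period, k * period + ramp) for k in range(spec.n_repeats)]
    waveform = _render_waveform(spec, times, env, total, seed) if render_waveform else None
    return StimulusTrain(times=times, envelope_db=env, windows=windows, spec=spec,
                         total_duration_s=total, waveform=waveform)


def synth_decrescendo_train(spec: StimulusSpec, seed: int = 0,
                            render_waveform: bool = False) -> StimulusTrain:
    """Build a decrescendo (receding) train.

    ``background_mode == "low"``: per repeat a 5-ms step background -> peak,
    then a linear fall peak -> background over ``rise_time_s``, then hold at
    background.  ``background_mode == "high"``: a continuous peak-level
    background with a per-repeat linear fall peak -> background over
    ``rise_time_s`` and a 5-ms return to peak; the inter-stimulus interval and
    everything after the train stay at peak level.
    """
    if spec.direction != DECRESCENDO:
        raise InvalidSpecError("spec.direction must be 'decrescendo'")
    period = spec.period_s
    total = spec.n_repeats * period
    times = _sample_times(spec, total)
    phase = np.mod(times, period)
    bg, pk, fall, trans = spec.background_db, spec.peak_db, spec.rise_time_s, spec.transition_time_s

    if spec.background_mode == "low":
        env = np.full_like(times, bg)
        if trans > 0:
            in_step = phase < trans
            env[in_step] = bg + (pk - bg) * phase[in_step] / trans
        if fall > 0:
            in_fall = (phase >= trans) & (phase < trans + fall)
            env[in_fall] = pk - (pk - bg) * (phase[in_fall] - trans) / fall
        windows = [(k * period + trans, k * period + trans + fall)
                   for k in range(spec.n_repeats)]
    else:  # high background
        env = np.full_like(times, pk)
        if fall > 0:
            in_fall = phase < fall
            env[in_fall] = pk - (pk - bg) * phase[in_fall] / fall
        if trans > 0:
            in_ret = (phase >= fall) & (phase < fall + trans)
            env[in_ret] = bg + (pk - bg) * (phase[in_ret] - fall) / trans
        windows = [(k * period, k * period + fall) for k in range(spec.n_repeats)]
    env = np.clip(env, bg, pk)
    waveform = _render_waveform(spec, times, env, total, seed) if render_waveform else None
    return StimulusTrain(times=times, envelope_db=env, windows=windows, spec=spec,
                         total_duration_s=total, waveform=waveform)


def synth_train(spec: StimulusSpec, seed: int = 0, render_waveform: bool = False) -> StimulusTrain:
    """Dispatch on ``spec.direction``."""
    if spec.direction == CRESCENDO:
        return synth_crescendo_train(spec, seed, render_waveform)
    return synth_decrescendo_train(spec, seed, render_waveform)


def stimulus_windows(train: StimulusTrain) -> list[tuple[float, float]]:
    """The per-repeat ramp windows ``[onset, offset)``, ascending.

    These are the analysis units for evoked firing rates.
    """
    return sorted(train.windows)


# ---------------------------------------------------------------------------
# I/O: envelope as a two-column table, windows + spec as a JSON sidecar,
# waveform optionally as WAV.

def write_train(train: StimulusTrain, out_json: str | Path,
                envelope_table: str | Path | None = None,
                wav: str | Path | None = None) -> None:
    out_json = Path(out_json)
    meta = {
        "spec": asdict(train.spec),
        "windows": [list(w) for w in train.windows],
        "total_duration_s": train.total_duration_s,
    }
    out_json.write_text(json.dumps(meta, indent=2, sort_keys=True))
    if envelope_table is not None:
        train.to_table().to_csv(envelope_table, sep="\t", index=False)
    if wav is not None:
        if train.waveform is None:
            raise ValueError("train has no rendered waveform")
        from scipy.io import wavfile
        w = train.waveform
        scaled = (w / (np.abs(w).max() or 1.0)).astype(np.float32)
        wavfile.write(str(wav), int(train.spec.audio_rate_hz), scaled)


def read_train(in_json: str | Path) -> StimulusTrain:
    meta = json.loads(Path(in_json).read_text())
    spec = StimulusSpec(**meta["spec"])
    train = synth_train(spec)
    # windows/total come from the deterministic spec; sanity-check the sidecar
    saved = [tuple(w) for w in meta["windows"]]
    if not np.allclose(np.asarray(saved), np.asarray(train.windows)):
        raise ValueError("sidecar windows inconsistent with spec")
    return train
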