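"""Spike-train response characterization: PSTHs, evoked rates, latency, typing, TRF.

Single-unit spike times aligned to stimulus-train onsets are summarized as
peri-stimulus time histograms and per-stimulus-window evoked firing rates.
Response onset latency uses the 3-standard-deviation rule (first PSTH bin
whose rate exceeds baseline mean + 3 SD); the same significance rule is reused
for tonal-receptive-field (TRF) pixels.  Response types (On / Sustained / Off)
follow declared operational criteria: the field draws these categories from
population PSTH shape without published numeric thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "UnitRecording",
    "PSTH",
    "ResponseProfile",
    "TRF",
    "compute_psth",
    "evoked_rates",
    "onset_latency",
    "classify_response_type",
    "adaptation_profile",
    "trf_metrics",
    "classify_rs_ib",
]

ON = "On"
SUSTAINED = "Sustained"
OFF = "Off"
UNRESPONSIVE = "unresponsive"


@dataclass
class UnitRecording:
    """Sorted spike times of one unit plus its stimulus-train onset markers."""

    unit_id: str
    spike_times_s: np.ndarray
    trial_onsets_s: np.ndarray
    region: str = "other"  # {TS, SC, AC_L5, other}

    def __post_init__(self) -> None:
        self.spike_times_s = np.sort(np.asarray(self.spike_times_s, dtype=float))
        self.trial_onsets_s = np.sort(np.asarray(self.trial_onsets_s, dtype=float))
        if self.spike_times_s.size and self.spike_times_s[0] < 0:
            raise ValueError("spike times must be non-negative")

    def aligned_spikes(self, window: tuple[float, float]) -> list[np.ndarray]:
        """Per-trial spike times relative to each trial onset, within window."""
        pre, post = window
        out = []
        for onset in self.trial_onsets_s:
            rel = self.spike_times_s - onset
            out.append(rel[(rel >= -pre) & (rel < post)])
        return out


@dataclass
class PSTH:
    bin_edges_s: np.ndarray
    rate_hz: np.ndarray
    n_trials: int
    alignment: str = "train-onset"

    @property
    def bin_s(self) -> float:
        return float(self.bin_edges_s[1] - self.bin_edges_s[0])

    @property
    def centers_s(self) -> np.ndarray:
        return (self.bin_edges_s[:-1] + self.bin_edges_s[1:]) / 2.0

    @property
    def total_spikes(self) -> float:
        return float(np.sum(self.rate_hz) * self.bin_s * self.n_trials)


@dataclass
class ResponseProfile:
    evoked_rate_hz: np.ndarray            # raw in-window rate, one per stimulus
    spontaneous_rate_hz: float
    evoked_minus_spont_hz: np.ndarray
    onset_latency_ms: Optional[float] = None
    response_type: str = UNRESPONSIVE
    adaptation: Optional[np.ndarray] = field(default=None)


def compute_psth(rec: UnitRecording, align_events_s: Sequence[float] | None = None,
                 window: tuple[float, float] = (1.0, 11.0),
                 bin_s: float = 0.010) -> PSTH:
    """Trial-averaged firing-rate histogram aligned to events.

    ``window = (pre_s, post_s)`` spans ``[-pre_s, post_s)`` around each event.
    Rates are counts / (bin_s * n_events), so total spike count is conserved:
    ``sum(rate) * bin_s * n_events`` equals the number of aligned spikes.
    """
    if bin_s <= 0:
        raise ValueError("bin_s must be > 0")
    events = np.asarray(align_events_s if align_events_s is not None
                        else rec.trial_onsets_s, dtype=float)
    if events.size == 0:
        raise ValueError("need at least one alignment event")
    pre, post = window
    n_bins = int(round((pre + post) / bin_s))
    edges = -pre + np.arange(n_bins + 1) * bin_s
    counts = np.zeros(n_bins)
    for onset in events:
        rel = rec.spike_times_s - onset
        rel = rel[(rel >= edges[0]) & (rel < edges[-1])]
        idx = np.floor((rel - edges[0]) / bin_s).astype(int)
        np.add.at(counts, np.clip(idx, 0, n_bins - 1), 1)
    return PSTH(bin_edges_s=edges, rate_hz=counts / (bin_s * events.size),
                n_trials=int(events.size))


def evoked_rates(rec: UnitRecording, windows: Sequence[tuple[float, float]],
                 baseline_window: tuple[float, float] = (-1.0, 0.0),
                 subtract_baseline: bool = False) -> ResponseProfile:
    """Per-stimulus-window spike rates averaged across trials.

    ``windows`` are relative to trial onset (the stimulus ramp windows).
    Spontaneous rate comes from ``baseline_window`` (relative, default the
    1 s before train onset).  The default evoked rate is the raw in-window
    rate; the baseline-subtracted variant is stored alongside and returned as
    the primary rate when ``subtract_baseline`` is set.
    """
    if any(off <= on for on, off in windows):
        raise ValueError("zero- or negative-length stimulus window")
    n_trials = rec.trial_onsets_s.size
    if n_trials == 0:
        raise ValueError("recording has no trial onsets")
    rates = np.zeros(len(windows))
    spikes = rec.spike_times_s
    for w, (on, off) in enumerate(windows):
        total = 0
        for onset in rec.trial_onsets_s:
            total += np.count_nonzero((spikes >= onset + on) & (spikes < onset + off))
        rates[w] = total / ((off - on) * n_trials)
    b0, b1 = baseline_window
    if b1 <= b0:
        raise ValueError("zero-length baseline window")
    base_total = 0
    for onset in rec.trial_onsets_s:
        base_total += np.count_nonzero((spikes >= onset + b0) & (spikes < onset + b1))
    spont = base_total / ((b1 - b0) * n_trials)
    sub = rates - spont
    primary = sub if subtract_baseline else rates
    return ResponseProfile(evoked_rate_hz=primary, spontaneous_rate_hz=float(spont),
                           evoked_minus_spont_hz=sub,
                           adaptation=adaptation_profile(primary) if len(windows) >= 2 else None)


def _sd_floor(baseline_mean: float, baseline_sd: float, bin_s: float,
              n_trials: int, eps: float = 1e-6) -> float:
    """SD floor for the 3-SD rule: guards sparse baselines where the sample
    SD underestimates Poisson counting noise (or is exactly zero)."""
    poisson_sd = np.sqrt(max(baseline_mean, 0.0) / (bin_s * n_trials))
    return max(baseline_sd, poisson_sd, eps)


def onset_latency(psth: PSTH, baseline_bins: int | None = None,
                  search_window_s: tuple[float, float] | None = None) -> Optional[float]:
    """Response onset latency (ms): first post-onset bin exceeding baseline
    mean + 3 SD.  ``None`` if the rate never exceeds the criterion.

    Baseline is the pre-onset bins (or the last ``baseline_bins`` of them).
    The SD is floored by the Poisson counting noise of the baseline rate so a
    flat baseline cannot produce a zero criterion.
    """
    centers = psth.centers_s
    pre = psth.rate_hz[centers < 0]
    if baseline_bins is not None:
        pre = pre[-baseline_bins:]
    if pre.size < 3:
        raise ValueError("need >= 3 baseline bins")
    mu = float(pre.mean())
    sd = _sd_floor(mu, float(pre.std(ddof=0)), psth.bin_s, psth.n_trials)
    lo, hi = search_window_s if search_window_s is not None else (0.0, np.inf)
    sel = (psth.bin_edges_s[:-1] >= lo - 1e-12) & (psth.bin_edges_s[:-1] < hi)
    above = np.flatnonzero(sel & (psth.rate_hz > mu + 3.0 * sd))
    if above.size == 0:
        return None
    return float(psth.bin_edges_s[above[0]] * 1000.0)


def classify_response_type(psth: PSTH, stim_window: tuple[float, float] = (0.0, 0.4),
                           offset_window_s: float = 0.3,
                           early_window_s: float = 0.1) -> str:
    """On / Sustained / Off / unresponsive from a single-stimulus-aligned PSTH.

    Operational criteria (consistent with the 3-SD significance rule):

    * significant elevation requires two consecutive bins above
      baseline mean + 3 SD (robust to single-bin Poisson excursions);
    * **On**: elevation confined to the first ``early_window_s`` of the
      stimulus, returning to <= baseline + 1 SD before stimulus offset;
    * **Sustained**: elevation persists past the early window, with the
      late-half mean rate >= early-half mean rate during the stimulus
      (the gradually-increasing ramp signature);
    * **Off**: no elevation during the stimulus but significant elevation
      within ``offset_window_s`` after stimulus offset;
    * otherwise **unresponsive**.
    """
    on_t, off_t = stim_window
    centers = psth.centers_s
    pre = psth.rate_hz[centers < on_t]
    mu = float(pre.mean()) if pre.size else 0.0
    sd = _sd_floor(mu, float(pre.std(ddof=0)) if pre.size else 0.0,
                   psth.bin_s, psth.n_trials)
    hi_thr = mu + 3.0 * sd

    def sig(mask: np.ndarray) -> bool:
        above = (psth.rate_hz > hi_thr) & mask
        return bool(np.any(above[:-1] & above[1:]))

    in_stim = (centers >= on_t) & (centers < off_t)
    in_late = in_stim & (centers >= on_t + early_window_s)
    in_offset = (centers >= off_t) & (centers < off_t + offset_window_s)

    stim_sig = sig(in_stim)
    off_sig = sig(in_offset)
    # latency-guarded mean excess rates arbitrate stim- vs offset-locked
    # responses when both windows show formally significant bins
    guard = 0.02
    stim_excess = (psth.rate_hz[in_stim & (centers >= on_t + guard)].mean() - mu
                   if in_stim.any() else 0.0)
    off_excess = (psth.rate_hz[(centers >= off_t + guard)
                               & (centers < off_t + offset_window_s)].mean() - mu
                  if in_offset.any() else 0.0)

    if off_sig and (not stim_sig or off_excess > stim_excess):
        return OFF
    if stim_sig:
        tail = in_stim & (centers >= off_t - 0.4 * (off_t - on_t))
        confined = not sig(in_late)
        returns = psth.rate_hz[tail].mean() <= mu + sd if tail.any() else True
        if confined and returns:
            return ON
        half = (on_t + off_t) / 2.0
        first = psth.rate_hz[in_stim & (centers < half)]
        second = psth.rate_hz[in_stim & (centers >= half)]
        if second.size and first.size and second.mean() >= first.mean():
            return SUSTAINED
        return ON
    return UNRESPONSIVE


def adaptation_profile(rates: np.ndarray) -> np.ndarray:
    """Per-stimulus rates normalized to the first stimulus.

    Returns all-NaN (flagged) when the first-window rate is zero.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.size < 2:
        raise ValueError("need >= 2 windows")
    if rates[0] == 0:
        return np.full_like(rates, np.nan)
    return rates / rates[0]


@dataclass
class TRF:
    """Tonal receptive field: response matrix over frequency x intensity.

    ``matrix`` has shape ``(n_intensities, n_frequencies)`` in Hz (evoked
    rate per tone).  ``spont_rate_hz``/``spont_sd_hz`` parameterize the
    significance criterion (evoked > spontaneous + 3 SD).
    """

    frequencies_hz: np.ndarray
    intensities_db: np.ndarray
    matrix: np.ndarray
    spont_rate_hz: float = 0.0
    spont_sd_hz: float = 0.0

    def __post_init__(self) -> None:
        self.frequencies_hz = np.asarray(self.frequencies_hz, dtype=float)
        self.intensities_db = np.asarray(self.intensities_db, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (self.intensities_db.size, self.frequencies_hz.size):
            raise ValueError("matrix shape must be (n_intensities, n_frequencies)")


@dataclass
class TRFMetrics:
    threshold_db: Optional[float]
    best_frequency_hz: Optional[float]
    bandwidth_octaves: Optional[float]


def trf_metrics(trf: TRF, sd_floor_hz: float = 1e-6) -> TRFMetrics:
    """Threshold, best frequency and bandwidth of a tonal receptive field.

    Threshold: lowest intensity with any significant pixel (3-SD rule).
    Best frequency: frequency of the peak response in the threshold row.
    Bandwidth: octave span of significant pixels in the row 20 dB above
    threshold (one 0.2-octave step counts as 0.2 octaves); ``None`` when that
    intensity was not mapped.
    """
    crit = trf.spont_rate_hz + 3.0 * max(trf.spont_sd_hz, sd_floor_hz)
    sig = trf.matrix > crit
    rows_with = np.flatnonzero(sig.any(axis=1))
    if rows_with.size == 0:
        return TRFMetrics(None, None, None)
    order = np.argsort(trf.intensities_db)
    thr_row = next(r for r in order if sig[r].any())
    threshold = float(trf.intensities_db[thr_row])
    bf = float(trf.frequencies_hz[np.argmax(trf.matrix[thr_row])])

    target = threshold + 20.0
    match = np.flatnonzero(np.isclose(trf.intensities_db, target))
    if match.size == 0:
        return TRFMetrics(threshold, bf, None)
    row = sig[match[0]]
    if not row.any():
        return TRFMetrics(threshold, bf, 0.0)
    freqs = trf.frequencies_hz[np.flatnonzero(row)]
    step = float(np.median(np.diff(np.log2(trf.frequencies_hz)))) if trf.frequencies_hz.size > 1 else 0.2
    bandwidth = float(np.log2(freqs[-1] / freqs[0]) + step)
    return TRFMetrics(threshold, bf, bandwidth)


def classify_rs_ib(trial_spike_times: Sequence[np.ndarray],
                   burst_min: int = 2, burst_isi_s: float = 0.010) -> str:
    """Regular-spiking vs. intrinsic-bursting from best-frequency tone trials.

    RS units fire exactly one spike per tone (median count 1); IB units fire
    a burst (median count >= ``burst_min`` with intra-burst inter-spike
    intervals < ``burst_isi_s`` in at least half the trials).  Anything else
    (including zero-spike medians) is unclassified.
    """
    if len(trial_spike_times) == 0:
        raise ValueError("need >= 1 trial")
    counts = np.array([len(np.asarray(t)) for t in trial_spike_times])
    med = float(np.median(counts))
    if med == 1:
        return "RS"
    if med >= burst_min:
        bursty = 0
        for t in trial_spike_times:
            t = np.sort(np.asarray(t, dtype=float))
            if t.size >= 2 and np.min(np.diff(t)) < burst_isi_s:
                bursty += 1
        if bursty >= len(trial_spike_times) / 2.0:
            return "IB"
    return "unclassified"
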