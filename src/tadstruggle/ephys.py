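"""Burst and rhythm statistics for ventral-root-like extracellular traces.

The processing chain mirrors standard fictive-locomotion analysis:
stimulus-artifact windows are zeroed, the trace is full-wave rectified and
smoothed by an iterated short moving average, events are triggered at a
multiple of the quiet-baseline standard deviation, neighbouring events are
merged into bursts, and from the bursts come duration, cycle period,
frequency and duty cycle.  Rhythm regularity is summarised by a
rhythmicity index R in [0, 1] computed from the inter-event-interval
histogram, and two-channel propagation speed comes from the
cross-correlation lag nearest zero.  Motoneuron spike phases within
struggling cycles can be calibrated for the rostrocaudal conduction delay.

Sign convention: propagation speed is positive caudorostrally (tail to
head), matching the kinematics module.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as _ndi
from scipy import signal as _sig

from ._signal import dominant_period, nearest_peak_lag

__all__ = [
    "RhythmTrace",
    "EventTrain",
    "Burst",
    "RhythmStats",
    "RhythmicityResult",
    "PropagationResult",
    "preprocess",
    "trigger_events",
    "group_bursts",
    "rhythmicity_index",
    "xcorr_propagation",
    "phase_of_spikes",
]


@dataclass
class RhythmTrace:
    """One sampled extracellular-like channel.

    samples are in microvolts; position is mm from the mid/hindbrain
    border; artifact_windows are (start, end) pairs in seconds that are
    forced to 0 uV during preprocessing (declared, never inferred).
    """

    samples: np.ndarray
    sampling_rate: float
    side: str = "left"
    position: float = 0.0
    artifact_windows: tuple = ()
    name: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate < 5000:
            raise ValueError("sampling_rate must be >= 5000 Hz")
        if self.position < 0:
            raise ValueError("position must be >= 0 mm")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate


@dataclass
class EventTrain:
    event_times: np.ndarray   # s, strictly increasing
    threshold: float          # uV
    baseline_sd: float        # uV

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        if np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event times must be strictly increasing")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


@dataclass
class Burst:
    start: float      # s
    end: float        # s
    duration: float   # ms (last event - first event)
    n_events: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("burst end must not precede start")
        if self.n_events < 1:
            raise ValueError("a burst holds at least one event")


@dataclass
class RhythmStats:
    cycle_period: float        # ms, NaN when undefined
    frequency: float           # Hz
    duty_cycle: float          # mean burst duration / mean cycle period
    rhythmicity: float | None = None
    flags: list = field(default_factory=list)


@dataclass
class RhythmicityResult:
    value: float
    flagged: bool
    bin_width: float           # ms, reported alongside R by design
    reason: str = ""


@dataclass
class PropagationResult:
    delay: float               # ms, positive = second channel delayed
    speed: float               # mm/s, positive = caudorostral
    synchronous: bool
    defined: bool


# ---------------------------------------------------------------------------

def preprocess(trace: RhythmTrace, smooth_window: float = 2.5,
               iterations: int = 4) -> RhythmTrace:
    """Zero declared artifacts, full-wave rectify, and smooth.

    Smoothing is an iterated centred moving average (default 2.5 ms
    window, 4 iterations), whose impulse response is the window convolved
    with itself four times -- close to Gaussian.  Circular boundary
    handling keeps the trace mean exactly unchanged.  ``iterations=0``
    rectifies without smoothing (the usual input for per-spike event
    triggering; the smoothed version is for cross-correlation and
    burst-envelope work).
    """
    w = int(round(smooth_window * 1e-3 * trace.sampling_rate))
    if iterations > 0 and w < 3:
        raise ValueError("smoothing window shorter than 3 samples")
    if w % 2 == 0:
        w += 1
    x = trace.samples.copy()
    for start, end in trace.artifact_windows:
        i0 = max(0, int(np.floor(start * trace.sampling_rate)))
        i1 = min(x.size, int(np.ceil(end * trace.sampling_rate)))
        x[i0:i1] = 0.0
    x = np.abs(x)
    for _ in range(iterations):
        x = _ndi.uniform_filter1d(x, size=w, mode="wrap")
    return dataclasses.replace(trace, samples=x, artifact_windows=())


def trigger_events(trace: RhythmTrace,
                   baseline_window: tuple[float, float],
                   k: float = 5.0,
                   refractory: float = 1.0) -> EventTrain:
    """Threshold-trigger events on a rectified (and usually smoothed) trace.

    The crossing level sits k standard deviations above the mean of a
    baseline window declared free of bursts (a rectified trace has a
    non-zero noise floor, so the level is referenced to it).  Events are
    upward threshold crossings; a refractory period (default 1 ms)
    prevents double triggering on one potential.
    """
    fs = trace.sampling_rate
    i0 = int(round(baseline_window[0] * fs))
    i1 = int(round(baseline_window[1] * fs))
    base = trace.samples[max(0, i0):min(trace.samples.size, i1)]
    if base.size < 2:
        raise ValueError("baseline window is empty or outside the trace")
    sd = float(np.std(base))
    if sd <= 0:
        raise ValueError("baseline window has zero variance")
    thr = float(np.mean(base)) + k * sd
    x = trace.samples
    up = np.nonzero((x[:-1] < thr) & (x[1:] >= thr))[0] + 1
    if up.size == 0:
        return EventTrain(np.empty(0), thr, sd)
    ref_n = refractory * 1e-3 * fs
    kept = [up[0]]
    for i in up[1:]:
        if i - kept[-1] >= ref_n:
            kept.append(i)
    return EventTrain(np.asarray(kept, dtype=float) / fs, thr, sd)


def group_bursts(events: EventTrain, max_gap: float = 15.0,
                 min_events: int = 1) -> tuple[list[Burst], RhythmStats]:
    """Merge events separated by less than ``max_gap`` ms into bursts.

    Burst duration is last-minus-first event time; the cycle period is the
    interval between successive burst starts; duty cycle is mean duration
    over mean period.  The default gap (15 ms) sits just above the 13 ms
    intra-burst inter-spike-interval bound, so struggling spikes merge and
    cycles do not.  ``min_events`` discards stray groups below that size
    (the automated stand-in for the visual inspection step that rejects
    isolated noise events between cycles).
    """
    t = events.event_times
    if t.size < 1:
        raise ValueError("no events to group")
    splits = np.nonzero(np.diff(t) * 1000.0 > max_gap)[0]
    starts = np.concatenate(([0], splits + 1))
    ends = np.concatenate((splits, [t.size - 1]))
    bursts = [
        Burst(start=float(t[i]), end=float(t[j]),
              duration=float((t[j] - t[i]) * 1000.0), n_events=int(j - i + 1))
        for i, j in zip(starts, ends)
        if j - i + 1 >= min_events
    ]
    if not bursts:
        raise ValueError("no burst meets the min_events requirement")
    flags = []
    durations = np.array([b.duration for b in bursts])
    if len(bursts) >= 2:
        periods = np.diff([b.start for b in bursts]) * 1000.0
        period = float(np.mean(periods))
        freq = 1000.0 / period
        duty = float(np.mean(durations) / period)
    else:
        period, freq, duty = float("nan"), float("nan"), float("nan")
        flags.append("single_burst_no_period")
    return bursts, RhythmStats(cycle_period=period, frequency=freq,
                               duty_cycle=duty, flags=flags)


def rhythmicity_index(event_times: np.ndarray, bin_width: float = 5.0,
                      ) -> RhythmicityResult:
    """Rhythmicity index R from the inter-event-interval histogram.

    The histogram of consecutive intervals is smoothed with a 3-bin moving
    average; R = (peak - trough) / (peak + trough), where the trough is
    the first local minimum after the initial peak and the peak the one
    that follows it.  A single isolated interval mode away from zero (a
    perfectly periodic train) has an empty trough, giving R = 1; a
    boundary-mode monotone histogram (Poisson-like) has no interior
    structure and is reported as R = 0, flagged.
    """
    t = np.asarray(event_times, dtype=float)
    iv = np.diff(t) * 1000.0  # ms
    if iv.size < 10:
        raise ValueError("rhythmicity needs at least 10 intervals")
    edges = np.arange(0.0, iv.max() + 2 * bin_width, bin_width)
    h, _ = np.histogram(iv, bins=edges)
    hs = _ndi.uniform_filter1d(h.astype(float), 3, mode="nearest")
    # zero padding turns boundary modes into interior, plateau-aware peaks
    hp = np.concatenate([[0.0], hs, [0.0, 0.0]])
    peaks, props = _sig.find_peaks(hp, plateau_size=(1, None))
    keep = hp[peaks] > 0
    peaks = peaks[keep]
    left_edges = props["left_edges"][keep]
    if peaks.size == 0:
        return RhythmicityResult(0.0, True, bin_width,
                                 "no interior histogram peak")
    if peaks.size == 1:
        if left_edges[0] <= 1:
            # lone mode starting at the zero-interval boundary: a
            # monotone-decaying (Poisson-like) histogram, not rhythmic
            return RhythmicityResult(0.0, True, bin_width,
                                     "unimodal histogram, no interior trough")
        p = peaks[0]
        lead = hs[:max(0, p - 1)]
        trough = float(lead.min()) if lead.size else 0.0
        peak = float(hp[p])
    else:
        p1 = peaks[0]
        cands = peaks[1:]
        # the cycle-period mode is the dominant later peak; count-noise
        # singletons in the trough are not "the following peak"
        p2 = cands[int(np.argmax(hp[cands]))]
        trough = (float(hp[p1 + 1:p2].min()) if p2 > p1 + 1
                  else float(min(hp[p1], hp[p2])))
        peak = float(hp[p2])
    if peak + trough <= 0:
        return RhythmicityResult(0.0, True, bin_width, "empty histogram")
    r = (peak - trough) / (peak + trough)
    return RhythmicityResult(float(np.clip(r, 0.0, 1.0)), False, bin_width)


def xcorr_propagation(trace_a: RhythmTrace, trace_b: RhythmTrace,
                      window_factor: float = 0.6) -> PropagationResult:
    """Rhythm propagation between two preprocessed same-side channels.

    The delay is the cross-correlation local maximum nearest zero lag
    (searched within +/- window_factor of the dominant cycle period);
    speed = -(position_b - position_a) / delay so caudorostral propagation
    (the caudal channel leading) is positive.  A sub-sample delay flags
    the pair synchronous; no interior correlation maximum leaves the
    result undefined.
    """
    if trace_a.sampling_rate != trace_b.sampling_rate:
        raise ValueError("traces must share a sampling rate")
    if trace_a.position == trace_b.position:
        raise ValueError("channel positions must differ")
    fs = trace_a.sampling_rate
    period = dominant_period(trace_a.samples, fs)
    max_lag = window_factor * period if period else None
    delay = nearest_peak_lag(trace_a.samples, trace_b.samples, fs,
                             max_lag=max_lag)
    if delay is None:
        return PropagationResult(float("nan"), float("nan"), False, False)
    if abs(delay) < 1.0 / fs:
        return PropagationResult(float(delay * 1000.0), float("nan"),
                                 True, True)
    speed = -(trace_b.position - trace_a.position) / delay
    return PropagationResult(float(delay * 1000.0), float(speed), False, True)


# Calibration measured over a 1.65 mm electrode separation: the standard
# phase delay per cycle is 0.185 - 0.00225 * period, period in seconds.
_PHASE_DELAY_DISTANCE = 1.65


def _wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap to (-0.5, 0.5]; the boundary maps to +0.5."""
    return 0.5 - np.mod(0.5 - np.asarray(phi, dtype=float), 1.0)


def phase_of_spikes(spike_times: np.ndarray, cycle_onsets: np.ndarray,
                    distance_l: float = 0.0, contralateral: bool = False,
                    cycle_period: float | None = None) -> np.ndarray:
    """Motoneuron spike phases within struggling cycles, delay-calibrated.

    Raw phase is (spike - onset) / period for the bracketing cycle.  The
    rostrocaudal conduction delay is removed by subtracting
    (0.185 - 0.00225 * period) * L / 1.65 (period in seconds, L the
    rostrocaudal electrode separation in mm), plus 0.5 for a contralateral
    recording; phases are wrapped to (-0.5, 0.5].  Spikes outside the
    onset brackets are dropped.  ``cycle_period`` (s) overrides the
    per-cycle period for the calibration term only.
    """
    spikes = np.asarray(spike_times, dtype=float)
    onsets = np.sort(np.asarray(cycle_onsets, dtype=float))
    if onsets.size < 2:
        raise ValueError("need at least two cycle onsets")
    periods = np.diff(onsets)
    if np.any(periods <= 0):
        raise ValueError("cycle period must be positive")
    idx = np.searchsorted(onsets, spikes, side="right") - 1
    ok = (idx >= 0) & (idx < periods.size)
    idx, spikes = idx[ok], spikes[ok]
    per = periods[idx]
    raw = (spikes - onsets[idx]) / per
    calib_period = cycle_period if cycle_period is not None else per
    delay = (0.185 - 0.00225 * np.asarray(calib_period)) * (
        distance_l / _PHASE_DELAY_DISTANCE)
    phi = raw - delay - (0.5 if contralateral else 0.0)
    return _wrap_phase(phi)
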