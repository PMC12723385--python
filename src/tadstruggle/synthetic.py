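"""Ground-truth generators emulating the study's raw inputs.

Two generators make every analysis module testable without recordings:

* ``make_tracked_movement`` builds an 11-point midline whose curvature is
  a travelling (optionally bidirectional) sinusoidal wave with a known
  frequency, sum-of-angles amplitude, propagation speed and origin.  The
  midline is integrated with exact per-segment rotations, so even coiling
  shapes (|sum| near 2 pi) are representable, and the configured
  parameters are attached as ground truth.

* ``make_vr_traces`` synthesises multi-channel bursty extracellular-like
  traces: biphasic spike waveforms in bursts whose onsets follow a
  longitudinal delay map, with configurable period, burst duration,
  in-burst event rate, onset jitter, per-channel event dropout and
  additive Gaussian noise.

All randomness flows from a single integer seed; identical seeds give
byte-identical outputs.  Presets for the four movement types are centred
on the reported class means.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ephys import RhythmTrace
from .kinematics import N_ANGLES, N_POINTS, TrackedBody

__all__ = [
    "WaveSpec",
    "TraceSpec",
    "MovementTruth",
    "TraceTruth",
    "MOVEMENT_PRESETS",
    "movement_preset",
    "make_tracked_movement",
    "make_vr_traces",
]


@dataclass
class WaveSpec:
    """Parameters of a synthetic curvature wave."""

    movement: str = "struggling"
    frequency: float = 4.0             # Hz
    amplitude: float = 2.4             # rad, sum-of-angles peak
    propagation_speed: float | None = 42.5  # mm/s signed; None = synchronous
    origin: float | None = None        # body-length fraction; bidirectional
    caudal_speed: float | None = None  # mm/s magnitude of the caudal branch
    duration: float = 2.0              # s
    frame_rate: float = 240.0          # Hz
    body_length: float = 5.0           # mm
    noise_sd: float = 0.0              # mm, i.i.d. Gaussian on coordinates
    head_yaw_deg: float = 0.0          # heading oscillation half-amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frequency <= 0 or self.frame_rate <= 0:
            raise ValueError("frequency and frame_rate must be positive")
        if self.origin is not None and not 0 < self.origin < 1:
            raise ValueError("origin must be a fraction in (0, 1)")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass
class MovementTruth:
    frequency: float
    amplitude: float
    propagation_speed: float | None
    origin: float | None
    caudal_speed: float | None
    vertex_amplitude: float
    phases: np.ndarray


MOVEMENT_PRESETS: dict[str, dict] = {
    # parameters centred on the reported class means
    "initial_coiling": dict(frequency=2.7, amplitude=4.1,
                            propagation_speed=None, duration=2.0),
    "struggling": dict(frequency=4.0, amplitude=2.4,
                       propagation_speed=42.5, duration=2.0),
    "transitional_coiling": dict(frequency=4.0, amplitude=4.0,
                                 propagation_speed=-218.0, duration=2.0),
    "swimming": dict(frequency=20.0, amplitude=1.0,
                     propagation_speed=-156.0, duration=1.0),
}


def movement_preset(name: str, **overrides) -> WaveSpec:
    params = dict(MOVEMENT_PRESETS[name])
    params.update(overrides)
    return WaveSpec(movement=name, **params)


def _vertex_phases(spec: WaveSpec, positions: np.ndarray) -> np.ndarray:
    """Phase offset (rad) of each vertex; positive = leads in time."""
    w = 2.0 * np.pi * spec.frequency
    if spec.origin is not None:
        x0 = spec.origin * spec.body_length
        v_r = abs(spec.propagation_speed or 42.5)
        v_c = abs(spec.caudal_speed or v_r)
        # wave diverges from the origin: vertices farther from it lag
        return np.where(positions <= x0,
                        -w * (x0 - positions) / v_r,
                        -w * (positions - x0) / v_c)
    if spec.propagation_speed is None:
        return np.zeros_like(positions)
    # positive speed: caudal vertices lead (caudorostral propagation)
    return w * positions / spec.propagation_speed


def make_tracked_movement(spec: WaveSpec) -> tuple[TrackedBody, MovementTruth]:
    """Synthesize a tracked midline and the ground truth it encodes.

    The nine vertex angles are sinusoids sharing the configured frequency,
    with phases from the propagation map; the per-vertex amplitude is
    scaled so the sum-of-angles trace peaks exactly at ``spec.amplitude``.
    Coordinates are integrated head-to-tail with equal segment lengths and
    exact rotations, then Gaussian coordinate noise is added.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.frame_rate))
    times = np.arange(n) / spec.frame_rate
    positions = np.arange(1, N_ANGLES + 1) / (N_POINTS - 1) * spec.body_length
    phases = _vertex_phases(spec, positions)
    gain = abs(np.sum(np.exp(1j * phases)))
    if gain < 1e-9:
        raise ValueError("phase pattern cancels the sum trace; choose a "
                         "slower propagation or shorter body")
    vertex_amp = spec.amplitude / gain
    w = 2.0 * np.pi * spec.frequency
    angles = vertex_amp * np.sin(w * times[:, None] + phases[None, :])

    heading0 = np.radians(spec.head_yaw_deg) * np.sin(w * times)
    seg = spec.body_length / (N_POINTS - 1)
    # heading of segment k = head heading + cumulative turn at vertices 1..k
    headings = heading0[:, None] + np.concatenate(
        [np.zeros((n, 1)), np.cumsum(angles, axis=1)], axis=1)
    steps = seg * np.stack([np.cos(headings), np.sin(headings)], axis=2)
    pts = np.concatenate([np.zeros((n, 1, 2)), np.cumsum(steps, axis=1)],
                         axis=1)
    if spec.noise_sd > 0:
        pts = pts + rng.normal(0.0, spec.noise_sd, size=pts.shape)
    body = TrackedBody(times=times, points=pts, frame_rate=spec.frame_rate,
                       body_length=spec.body_length)
    truth = MovementTruth(
        frequency=spec.frequency, amplitude=spec.amplitude,
        propagation_speed=spec.propagation_speed, origin=spec.origin,
        caudal_speed=spec.caudal_speed, vertex_amplitude=vertex_amp,
        phases=phases,
    )
    return body, truth


# ---------------------------------------------------------------------------
# extracellular-like traces


@dataclass
class TraceSpec:
    """Parameters of synthetic multi-channel bursty traces."""

    channels: tuple = (("left", 0.5), ("left", 2.5))  # (side, position mm)
    cycle_period: float = 250.0       # ms
    burst_duration: float = 77.0      # ms
    propagation_speed: float = 53.8   # mm/s signed, + = caudorostral
    event_rate_in_burst: float = 150.0  # Hz
    jitter: tuple | float = 0.0       # burst-onset jitter, fraction of
                                      # period; scalar or per channel
    dropout: tuple | float = 0.0      # per-channel drop probability, applied
                                      # independently per event and per burst
                                      # (sporadic caudal bursting)
    noise_sd: float = 2.0             # uV
    spike_amp: float = 80.0           # uV
    duration: float = 4.0             # s
    sampling_rate: float = 10000.0    # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burst_duration >= self.cycle_period:
            raise ValueError("burst_duration must be below cycle_period")
        if np.any(np.asarray(self.jitter) < 0):
            raise ValueError("jitter must be non-negative")

    def dropout_for(self, channel_index: int) -> float:
        if np.isscalar(self.dropout):
            return float(self.dropout)
        return float(self.dropout[channel_index])

    def jitter_for(self, channel_index: int) -> float:
        if np.isscalar(self.jitter):
            return float(self.jitter)
        return float(self.jitter[channel_index])


@dataclass
class TraceTruth:
    event_times: list = field(default_factory=list)   # per channel, s
    burst_onsets: list = field(default_factory=list)  # per channel, s


def _spike_kernel(fs: float) -> np.ndarray:
    """Biphasic extracellular spike waveform, ~1.5 ms, unit peak."""
    t = np.arange(-int(0.75e-3 * fs), int(0.75e-3 * fs) + 1) / fs
    sigma = 0.18e-3
    k = -t / sigma * np.exp(0.5 - (t / (np.sqrt(2) * sigma)) ** 2)
    return k / np.abs(k).max()


def make_vr_traces(spec: TraceSpec) -> tuple[list[RhythmTrace], TraceTruth]:
    """Synthesize ventral-root-like channels plus ground-truth event times.

    Burst onsets at each channel follow the longitudinal delay map of the
    configured propagation speed (positive = caudal leads), with optional
    Gaussian onset jitter; events inside a burst are regular at the
    configured rate and each is dropped independently with the channel's
    dropout probability.  Events are rendered as biphasic waveforms on
    i.i.d. Gaussian noise.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.sampling_rate
    n = int(round(spec.duration * fs))
    kernel = _spike_kernel(fs)
    half = kernel.size // 2
    period_s = spec.cycle_period / 1000.0
    positions = np.array([p for _, p in spec.channels], dtype=float)
    x_ref = positions.min()
    delays = (x_ref - positions) / spec.propagation_speed  # s; +v: caudal leads
    max_jit = max(spec.jitter_for(i) for i in range(len(spec.channels)))
    # quiet lead-in long enough that jittered bursts stay clear of the
    # baseline window used for threshold estimation
    offset = 0.05 - min(0.0, float(delays.min())) + 3.0 * max_jit * period_s
    n_cycles = int(np.floor((spec.duration - offset - 0.05) / period_s))

    traces, truth = [], TraceTruth()
    in_burst = np.arange(0.0, spec.burst_duration / 1000.0,
                         1.0 / spec.event_rate_in_burst)
    for ci, (side, pos) in enumerate(spec.channels):
        drop = spec.dropout_for(ci)
        jit = spec.jitter_for(ci)
        onsets, events = [], []
        for c in range(n_cycles):
            onset = c * period_s + delays[ci] + offset
            if jit > 0:
                onset += rng.normal(0.0, jit * period_s)
            if drop > 0 and rng.uniform() < drop:
                continue  # the whole burst fails (sporadic bursting)
            onsets.append(onset)
            for ev in onset + in_burst:
                if drop > 0 and rng.uniform() < drop:
                    continue
                events.append(ev)
        samples = rng.normal(0.0, spec.noise_sd, size=n)
        for ev in events:
            i = int(round(ev * fs))
            lo, hi = i - half, i + half + 1
            if lo < 0 or hi > n:
                continue
            samples[lo:hi] += spec.spike_amp * kernel
        traces.append(RhythmTrace(samples=samples, sampling_rate=fs,
                                  side=side, position=pos,
                                  name=f"ch{ci}"))
        truth.event_times.append(np.asarray(events))
        truth.burst_onsets.append(np.asarray(onsets))
    return traces, truth
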