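"""Midline kinematics of gripped and free-swimming tadpoles.

A tadpole midline is tracked as 11 evenly spaced points from the head
extremity (p1) to the tail tip (p11).  The nine signed curvature angles at
the interior points, their sum (a compact descriptor of overall body
shape: |sum| near 2*pi is a C/O-shaped coil, near pi an S-shaped struggle,
below 0.5*pi a swimming bend), half-cycle segmentation of the sum trace,
cross-correlation propagation speed of the curvature wave, the curvature
origin point of bidirectional struggling waves, and head yaw are computed
here.

Sign convention throughout: a left bend is positive (counter-clockwise
turn of the midline in the tracking plane); propagation speed is positive
when the wave travels caudorostrally (tail to head) and negative
rostrocaudally, in mm/s.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig
from scipy import stats as _stats

from ._signal import dominant_period, nearest_peak_lag

__all__ = [
    "TrackedBody",
    "AngleSet",
    "HalfCycle",
    "PropagationEstimate",
    "OriginEstimate",
    "MovementClass",
    "ClassifyThresholds",
    "compute_curvature_angles",
    "lowpass_sum",
    "detect_half_cycles",
    "classify_movement",
    "propagation_speed",
    "find_curvature_origin",
    "compute_yaw",
]

N_POINTS = 11
N_ANGLES = 9


@dataclass
class TrackedBody:
    """Time series of 11 ordered midline points, head (p1) to tail tip (p11).

    Parameters
    ----------
    times : (n,) array, seconds, strictly increasing and uniform.
    points : (n, 11, 2) or (n, 11, 3) array, coordinates in mm.  NaN marks
        an untracked sample.
    frame_rate : Hz.
    body_length : mm.  Point spacing is assumed equidistant at
        body_length / 10.
    """

    times: np.ndarray
    points: np.ndarray
    frame_rate: float
    body_length: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.points = np.asarray(self.points, dtype=float)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.body_length <= 0:
            raise ValueError("body_length must be positive")
        if self.points.ndim != 3 or self.points.shape[1] != N_POINTS:
            raise ValueError("points must have shape (n_frames, 11, 2|3)")
        if self.points.shape[2] not in (2, 3):
            raise ValueError("points must be 2D or 3D coordinates")
        if self.times.shape[0] != self.points.shape[0]:
            raise ValueError("times and points disagree on frame count")
        dt = np.diff(self.times)
        if dt.size and (np.any(dt <= 0)
                        or np.any(np.abs(dt - 1.0 / self.frame_rate)
                                  > 1.0 / self.frame_rate)):
            raise ValueError("times must be strictly increasing and uniform "
                             "to within one sample interval")

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]

    @property
    def point_spacing(self) -> float:
        return self.body_length / (N_POINTS - 1)

    @classmethod
    def from_points(cls, times, points, frame_rate: float,
                    body_length: float | None = None) -> "TrackedBody":
        """Build a body, inferring body_length from the mean polyline length
        when not given."""
        points = np.asarray(points, dtype=float)
        if body_length is None:
            seg = np.linalg.norm(np.diff(points, axis=1), axis=2)
            body_length = float(np.nanmean(np.nansum(seg, axis=1)))
        return cls(np.asarray(times, dtype=float), points,
                   frame_rate, body_length)


@dataclass
class AngleSet:
    """Nine signed curvature-angle traces (radians) plus their sum."""

    times: np.ndarray
    angles: np.ndarray          # (n_frames, 9), NaN where the frame is bad
    sum_trace: np.ndarray       # (n_frames,)
    vertex_positions: np.ndarray  # mm from head, fractions 0.1..0.9 of length
    frame_rate: float
    filtered: bool = False
    cutoff_hz: float | None = None

    @property
    def valid(self) -> np.ndarray:
        """Per-frame mask: True where all nine angles are finite."""
        return np.all(np.isfinite(self.angles), axis=1)


@dataclass
class HalfCycle:
    """One body bend to a single side, bounded by zero crossings of the
    mean-subtracted sum-of-angles trace."""

    start: float       # s
    end: float         # s
    duration: float    # ms
    amplitude: float   # rad, half of adjacent peak/trough difference
    side: int          # sign of the extremum (+1 left, -1 right)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("half-cycle duration must be positive")
        if self.amplitude < 0:
            raise ValueError("half-cycle amplitude must be non-negative")


@dataclass
class PropagationEstimate:
    """Signed propagation speed of the curvature wave.

    speed > 0: caudorostral (tail-to-head); speed < 0: rostrocaudal.
    ``synchronous`` is set when lags are all sub-sample or the regression
    is not significant (p >= 0.05), in which case speed is NaN.
    """

    speed: float
    regression_p: float
    n_lags: int
    synchronous: bool


@dataclass
class OriginEstimate:
    """Curvature origin of a bidirectional wave (fraction of body length
    from the head) with the one-sided propagation speeds."""

    origin_fraction: float | None
    rostral_speed: float | None   # mm/s, expected > 0 (toward the head)
    caudal_speed: float | None    # mm/s, expected < 0 (toward the tail)
    rostral_p: float | None
    caudal_p: float | None
    caudal_propagation: bool      # False: "no caudal propagation detected"
    defined: bool


@dataclass
class ClassifyThresholds:
    """Amplitude bands (rad) separating the movement classes; centred
    between the reported class means (coiling ~4.1, struggling ~2.4,
    swimming ~1.0 rad)."""

    coil_min: float = 3.2
    struggle_min: float = 1.2


@dataclass
class MovementClass:
    label: str
    amplitude: float
    half_cycle_ms: float
    distances: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# operations

def compute_curvature_angles(body: TrackedBody) -> AngleSet:
    """Signed curvature angles at the nine interior midline points.

    At vertex i the magnitude is the angle between vector a (previous point
    to vertex) and vector b (vertex to next point),
    ``arccos(a.b / |a||b|)``; the sign is the orientation of the turn in
    the tracking plane (z component of a x b), left bend positive.  Frames
    with coincident consecutive points yield NaN for that frame's angles,
    never a silent zero.
    """
    p = body.points
    a = p[:, 1:N_POINTS - 1, :] - p[:, 0:N_POINTS - 2, :]
    b = p[:, 2:N_POINTS, :] - p[:, 1:N_POINTS - 1, :]
    na = np.linalg.norm(a, axis=2)
    nb = np.linalg.norm(b, axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("fij,fij->fi", a, b) / (na * nb)
        mag = np.arccos(np.clip(cosang, -1.0, 1.0))
    cross = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    angles = np.where(cross >= 0, mag, -mag)
    bad = (na < 1e-12) | (nb < 1e-12) | ~np.isfinite(cosang)
    # a bad vertex invalidates the whole frame: the sum would be biased
    angles[np.any(bad, axis=1), :] = np.nan
    positions = np.arange(1, N_ANGLES + 1) / (N_POINTS - 1) * body.body_length
    return AngleSet(
        times=body.times,
        angles=angles,
        sum_trace=angles.sum(axis=1),
        vertex_positions=positions,
        frame_rate=body.frame_rate,
    )


def _fill_nan(x: np.ndarray) -> np.ndarray:
    """Linearly interpolate NaN runs (for filtering only)."""
    x = x.copy()
    bad = ~np.isfinite(x)
    if bad.all():
        raise ValueError("trace contains no finite samples")
    if bad.any():
        idx = np.arange(x.size)
        x[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    return x


def lowpass_sum(angle_set: AngleSet, cutoff: float = 50.0,
                order: int = 4) -> AngleSet:
    """Zero-phase Butterworth low-pass of every angle trace (and their sum).

    Tracking jitter sits well above the movement band; 50 Hz keeps even
    the 20 Hz swimming rhythm untouched.  Filtering is zero-phase
    (forward-backward) so it cannot bias the propagation-lag estimates.
    The original AngleSet is left untouched.
    """
    nyq = angle_set.frame_rate / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz is at or above Nyquist {nyq} Hz")
    sos = _sig.butter(order, cutoff, btype="low", fs=angle_set.frame_rate,
                      output="sos")
    nanmask = ~np.isfinite(angle_set.angles)
    filt = np.empty_like(angle_set.angles)
    for j in range(N_ANGLES):
        filt[:, j] = _sig.sosfiltfilt(sos, _fill_nan(angle_set.angles[:, j]))
    filt[nanmask] = np.nan
    return dataclasses.replace(
        angle_set, angles=filt, sum_trace=filt.sum(axis=1),
        filtered=True, cutoff_hz=cutoff,
    )


def detect_half_cycles(sum_trace: np.ndarray, times: np.ndarray,
                       ) -> list[HalfCycle]:
    """Segment a (filtered) sum-of-angles trace into half cycles.

    Bounds are the zero crossings of the mean-subtracted trace; each half
    cycle holds one extremum and its amplitude is half the difference
    between that extremum and the adjacent opposite one.  A trace shorter
    than one half cycle (or constant) yields an empty list.
    """
    x = np.asarray(sum_trace, dtype=float)
    t = np.asarray(times, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 3:
        return []
    x = _fill_nan(x) - np.nanmean(x)
    s = np.sign(x)
    s[s == 0] = 1
    flips = np.nonzero(s[:-1] != s[1:])[0]
    if flips.size < 2:
        return []
    # zero-crossing times by linear interpolation
    zc = t[flips] + (t[flips + 1] - t[flips]) * (-x[flips]) / (x[flips + 1] - x[flips])
    ext_val = np.empty(flips.size - 1)
    sides = np.empty(flips.size - 1, dtype=int)
    for k in range(flips.size - 1):
        seg = x[flips[k] + 1:flips[k + 1] + 1]
        ext_val[k] = seg[np.argmax(np.abs(seg))]
        sides[k] = 1 if ext_val[k] >= 0 else -1
    cycles = []
    for k in range(flips.size - 1):
        other = ext_val[k + 1] if k + 1 < ext_val.size else ext_val[k - 1]
        amp = 0.5 * abs(ext_val[k] - other)
        cycles.append(HalfCycle(
            start=float(zc[k]), end=float(zc[k + 1]),
            duration=float((zc[k + 1] - zc[k]) * 1000.0),
            amplitude=float(amp), side=int(sides[k]),
        ))
    return cycles


def classify_movement(half_cycles: list[HalfCycle],
                      propagation: PropagationEstimate | None = None,
                      after_release: bool = False,
                      thresholds: ClassifyThresholds | None = None,
                      ) -> MovementClass:
    """Rule-based movement label from half-cycle amplitude and propagation.

    Near-2*pi sums (coils) split into initial vs transitional coiling by the
    release epoch marker; struggling requires caudorostral (or synchronous)
    propagation; swimming requires rostrocaudal propagation.  Epochs that
    satisfy no rule are labelled "unclassified" with the amplitude distance
    to each class band reported.
    """
    if not half_cycles:
        raise ValueError("classification needs at least one half cycle")
    th = thresholds or ClassifyThresholds()
    amp = float(np.mean([abs(h.amplitude) for h in half_cycles]))
    dur = float(np.mean([h.duration for h in half_cycles]))
    dist = {
        "coiling": max(0.0, th.coil_min - amp),
        "struggling": max(0.0, th.struggle_min - amp, amp - th.coil_min),
        "swimming": max(0.0, amp - th.struggle_min),
    }
    prop_dir = None
    if propagation is not None and not propagation.synchronous:
        prop_dir = 1 if propagation.speed > 0 else -1

    if amp >= th.coil_min:
        label = "transitional_coiling" if after_release else "initial_coiling"
    elif amp >= th.struggle_min:
        label = "struggling" if prop_dir in (None, 1) else "unclassified"
    else:
        label = "swimming" if prop_dir == -1 else "unclassified"
    return MovementClass(label=label, amplitude=amp, half_cycle_ms=dur,
                         distances=dist)


def _lags_vs_reference(angle_set: AngleSet, ref: np.ndarray,
                       window_factor: float = 0.6):
    """Cross-correlation lag (s) of each angle trace against a reference."""
    period = dominant_period(ref, angle_set.frame_rate)
    max_lag = window_factor * period if period else None
    lags = np.full(N_ANGLES, np.nan)
    for j in range(N_ANGLES):
        col = angle_set.angles[:, j]
        if not np.any(np.isfinite(col)):
            continue
        lag = nearest_peak_lag(ref, _fill_nan(col), angle_set.frame_rate,
                               max_lag=max_lag)
        if lag is not None:
            lags[j] = lag
    return lags


def propagation_speed(angle_set: AngleSet, ref_index: int = 3,
                      window_factor: float = 0.6,
                      alpha: float = 0.05) -> PropagationEstimate:
    """Curvature-wave propagation speed from cross-correlation lags.

    Each angle trace is cross-correlated against the reference angle
    (alpha4 by default, which usually shows the clearest rhythm); the
    local-maximum lag nearest zero (within +/- window_factor of the
    dominant cycle period) is regressed against vertex position.  The
    signed speed is ``-1/slope`` so that caudorostral propagation (caudal
    vertices leading) is positive.  Estimates with regression p >= alpha,
    or with all lags below one sample, are flagged synchronous and carry
    no finite speed.
    """
    ref = _fill_nan(angle_set.angles[:, ref_index])
    lags = _lags_vs_reference(angle_set, ref, window_factor)
    ok = np.isfinite(lags)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 usable cross-correlation lags")
    x = angle_set.vertex_positions[ok]
    y = lags[ok]
    if np.max(np.abs(y)) < 1.0 / angle_set.frame_rate:
        return PropagationEstimate(np.nan, 1.0, int(ok.sum()), True)
    fit = _stats.linregress(x, y)
    if not np.isfinite(fit.pvalue) or fit.pvalue >= alpha or fit.slope == 0:
        return PropagationEstimate(np.nan, float(fit.pvalue), int(ok.sum()),
                                   True)
    return PropagationEstimate(float(-1.0 / fit.slope), float(fit.pvalue),
                               int(ok.sum()), False)


def find_curvature_origin(angle_set: AngleSet,
                          window_factor: float = 0.6,
                          alpha: float = 0.05) -> OriginEstimate:
    """Locate the vertex from which struggling bends diverge toward head
    and tail.

    Per-angle timing is taken as the cross-correlation lag against the sum
    trace; for each candidate split vertex separate lag-vs-position
    regressions are fitted rostral and caudal of it, and the split with
    opposite-signed slopes minimising the pooled squared residual is the
    origin.  One-sided speeds are ``-1/slope`` (rostral branch positive =
    toward the head; caudal branch negative = toward the tail).  A caudal
    branch without a significant fit is reported as "no caudal propagation
    detected"; if no valid split exists the origin is undefined.
    """
    ref = _fill_nan(angle_set.sum_trace)
    lags = _lags_vs_reference(angle_set, ref, window_factor)
    ok = np.isfinite(lags)
    if ok.sum() < 5:
        return OriginEstimate(None, None, None, None, None, False, False)
    xs = angle_set.vertex_positions
    body_length = xs[-1] / 0.9
    best = None
    for split in range(2, N_ANGLES - 2):
        li = ok & (np.arange(N_ANGLES) <= split)
        ri = ok & (np.arange(N_ANGLES) >= split)
        if li.sum() < 3 or ri.sum() < 3:
            continue
        fr = _stats.linregress(xs[li], lags[li])
        fc = _stats.linregress(xs[ri], lags[ri])
        if not (fr.slope < 0 < fc.slope):
            continue
        sse = (np.sum((lags[li] - fr.intercept - fr.slope * xs[li]) ** 2)
               + np.sum((lags[ri] - fc.intercept - fc.slope * xs[ri]) ** 2))
        if best is None or sse < best[0]:
            best = (sse, split, fr, fc)
    if best is None:
        return OriginEstimate(None, None, None, None, None, False, False)
    _, split, fr, fc = best
    if fr.pvalue >= alpha and fc.pvalue >= alpha:
        return OriginEstimate(None, None, None, float(fr.pvalue),
                              float(fc.pvalue), False, False)
    caudal_ok = fc.pvalue < alpha
    return OriginEstimate(
        origin_fraction=float(xs[split] / body_length),
        rostral_speed=float(-1.0 / fr.slope),
        caudal_speed=float(-1.0 / fc.slope) if caudal_ok else None,
        rostral_p=float(fr.pvalue),
        caudal_p=float(fc.pvalue),
        caudal_propagation=bool(caudal_ok),
        defined=True,
    )


def compute_yaw(body: TrackedBody,
                cycles: list[tuple[float, float]] | None = None):
    """Head-segment yaw, degrees.

    Yaw is the peak-to-peak excursion of the p1->p2 heading angle.  With
    ``cycles`` (list of (start, end) in seconds) one value per cycle is
    returned; otherwise a single value over the whole trace.  Degenerate
    head segments give NaN.
    """
    seg = body.points[:, 1, :2] - body.points[:, 0, :2]
    norm = np.linalg.norm(seg, axis=1)
    heading = np.degrees(np.unwrap(np.arctan2(seg[:, 1], seg[:, 0])))
    heading[norm < 1e-12] = np.nan
    if cycles is None:
        h = heading[np.isfinite(heading)]
        return float(np.ptp(h)) if h.size else float("nan")
    out = []
    for start, end in cycles:
        m = (body.times >= start) & (body.times <= end) & np.isfinite(heading)
        out.append(float(np.ptp(heading[m])) if m.sum() >= 2 else float("nan"))
    return np.asarray(out)
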