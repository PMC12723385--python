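"""Shared cross-correlation and spectral helpers.

Both the kinematic propagation-speed estimate and the two-channel rhythm
propagation use the same primitive: the cross-correlation local maximum
nearest zero lag, refined to sub-sample precision by parabolic
interpolation.  Searching only a window around zero (a fraction of the
dominant cycle period) prevents locking onto a neighbouring cycle of a
periodic signal.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as _sig


def dominant_period(x: np.ndarray, fs: float) -> float | None:
    """Dominant cycle period (s) of a rhythmic trace, from the discrete
    Fourier amplitude peak (DC excluded).  Returns None for traces with no
    oscillatory power (e.g. constant input)."""
    x = np.asarray(x, dtype=float)
    x = x - np.mean(x)
    n = x.size
    if n < 8 or not np.any(x):
        return None
    amp = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    k = int(np.argmax(amp[1:])) + 1
    if freqs[k] <= 0:
        return None
    return 1.0 / freqs[k]


def nearest_peak_lag(
    ref: np.ndarray,
    sig: np.ndarray,
    fs: float,
    max_lag: float | None = None,
) -> float | None:
    """Lag (s) of the cross-correlation local maximum nearest zero lag.

    Positive lag means ``sig`` is delayed relative to ``ref`` (i.e.
    ``sig(t) ~ ref(t - lag)``).  Only local maxima strictly inside the
    search window count; if none exists (e.g. the correlation is monotone
    over the window) the function returns None.  The returned lag is
    refined by fitting a parabola through the peak and its neighbours.

    The maximum of the windowed correlation is used: restricting the
    search to a fraction of the dominant cycle period excludes the
    one-cycle-away aliases, so the windowed maximum is exactly "the peak
    closest to zero lag" while staying robust to ripple riding on the
    envelope (e.g. the in-burst event rhythm of smoothed burst traces).
    """
    ref = np.asarray(ref, dtype=float) - np.mean(ref)
    sig = np.asarray(sig, dtype=float) - np.mean(sig)
    if ref.size < 3 or sig.size < 3:
        return None
    c = _sig.correlate(sig, ref, mode="full")
    lags = _sig.correlation_lags(sig.size, ref.size)
    # unbiased normalisation: the raw sum carries a triangular envelope
    # that pulls large-lag peaks toward zero
    overlap = np.minimum.reduce([
        np.full(lags.shape, sig.size), np.full(lags.shape, ref.size),
        sig.size - lags, ref.size + lags])
    c = c / np.maximum(overlap, 1)
    if max_lag is not None:
        half = max(2, int(round(max_lag * fs)))
        keep = np.abs(lags) <= half
        c, lags = c[keep], lags[keep]
    if c.size < 3:
        return None
    # the correlation maximum inside the window IS the peak closest to
    # zero: period aliases sit one cycle away, outside +/-0.6 T.  A
    # boundary maximum means the correlation is monotone over the window
    # (no interior peak) -> undefined.
    best = int(np.argmax(c))
    if best in (0, c.size - 1):
        return None
    if not (c[best] >= c[best - 1] and c[best] >= c[best + 1]):
        return None
    lag = float(lags[best])
    # parabolic sub-sample refinement
    if 0 < best < c.size - 1:
        denom = c[best - 1] - 2.0 * c[best] + c[best + 1]
        if denom < 0:
            lag += 0.5 * float(c[best - 1] - c[best + 1]) / float(denom)
    return lag / fs
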