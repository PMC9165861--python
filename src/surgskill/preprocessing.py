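"""Surface-EMG preprocessing chain.

Raw EMG (microvolts, typically 2000 Hz) is transformed into an
MVC-normalized rectified envelope through six steps applied in order:

1. linear detrend (removes bias and slow drift),
2. 20-500 Hz Butterworth band-pass,
3. 60 Hz notch (mains interference),
4. 6-sample windowed RMS (the rectification step),
5. 4th-order 5 Hz Butterworth low-pass,
6. division by the muscle's MVC reference.

All IIR filters are applied forward-backward (zero phase) so activation
onset timing is unbiased.  Each step records itself in the envelope's
provenance list.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal

from .types import EMGEnvelope, InvalidArgumentError, SensorChannelSeries

logger = logging.getLogger(__name__)


def _as_series(x: SensorChannelSeries | np.ndarray, fs: float | None) -> tuple[np.ndarray, float]:
    if isinstance(x, SensorChannelSeries):
        return x.samples, x.fs
    if fs is None:
        raise InvalidArgumentError("fs required when passing a bare array")
    return np.asarray(x, dtype=float), float(fs)


def detrend_signal(series: SensorChannelSeries) -> SensorChannelSeries:
    """Remove a least-squares linear trend (constant + slope).

    Strictly more general than mean removal; a constant series maps to
    zeros and a pure ramp is removed exactly.
    """
    if series.samples.size < 2:
        raise InvalidArgumentError("detrend requires at least 2 samples")
    return series.with_samples(signal.detrend(series.samples, type="linear"))


def bandpass_filter(
    series: SensorChannelSeries,
    low: float = 20.0,
    high: float = 500.0,
    order: int = 4,
) -> SensorChannelSeries:
    """Zero-phase Butterworth band-pass.

    At low sampling rates (< 1100 Hz) the upper edge is clamped to
    0.45 * fs with a logged warning so the filter remains realizable.
    """
    fs = series.fs
    if fs < 1100.0 and high > 0.45 * fs:
        logger.warning(
            "band-pass upper edge %.1f Hz clamped to %.1f Hz at fs=%.1f Hz",
            high, 0.45 * fs, fs,
        )
        high = 0.45 * fs
    if not (0 < low < high):
        raise InvalidArgumentError(
            f"band edges must satisfy 0 < low < high, got low={low}, high={high}"
        )
    if high >= fs / 2:
        raise InvalidArgumentError(
            f"upper band edge {high} Hz must be below Nyquist {fs / 2} Hz"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return series.with_samples(signal.sosfiltfilt(sos, series.samples))


def notch_filter(
    series: SensorChannelSeries, f0: float = 60.0, q: float = 30.0
) -> SensorChannelSeries:
    """Zero-phase IIR notch attenuating mains interference at ``f0`` Hz."""
    fs = series.fs
    if not (0 < f0 < fs / 2):
        raise InvalidArgumentError(f"notch frequency {f0} Hz must be below Nyquist {fs / 2} Hz")
    b, a = signal.iirnotch(f0, q, fs=fs)
    return series.with_samples(signal.filtfilt(b, a, series.samples))


def rms_envelope(series: SensorChannelSeries, window: int = 6) -> SensorChannelSeries:
    """Windowed root-mean-square rectification.

    Centered moving window with edge truncation: near the boundaries the
    effective window shrinks to the overlap with the series.
    """
    x = series.samples
    n = x.size
    if window < 1:
        raise InvalidArgumentError("window must be >= 1")
    if window > n:
        raise InvalidArgumentError(f"window {window} exceeds series length {n}")
    sq = np.concatenate(([0.0], np.cumsum(x * x)))
    idx = np.arange(n)
    start = np.clip(idx - (window - 1) // 2, 0, n)
    stop = np.clip(start + window, 0, n)
    start = np.minimum(start, stop)  # keep windows valid at the tail
    counts = stop - start
    means = (sq[stop] - sq[start]) / counts
    return series.with_samples(np.sqrt(means))


def lowpass_envelope(
    series: SensorChannelSeries, cutoff: float = 5.0, order: int = 4
) -> SensorChannelSeries:
    """Zero-phase Butterworth low-pass smoothing of the rectified signal.

    Output is clipped at zero: smoothing ringing must not produce a
    negative envelope.
    """
    fs = series.fs
    if not (0 < cutoff < fs / 2):
        raise InvalidArgumentError(f"cutoff {cutoff} Hz must be below Nyquist {fs / 2} Hz")
    sos = signal.butter(order, cutoff, btype="lowpass", fs=fs, output="sos")
    out = signal.sosfiltfilt(sos, series.samples)
    return series.with_samples(np.clip(out, 0.0, None))


def normalize_mvc(series: SensorChannelSeries, mvc_value: float,
                  provenance: tuple[str, ...] = ()) -> EMGEnvelope:
    """Express the envelope as a fraction of maximum voluntary contraction."""
    if mvc_value <= 0:
        raise InvalidArgumentError("mvc_value must be positive")
    return EMGEnvelope(
        samples=series.samples / mvc_value,
        fs=series.fs,
        provenance=provenance + (f"mvc_normalize:{mvc_value:g}",),
    )


def preprocess_emg(
    raw: SensorChannelSeries,
    mvc_value: float,
    *,
    band: tuple[float, float] = (20.0, 500.0),
    notch_hz: float = 60.0,
    notch_q: float = 30.0,
    rms_window: int = 6,
    lowpass_hz: float = 5.0,
    lowpass_order: int = 4,
) -> EMGEnvelope:
    """Apply the full six-step chain and return the normalized envelope."""
    steps = []
    x = detrend_signal(raw)
    steps.append("detrend:linear")
    x = bandpass_filter(x, band[0], band[1])
    steps.append(f"bandpass:{band[0]:g}-{band[1]:g}Hz")
    x = notch_filter(x, notch_hz, notch_q)
    steps.append(f"notch:{notch_hz:g}Hz,Q={notch_q:g}")
    x = rms_envelope(x, rms_window)
    steps.append(f"rms_window:{rms_window}")
    x = lowpass_envelope(x, lowpass_hz, lowpass_order)
    steps.append(f"lowpass:{lowpass_hz:g}Hz,order={lowpass_order}")
    return normalize_mvc(x, mvc_value, provenance=tuple(steps))
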