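"""Linear muscular-workload features from preprocessed EMG.

Six features summarize each recording:

* **CMW** — cumulative muscular workload, the time integral of the
  MVC-normalized envelope over the task (units: MVC-fraction * s);
* **AWS** — average work per second, CMW / performance time;
* **TotalTime** — duration of muscular activity between the first onset
  and the last cessation, where activity means the envelope exceeds a
  baseline-derived threshold of mean + 5 * SD;
* **RMS** and **Range** — linear variability of the envelope;
* **DominantFreq** — the frequency with the highest power in the
  zero-padded periodogram of the filtered EMG (muscle firing frequency).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .preprocessing import bandpass_filter, detrend_signal, notch_filter, preprocess_emg
from .types import (
    EMGEnvelope,
    InvalidArgumentError,
    Recording,
    SensorChannelSeries,
    UndefinedResultError,
)

logger = logging.getLogger(__name__)

EMG_FEATURE_NAMES = ("CMW", "AWS", "TotalTime", "RMS", "Range", "DominantFreq")


@dataclass(frozen=True)
class ActivationThreshold:
    """Activity threshold derived from a resting baseline segment."""

    value: float
    baseline_mean: float
    baseline_sd: float


@dataclass(frozen=True)
class ActivityWindow:
    onset_time: float | None
    cessation_time: float | None
    total_time: float

    @property
    def active(self) -> bool:
        return self.onset_time is not None


def compute_threshold(baseline: EMGEnvelope | np.ndarray) -> ActivationThreshold:
    """Threshold = baseline mean + 5 * baseline SD (sample SD, n-1)."""
    x = baseline.samples if isinstance(baseline, EMGEnvelope) else np.asarray(baseline, float)
    if x.size < 2:
        raise InvalidArgumentError("baseline must contain at least 2 samples")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    return ActivationThreshold(value=mean + 5.0 * sd, baseline_mean=mean, baseline_sd=sd)


def detect_activity(
    envelope: EMGEnvelope, threshold: ActivationThreshold | float
) -> ActivityWindow:
    """First onset and last cessation of supra-threshold activity.

    Samples strictly above the threshold count as active.  A recording
    that never crosses the threshold yields ``total_time = 0`` with onset
    and cessation absent (not an error).
    """
    thr = threshold.value if isinstance(threshold, ActivationThreshold) else float(threshold)
    above = envelope.samples > thr
    if not above.any():
        return ActivityWindow(onset_time=None, cessation_time=None, total_time=0.0)
    idx = np.flatnonzero(above)
    onset = idx[0] / envelope.fs
    cessation = idx[-1] / envelope.fs
    return ActivityWindow(onset, cessation, cessation - onset)


def cumulative_muscular_workload(envelope: EMGEnvelope) -> float:
    """Trapezoidal time integral of the normalized envelope over the task."""
    if not any(step.startswith("mvc_normalize") for step in envelope.provenance):
        logger.warning("computing CMW on an envelope without MVC-normalization provenance")
    return float(np.trapezoid(envelope.samples, dx=1.0 / envelope.fs))


def average_work_per_second(cmw: float, performance_time: float) -> float:
    """AWS = CMW / performance time (whole-trial duration by default)."""
    if performance_time <= 0:
        raise InvalidArgumentError("performance_time must be positive")
    return cmw / performance_time


def emg_rms(x: np.ndarray | EMGEnvelope) -> float:
    x = x.samples if isinstance(x, EMGEnvelope) else np.asarray(x, float)
    if x.size < 1:
        raise InvalidArgumentError("empty signal")
    return float(np.sqrt(np.mean(x * x)))


def signal_range(x: np.ndarray | EMGEnvelope) -> float:
    x = x.samples if isinstance(x, EMGEnvelope) else np.asarray(x, float)
    if x.size < 1:
        raise InvalidArgumentError("empty signal")
    return float(np.max(x) - np.min(x))


def dominant_frequency(x: np.ndarray, fs: float) -> float:
    """Peak of the zero-padded power spectral density, DC excluded.

    The signal is detrended, zero-padded to the next power of two, and the
    squared modulus of its FFT taken as the raw PSD.  Ties break toward
    the lowest frequency.  An (effectively) all-zero signal has no
    dominant frequency and raises :class:`UndefinedResultError`.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 16:
        raise InvalidArgumentError("dominant_frequency requires at least 16 samples")
    x = sps.detrend(x, type="linear")
    nfft = 1 << int(np.ceil(np.log2(x.size)))
    spec = np.abs(np.fft.rfft(x, n=nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    spec = spec[1:]  # exclude the DC bin
    freqs = freqs[1:]
    if not np.any(spec > 0):
        raise UndefinedResultError("all-zero signal has no dominant frequency")
    return float(freqs[int(np.argmax(spec))])


@dataclass(frozen=True)
class EMGFeatureSet:
    cmw: float
    aws: float
    total_time: float
    rms: float
    range: float
    dominant_freq: float
    onset_time: float | None
    cessation_time: float | None

    def as_dict(self) -> dict[str, float]:
        return {
            "CMW": self.cmw,
            "AWS": self.aws,
            "TotalTime": self.total_time,
            "RMS": self.rms,
            "Range": self.range,
            "DominantFreq": self.dominant_freq,
        }


def emg_features_from_envelope(
    env: EMGEnvelope,
    baseline_env: EMGEnvelope,
    raw_emg: SensorChannelSeries | None = None,
) -> EMGFeatureSet:
    """Linear feature set from a preprocessed envelope and baseline.

    CMW/AWS/TotalTime/RMS/Range come from the MVC-normalized envelope;
    the dominant firing frequency comes from the detrended, band-passed,
    notch-filtered raw EMG (the envelope's 5 Hz low-pass would erase the
    firing spectrum) and is absent when no raw signal is supplied.
    """
    thr = compute_threshold(baseline_env)
    act = detect_activity(env, thr)
    cmw = cumulative_muscular_workload(env)
    aws = average_work_per_second(cmw, env.duration)
    dom = float("nan")
    if raw_emg is not None:
        filtered = notch_filter(bandpass_filter(detrend_signal(raw_emg)))
        try:
            dom = dominant_frequency(filtered.samples, raw_emg.fs)
        except UndefinedResultError:
            pass
    return EMGFeatureSet(
        cmw=cmw,
        aws=aws,
        total_time=act.total_time,
        rms=emg_rms(env),
        range=signal_range(env),
        dominant_freq=dom,
        onset_time=act.onset_time,
        cessation_time=act.cessation_time,
    )


def emg_feature_vector(recording: Recording, **preprocess_kwargs) -> EMGFeatureSet:
    """Full linear feature set for one recording.

    Runs the preprocessing chain on the task and baseline channels (with
    the recording's MVC reference) and delegates to
    :func:`emg_features_from_envelope`.
    """
    env = preprocess_emg(recording.emg, recording.mvc_value, **preprocess_kwargs)
    baseline_env = preprocess_emg(
        recording.baseline_emg, recording.mvc_value, **preprocess_kwargs
    )
    return emg_features_from_envelope(env, baseline_env, raw_emg=recording.emg)
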