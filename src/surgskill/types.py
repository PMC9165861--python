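"""Core domain types for wearable surgical-skill recordings.

A recording unit is one (subject, skill, task, trial, muscle, side)
combination carrying a single surface-EMG channel (2000 Hz, microvolts)
and a triaxial accelerometer (100 Hz, g), plus a resting-baseline EMG
segment and an MVC (maximum voluntary contraction) reference used to
normalize muscle activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

SKILLS = ("novice", "intermediate", "expert")
TASKS = ("knot_tying", "pegboard", "robotic_suturing")
MUSCLES = ("biceps", "triceps", "deltoid", "ECU", "FCU", "TE")
SIDES = ("left", "right")

CHANNEL_KINDS = ("emg", "acc_x", "acc_y", "acc_z")

DEFAULT_EMG_FS = 2000.0
DEFAULT_ACC_FS = 100.0


class InvalidArgumentError(ValueError):
    """Raised when an operation receives arguments violating its contract."""


class UndefinedResultError(RuntimeError):
    """Raised when a quantity is mathematically undefined for the input.

    Estimators raise this instead of silently substituting 0 or infinity
    (e.g. sample entropy with no template matches, correlation dimension
    of a constant series).
    """


class CorruptDatasetError(RuntimeError):
    """Raised when an on-disk dataset is inconsistent with its manifest."""


@dataclass(frozen=True)
class SensorChannelSeries:
    """One uniformly sampled sensor channel.

    Parameters
    ----------
    samples : array of float
        Signal values — microvolts for EMG, g for acceleration.
    fs : float
        Sampling rate in Hz, > 0.
    kind : str
        One of ``emg``, ``acc_x``, ``acc_y``, ``acc_z``.
    """

    samples: np.ndarray
    fs: float
    kind: str = "emg"

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", arr)
        if self.fs <= 0:
            raise InvalidArgumentError(f"sampling rate must be positive, got {self.fs}")
        if arr.ndim != 1 or arr.size < 1:
            raise InvalidArgumentError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(arr)):
            raise InvalidArgumentError("samples must all be finite")
        if self.kind not in CHANNEL_KINDS:
            raise InvalidArgumentError(
                f"kind must be one of {CHANNEL_KINDS}, got {self.kind!r}"
            )

    @property
    def duration(self) -> float:
        """Wall-clock span covered by the samples, in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs

    def with_samples(self, samples: np.ndarray) -> "SensorChannelSeries":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass(frozen=True)
class Recording:
    """All channels for one (subject, skill, task, trial, muscle, side) unit."""

    subject_id: str
    skill: str
    task: str
    trial: int
    muscle: str
    side: str
    emg: SensorChannelSeries
    acc_x: SensorChannelSeries
    acc_y: SensorChannelSeries
    acc_z: SensorChannelSeries
    baseline_emg: SensorChannelSeries
    mvc_value: float

    def __post_init__(self) -> None:
        if self.skill not in SKILLS:
            raise InvalidArgumentError(f"unknown skill {self.skill!r}")
        if self.task not in TASKS:
            raise InvalidArgumentError(f"unknown task {self.task!r}")
        if self.muscle not in MUSCLES:
            raise InvalidArgumentError(f"unknown muscle {self.muscle!r}")
        if self.side not in SIDES:
            raise InvalidArgumentError(f"unknown side {self.side!r}")
        if self.trial < 1:
            raise InvalidArgumentError("trial must be a positive integer")
        if self.mvc_value <= 0:
            raise InvalidArgumentError("mvc_value must be positive")
        # All channels must span the same wall-clock duration (within one
        # sample period of the slowest channel).
        durs = [c.duration for c in (self.emg, self.acc_x, self.acc_y, self.acc_z)]
        tol = 1.0 / min(c.fs for c in (self.emg, self.acc_x))
        if max(durs) - min(durs) > tol + 1e-12:
            raise InvalidArgumentError(
                f"channel durations differ by more than one sample period: {durs}"
            )
        if self.baseline_emg.duration > self.emg.duration + tol:
            raise InvalidArgumentError("baseline segment longer than task channel")

    @property
    def key(self) -> tuple:
        return (self.subject_id, self.task, self.trial, self.muscle, self.side)

    @property
    def acc_channels(self) -> tuple[SensorChannelSeries, ...]:
        return (self.acc_x, self.acc_y, self.acc_z)


@dataclass(frozen=True)
class MuscleActivationProfile:
    """Statistical description of a muscle's burst activity during a task.

    ``burst_amplitude`` is expressed as a fraction of the subject's MVC
    envelope amplitude; ``baseline_noise_sd`` is in microvolts.
    """

    burst_rate: float  # bursts / s
    burst_duration_mean: float  # s
    burst_amplitude: float  # fraction of MVC
    baseline_noise_sd: float  # uV
    task_duration: float  # s

    def __post_init__(self) -> None:
        if self.burst_rate <= 0 or self.burst_duration_mean <= 0:
            raise InvalidArgumentError("burst rate and duration must be positive")
        if not (0.0 <= self.burst_amplitude <= 1.5):
            raise InvalidArgumentError("burst_amplitude must lie in [0, 1.5]")
        if self.baseline_noise_sd < 0:
            raise InvalidArgumentError("baseline_noise_sd must be non-negative")
        if self.task_duration <= 0:
            raise InvalidArgumentError("task_duration must be positive")


@dataclass(frozen=True)
class MovementComplexityProfile:
    """Mixture weights controlling the complexity of simulated movement.

    Each accelerometer axis is a convex mixture of a sinusoid (regular,
    well-practised movement), a chaotic-flow trajectory (structured but
    unpredictable variability) and white noise, scaled to ``amplitude`` g.
    """

    periodic_weight: float
    chaotic_weight: float
    noise_weight: float
    amplitude: float = 0.5  # g
    base_frequency: float = 1.5  # Hz

    def __post_init__(self) -> None:
        w = (self.periodic_weight, self.chaotic_weight, self.noise_weight)
        if any(x < 0 for x in w):
            raise InvalidArgumentError("mixture weights must be non-negative")
        if abs(sum(w) - 1.0) > 1e-9:
            raise InvalidArgumentError(f"mixture weights must sum to 1, got {sum(w)}")
        if self.amplitude <= 0:
            raise InvalidArgumentError("amplitude must be positive")
        if self.base_frequency <= 0:
            raise InvalidArgumentError("base_frequency must be positive")

    @property
    def weights(self) -> tuple[float, float, float]:
        return (self.periodic_weight, self.chaotic_weight, self.noise_weight)


@dataclass(frozen=True)
class EMGEnvelope:
    """MVC-normalized rectified EMG envelope with processing provenance."""

    samples: np.ndarray
    fs: float
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", arr)
        object.__setattr__(self, "provenance", tuple(self.provenance))
        if self.fs <= 0:
            raise InvalidArgumentError("fs must be positive")
        if np.any(arr < 0):
            raise InvalidArgumentError("envelope samples must be non-negative")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs
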