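"""Synthetic multi-sensor surgical-task cohort generator.

Emulates the statistical structure the downstream analysis assumes:

* surface-EMG channels (2000 Hz) built as band-limited Gaussian carriers
  (20-450 Hz, inside the analysis band) modulated by a burst envelope whose
  rate, duration and amplitude differ by skill group — so cumulative
  muscular workload, activation time and firing statistics separate the
  groups;
* triaxial accelerometer channels (100 Hz) built as a convex mixture of a
  sinusoid, a chaotic Lorenz-flow trajectory and white noise — so entropy,
  correlation-dimension and Lyapunov features separate the groups.

Every generator output is a pure function of (config, seed).  Datasets are
written as plain delimited text plus a YAML manifest and round-trip
losslessly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal

from .types import (
    MUSCLES,
    SIDES,
    SKILLS,
    TASKS,
    CorruptDatasetError,
    InvalidArgumentError,
    MovementComplexityProfile,
    MuscleActivationProfile,
    Recording,
    SensorChannelSeries,
)

logger = logging.getLogger(__name__)

MANIFEST_NAME = "manifest.yaml"

# Lorenz-63 canonical parameters; largest Lyapunov exponent ~0.9056 per
# unit flow time (used as the chaotic benchmark by the validation suite).
LORENZ_SIGMA, LORENZ_RHO, LORENZ_BETA = 10.0, 28.0, 8.0 / 3.0
LORENZ_LARGEST_LYAPUNOV = 0.9056  # per unit flow time


def lorenz_trajectory(
    n: int,
    dt: float = 0.01,
    discard: int = 1000,
    x0: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Integrate the Lorenz-63 flow with fixed-step RK4.

    Returns an ``(n, 3)`` array of the (x, y, z) state after discarding an
    initial transient of ``discard`` steps.
    """
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")

    def deriv(s: np.ndarray) -> np.ndarray:
        x, y, z = s
        return np.array(
            [
                LORENZ_SIGMA * (y - x),
                x * (LORENZ_RHO - z) - y,
                x * y - LORENZ_BETA * z,
            ]
        )

    s = np.asarray(x0, dtype=float)
    out = np.empty((n, 3))
    total = discard + n
    for i in range(total):
        k1 = deriv(s)
        k2 = deriv(s + 0.5 * dt * k1)
        k3 = deriv(s + 0.5 * dt * k2)
        k4 = deriv(s + dt * k3)
        s = s + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if i >= discard:
            out[i - discard] = s
    return out


def bandlimited_noise(
    n: int,
    fs: float,
    rng: np.random.Generator,
    low: float = 20.0,
    high: float = 450.0,
) -> np.ndarray:
    """Zero-mean unit-SD Gaussian noise band-passed to [low, high] Hz.

    The band sits inside the 20-500 Hz analysis band so that the
    preprocessing chain does not destroy the simulated signal energy.
    """
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    white = rng.standard_normal(n)
    high = min(high, 0.49 * fs)
    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white)
    sd = x.std()
    if sd > 0:
        x = x / sd
    return x - x.mean()


def burst_envelope(
    profile: MuscleActivationProfile,
    fs: float,
    rng: np.random.Generator,
    mvc_scale_uv: float = 400.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a burst amplitude envelope in microvolts.

    Bursts are Hann-shaped bumps with Poisson-drawn count, uniform centers
    and jittered durations/amplitudes; overlapping bursts take the
    pointwise maximum so the envelope never stacks above the drawn burst
    amplitude.  Returns ``(envelope_uv, burst_centers_s)``.
    """
    n = int(round(profile.task_duration * fs))
    if n < 1:
        raise InvalidArgumentError("task_duration * fs must give >= 1 sample")
    env = np.zeros(n)
    n_bursts = rng.poisson(profile.burst_rate * profile.task_duration)
    centers = np.sort(rng.uniform(0.0, profile.task_duration, size=n_bursts))
    t = np.arange(n) / fs
    for c in centers:
        dur = max(0.15 * profile.burst_duration_mean,
                  profile.burst_duration_mean * (1.0 + 0.2 * rng.standard_normal()))
        amp = np.clip(
            profile.burst_amplitude * (1.0 + 0.1 * rng.standard_normal()), 0.0, 1.5
        ) * mvc_scale_uv
        lo, hi = c - dur / 2.0, c + dur / 2.0
        mask = (t >= lo) & (t <= hi)
        if not mask.any():
            continue
        bump = amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * (t[mask] - lo) / dur))
        env[mask] = np.maximum(env[mask], bump)
    return env, centers


def modulated_emg(
    envelope_uv: np.ndarray,
    baseline_noise_sd: float,
    fs: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Multiply a band-limited carrier by an amplitude envelope (µV)."""
    n = envelope_uv.size
    carrier = bandlimited_noise(n, fs, rng)
    out = carrier * envelope_uv
    if baseline_noise_sd > 0:
        out = out + baseline_noise_sd * bandlimited_noise(n, fs, rng)
    return out


def generate_emg_channel(
    profile: MuscleActivationProfile,
    fs: float = 2000.0,
    seed: int = 0,
    mvc_scale_uv: float = 400.0,
) -> SensorChannelSeries:
    """Generate one synthetic surface-EMG channel.

    Deterministic: identical (profile, fs, seed) give identical samples.
    """
    if fs < 1000:
        raise InvalidArgumentError("EMG sampling rate must be >= 1000 Hz")
    samples, _env = _emg_with_envelope(profile, fs, np.random.default_rng(seed),
                                       mvc_scale_uv)
    return SensorChannelSeries(samples=samples, fs=fs, kind="emg")


def _emg_with_envelope(
    profile: MuscleActivationProfile,
    fs: float,
    rng: np.random.Generator,
    mvc_scale_uv: float,
) -> tuple[np.ndarray, np.ndarray]:
    env, _ = burst_envelope(profile, fs, rng, mvc_scale_uv)
    return modulated_emg(env, profile.baseline_noise_sd, fs, rng), env


def generate_baseline_emg(
    profile: MuscleActivationProfile,
    fs: float = 2000.0,
    duration: float = 5.0,
    seed: int = 0,
) -> SensorChannelSeries:
    """Resting-segment EMG: baseline noise only, no bursts."""
    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    if profile.baseline_noise_sd > 0:
        samples = profile.baseline_noise_sd * bandlimited_noise(n, fs, rng)
    else:
        samples = np.zeros(n)
    return SensorChannelSeries(samples=samples, fs=fs, kind="emg")


def generate_acc_channels(
    profile: MovementComplexityProfile,
    duration: float,
    fs: float = 100.0,
    seed: int = 0,
) -> tuple[SensorChannelSeries, SensorChannelSeries, SensorChannelSeries]:
    """Generate three accelerometer axes with controlled complexity.

    Each axis = periodic_weight * sinusoid + chaotic_weight * (normalized
    Lorenz trajectory component) + noise_weight * white noise, each
    component peak-normalized, the mixture scaled by ``amplitude``.  The
    resultant magnitude is therefore bounded by amplitude * sqrt(3).
    """
    if duration <= 0 or fs <= 0:
        raise InvalidArgumentError("duration and fs must be positive")
    n = int(round(duration * fs))
    if n < 2:
        raise InvalidArgumentError("duration * fs must give >= 2 samples")
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    phases = rng.uniform(0, 2 * np.pi, size=3)
    need_chaos = profile.chaotic_weight > 0
    if need_chaos:
        x0 = tuple(np.array([1.0, 1.0, 1.0]) + 0.1 * rng.standard_normal(3))
        traj = lorenz_trajectory(n, dt=0.01, discard=1000, x0=x0)
    kinds = ("acc_x", "acc_y", "acc_z")
    out = []
    for ax in range(3):
        periodic = np.sin(2 * np.pi * profile.base_frequency * t + phases[ax])
        parts = profile.periodic_weight * periodic
        if need_chaos:
            c = traj[:, ax]
            c = c - c.mean()
            peak = np.max(np.abs(c))
            if peak > 0:
                c = c / peak
            parts = parts + profile.chaotic_weight * c
        if profile.noise_weight > 0:
            w = rng.standard_normal(n)
            peak = np.max(np.abs(w))
            if peak > 0:
                w = w / peak
            parts = parts + profile.noise_weight * w
        out.append(
            SensorChannelSeries(samples=profile.amplitude * parts, fs=fs, kind=kinds[ax])
        )
    return tuple(out)


# -- cohort configuration -------------------------------------------------

#: Per-skill activation templates.  Novices fire longer, harder bursts;
#: experts produce shorter, lighter, sparser activity.
DEFAULT_ACTIVATION_TEMPLATES: dict[str, MuscleActivationProfile] = {
    "novice": MuscleActivationProfile(
        burst_rate=0.60, burst_duration_mean=1.2, burst_amplitude=0.55,
        baseline_noise_sd=8.0, task_duration=60.0,
    ),
    "intermediate": MuscleActivationProfile(
        burst_rate=0.50, burst_duration_mean=1.0, burst_amplitude=0.42,
        baseline_noise_sd=8.0, task_duration=60.0,
    ),
    "expert": MuscleActivationProfile(
        burst_rate=0.42, burst_duration_mean=0.8, burst_amplitude=0.30,
        baseline_noise_sd=8.0, task_duration=60.0,
    ),
}

#: Per-skill movement-complexity templates.  Novice movement is dominated
#: by irregular corrections (noise); expert movement is smooth and
#: repeatable (periodic); the chaotic share models structured variability.
DEFAULT_COMPLEXITY_TEMPLATES: dict[str, MovementComplexityProfile] = {
    "novice": MovementComplexityProfile(0.20, 0.35, 0.45),
    "intermediate": MovementComplexityProfile(0.40, 0.35, 0.25),
    "expert": MovementComplexityProfile(0.60, 0.30, 0.10),
}

#: Task completion times in seconds per (skill, task).  Knot tying takes
#: all groups a similar time; novices are markedly slower on pegboard
#: transfer and robotic suturing.
DEFAULT_TASK_DURATIONS: dict[str, dict[str, float]] = {
    "novice": {"knot_tying": 50.0, "pegboard": 110.0, "robotic_suturing": 100.0},
    "intermediate": {"knot_tying": 48.0, "pegboard": 85.0, "robotic_suturing": 75.0},
    "expert": {"knot_tying": 45.0, "pegboard": 70.0, "robotic_suturing": 65.0},
}


@dataclass(frozen=True)
class CohortConfig:
    """Configuration for a full synthetic cohort.

    Defaults mirror the study design: 10 novice / 11 intermediate / 5
    expert subjects, three tasks with at least three trials each, six
    bilateral muscle sites.  ``informative_muscles=None`` means every
    muscle carries the skill-dependent structure; a subset restricts the
    group signal to those muscles (the others use a skill-independent
    profile), which is how planted-signal validation cohorts are built.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"novice": 10, "intermediate": 11, "expert": 5}
    )
    tasks: tuple[str, ...] = TASKS
    trials_per_task: int = 3
    muscles: tuple[str, ...] = MUSCLES
    sides: tuple[str, ...] = SIDES
    activation_templates: dict[str, MuscleActivationProfile] = field(
        default_factory=lambda: dict(DEFAULT_ACTIVATION_TEMPLATES)
    )
    complexity_templates: dict[str, MovementComplexityProfile] = field(
        default_factory=lambda: dict(DEFAULT_COMPLEXITY_TEMPLATES)
    )
    task_durations: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TASK_DURATIONS.items()}
    )
    subject_jitter: float = 0.08  # relative between-subject spread
    informative_muscles: tuple[str, ...] | None = None
    emg_fs: float = 2000.0
    acc_fs: float = 100.0
    baseline_duration: float = 5.0
    mvc_scale_uv: float = 400.0
    mvc_multiple: float = 2.0  # MVC reference = multiple of max task envelope
    seed: int = 0

    def __post_init__(self) -> None:
        for skill in SKILLS:
            if skill not in self.group_sizes:
                raise InvalidArgumentError(f"group_sizes missing skill {skill!r}")
            if self.group_sizes[skill] < 1:
                raise InvalidArgumentError(f"empty group {skill!r}")
        if self.trials_per_task < 1:
            raise InvalidArgumentError("trials_per_task must be >= 1")
        for m in self.muscles:
            if m not in MUSCLES:
                raise InvalidArgumentError(f"unknown muscle {m!r}")
        if self.informative_muscles is not None:
            for m in self.informative_muscles:
                if m not in MUSCLES:
                    raise InvalidArgumentError(f"unknown muscle {m!r}")


def _jitter_activation(
    p: MuscleActivationProfile, rel: float, rng: np.random.Generator
) -> MuscleActivationProfile:
    j = lambda v: float(v * np.exp(rel * rng.standard_normal()))  # noqa: E731
    return MuscleActivationProfile(
        burst_rate=j(p.burst_rate),
        burst_duration_mean=j(p.burst_duration_mean),
        burst_amplitude=float(np.clip(j(p.burst_amplitude), 0.01, 1.5)),
        baseline_noise_sd=j(p.baseline_noise_sd),
        task_duration=p.task_duration,
    )


def _jitter_complexity(
    p: MovementComplexityProfile, rel: float, rng: np.random.Generator
) -> MovementComplexityProfile:
    w = np.array(p.weights) + 0.5 * rel * rng.standard_normal(3)
    w = np.clip(w, 0.0, None)
    if w.sum() == 0:
        w = np.array(p.weights)
    w = w / w.sum()
    return MovementComplexityProfile(
        periodic_weight=float(w[0]),
        chaotic_weight=float(w[1]),
        noise_weight=float(w[2]),
        amplitude=float(p.amplitude * np.exp(rel * rng.standard_normal())),
        base_frequency=p.base_frequency,
    )


def generate_cohort(config: CohortConfig) -> list[Recording]:
    """Generate one Recording per (subject x task x trial x muscle x side).

    Fully reproducible from ``config.seed``: subject-level profile jitter
    and every channel draw derive from a spawned seed sequence.
    """
    root_ss = np.random.SeedSequence(config.seed)
    recordings: list[Recording] = []
    subject_index = 0
    for skill in SKILLS:
        n_subj = config.group_sizes[skill]
        for s in range(n_subj):
            subject_index += 1
            subject_id = f"S{subject_index:03d}"
            subj_ss = np.random.SeedSequence(
                entropy=config.seed, spawn_key=(subject_index,)
            )
            subj_rng = np.random.default_rng(subj_ss)
            mvc_scale = config.mvc_scale_uv * float(
                np.exp(0.15 * subj_rng.standard_normal())
            )
            # subject-level jittered templates, one per skill role
            act = _jitter_activation(
                config.activation_templates[skill], config.subject_jitter, subj_rng
            )
            cx = _jitter_complexity(
                config.complexity_templates[skill], config.subject_jitter, subj_rng
            )
            neutral_act = _jitter_activation(
                config.activation_templates["intermediate"],
                config.subject_jitter,
                subj_rng,
            )
            neutral_cx = _jitter_complexity(
                config.complexity_templates["intermediate"],
                config.subject_jitter,
                subj_rng,
            )
            neutral_dur = config.task_durations["intermediate"]
            for ti, task in enumerate(config.tasks):
                for trial in range(1, config.trials_per_task + 1):
                    for mi, muscle in enumerate(config.muscles):
                        informative = (
                            config.informative_muscles is None
                            or muscle in config.informative_muscles
                        )
                        base_act = act if informative else neutral_act
                        base_cx = cx if informative else neutral_cx
                        durs = (
                            config.task_durations[skill] if informative else neutral_dur
                        )
                        duration = durs[task] * float(
                            np.exp(0.05 * subj_rng.standard_normal())
                        )
                        profile = replace(base_act, task_duration=duration)
                        for si, side in enumerate(config.sides):
                            unit_ss = np.random.SeedSequence(
                                entropy=config.seed,
                                spawn_key=(subject_index, ti, trial, mi, si),
                            )
                            rng = np.random.default_rng(unit_ss)
                            samples, env = _emg_with_envelope(
                                profile, config.emg_fs, rng, mvc_scale
                            )
                            emg = SensorChannelSeries(
                                samples=samples, fs=config.emg_fs, kind="emg"
                            )
                            base_n = int(
                                round(
                                    min(config.baseline_duration, duration)
                                    * config.emg_fs
                                )
                            )
                            base_samples = (
                                profile.baseline_noise_sd
                                * bandlimited_noise(base_n, config.emg_fs, rng)
                                if profile.baseline_noise_sd > 0
                                else np.zeros(base_n)
                            )
                            baseline = SensorChannelSeries(
                                samples=base_samples, fs=config.emg_fs, kind="emg"
                            )
                            peak = max(float(env.max()), profile.baseline_noise_sd, 1.0)
                            mvc_value = config.mvc_multiple * peak
                            acc_seed = int(rng.integers(0, 2**31 - 1))
                            ax, ay, az = generate_acc_channels(
                                base_cx, duration, config.acc_fs, seed=acc_seed
                            )
                            recordings.append(
                                Recording(
                                    subject_id=subject_id,
                                    skill=skill,
                                    task=task,
                                    trial=trial,
                                    muscle=muscle,
                                    side=side,
                                    emg=emg,
                                    acc_x=ax,
                                    acc_y=ay,
                                    acc_z=az,
                                    baseline_emg=baseline,
                                    mvc_value=mvc_value,
                                )
                            )
    return recordings


# -- dataset serialization ------------------------------------------------


def _stem(rec: Recording) -> str:
    return f"{rec.subject_id}_{rec.task}_{rec.trial}_{rec.muscle}_{rec.side}"


def write_dataset(recordings: list[Recording], directory: str | Path) -> Path:
    """Write a cohort as delimited-text channel files plus a YAML manifest.

    Samples are written with 17 significant digits so the text round-trip
    reproduces every float bit-exactly.  Returns the manifest path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in recordings:
        stem = _stem(rec)
        emg_file = f"{stem}.csv"
        acc_file = f"{stem}_acc.csv"
        baseline_file = f"{stem}_baseline.csv"
        pd.DataFrame(
            {"time_s": rec.emg.times, "emg_uV": rec.emg.samples}
        ).to_csv(directory / emg_file, index=False, float_format="%.17g")
        pd.DataFrame(
            {
                "time_s": rec.acc_x.times,
                "acc_x_g": rec.acc_x.samples,
                "acc_y_g": rec.acc_y.samples,
                "acc_z_g": rec.acc_z.samples,
            }
        ).to_csv(directory / acc_file, index=False, float_format="%.17g")
        pd.DataFrame(
            {"time_s": rec.baseline_emg.times, "emg_uV": rec.baseline_emg.samples}
        ).to_csv(directory / baseline_file, index=False, float_format="%.17g")
        entries.append(
            {
                "subject_id": rec.subject_id,
                "skill": rec.skill,
                "task": rec.task,
                "trial": int(rec.trial),
                "muscle": rec.muscle,
                "side": rec.side,
                "mvc_value": float(rec.mvc_value),
                "emg_fs": float(rec.emg.fs),
                "acc_fs": float(rec.acc_x.fs),
                "emg_file": emg_file,
                "acc_file": acc_file,
                "baseline_file": baseline_file,
            }
        )
    manifest = {"format": "surgskill-dataset", "version": 1, "entries": entries}
    manifest_path = directory / MANIFEST_NAME
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path


def read_dataset(directory: str | Path) -> list[Recording]:
    """Read a cohort back from a dataset directory.

    Raises :class:`CorruptDatasetError` naming the first channel file the
    manifest references that is missing on disk.
    """
    directory = Path(directory)
    manifest_path = directory / MANIFEST_NAME
    if not manifest_path.exists():
        raise CorruptDatasetError(f"manifest not found: {manifest_path}")
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    recordings = []
    for e in manifest.get("entries", []):
        for key in ("emg_file", "acc_file", "baseline_file"):
            path = directory / e[key]
            if not path.exists():
                raise CorruptDatasetError(
                    f"manifest references missing channel file: {path}"
                )
        emg_df = pd.read_csv(directory / e["emg_file"], float_precision="round_trip")
        acc_df = pd.read_csv(directory / e["acc_file"], float_precision="round_trip")
        base_df = pd.read_csv(directory / e["baseline_file"], float_precision="round_trip")
        emg_fs, acc_fs = float(e["emg_fs"]), float(e["acc_fs"])
        recordings.append(
            Recording(
                subject_id=e["subject_id"],
                skill=e["skill"],
                task=e["task"],
                trial=int(e["trial"]),
                muscle=e["muscle"],
                side=e["side"],
                emg=SensorChannelSeries(emg_df["emg_uV"].to_numpy(), emg_fs, "emg"),
                acc_x=SensorChannelSeries(acc_df["acc_x_g"].to_numpy(), acc_fs, "acc_x"),
                acc_y=SensorChannelSeries(acc_df["acc_y_g"].to_numpy(), acc_fs, "acc_y"),
                acc_z=SensorChannelSeries(acc_df["acc_z_g"].to_numpy(), acc_fs, "acc_z"),
                baseline_emg=SensorChannelSeries(
                    base_df["emg_uV"].to_numpy(), emg_fs, "emg"
                ),
                mvc_value=float(e["mvc_value"]),
            )
        )
    return recordings
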