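"""Synthetic cohort generator: determinism, structure, serialization."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

import surgskill as sk
from surgskill.nonlinear import multiscale_entropy, resultant_acceleration, sample_entropy
from surgskill.preprocessing import preprocess_emg
from surgskill.emg_features import cumulative_muscular_workload, compute_threshold, detect_activity
from surgskill.synth import (
    DEFAULT_ACTIVATION_TEMPLATES,
    burst_envelope,
    generate_acc_channels,
    generate_cohort,
    generate_emg_channel,
    lorenz_trajectory,
    read_dataset,
    write_dataset,
)
from surgskill.types import (
    CorruptDatasetError,
    InvalidArgumentError,
    MovementComplexityProfile,
    MuscleActivationProfile,
)

from conftest import scaled_durations


def small_profile(**kw) -> MuscleActivationProfile:
    base = dict(burst_rate=0.5, burst_duration_mean=1.0, burst_amplitude=0.4,
                baseline_noise_sd=8.0, task_duration=10.0)
    base.update(kw)
    return MuscleActivationProfile(**base)


class TestEMGChannel:
    def test_zero_amplitude_zero_noise_gives_silence(self):
        prof = small_profile(burst_amplitude=0.0, baseline_noise_sd=0.0)
        ch = generate_emg_channel(prof, 2000.0, seed=1)
        assert np.all(ch.samples == 0.0)

    def test_same_seed_bit_identical(self):
        prof = small_profile()
        a = generate_emg_channel(prof, 2000.0, seed=7)
        b = generate_emg_channel(prof, 2000.0, seed=7)
        assert np.array_equal(a.samples, b.samples)

    def test_different_seed_differs(self):
        prof = small_profile()
        a = generate_emg_channel(prof, 2000.0, seed=7)
        b = generate_emg_channel(prof, 2000.0, seed=8)
        assert not np.array_equal(a.samples, b.samples)

    def test_low_rate_rejected(self):
        with pytest.raises(InvalidArgumentError):
            generate_emg_channel(small_profile(), fs=500.0, seed=0)

    def test_novice_template_outworks_expert_template(self):
        """CMW computed downstream separates the skill templates.

        Novice bursts are larger and the task longer, so the integral of
        the normalized envelope must come out larger in almost every
        seeded draw (Monte-Carlo over 100 seeds).
        """
        nov = replace(DEFAULT_ACTIVATION_TEMPLATES["novice"], task_duration=20.0)
        exp = replace(DEFAULT_ACTIVATION_TEMPLATES["expert"], task_duration=14.0)
        wins = 0
        for seed in range(100):
            cmw = {}
            for key, prof in (("nov", nov), ("exp", exp)):
                ch = generate_emg_channel(prof, 2000.0, seed=seed)
                env_known, _ = burst_envelope(prof, 2000.0, np.random.default_rng(seed), 400.0)
                mvc = 2.0 * max(env_known.max(), prof.baseline_noise_sd, 1.0)
                cmw[key] = cumulative_muscular_workload(preprocess_emg(ch, mvc))
            wins += cmw["nov"] > cmw["exp"]
        assert wins >= 95


class TestAccChannels:
    def test_pure_sinusoid_is_regular(self):
        prof = MovementComplexityProfile(1.0, 0.0, 0.0)
        ax, ay, az = generate_acc_channels(prof, 30.0, 100.0, seed=3)
        res = resultant_acceleration(ax, ay, az)
        assert sample_entropy(res.samples) <= 0.3

    def test_pure_noise_is_irregular(self):
        prof = MovementComplexityProfile(0.0, 0.0, 1.0)
        ax, ay, az = generate_acc_channels(prof, 30.0, 100.0, seed=3)
        res = resultant_acceleration(ax, ay, az)
        assert sample_entropy(res.samples) >= 1.5

    @pytest.mark.parametrize("weights", [(1, 0, 0), (0, 1, 0), (0, 0, 1), (0.2, 0.5, 0.3)])
    def test_resultant_amplitude_bound(self, weights):
        prof = MovementComplexityProfile(*weights, amplitude=0.7)
        ax, ay, az = generate_acc_channels(prof, 20.0, 100.0, seed=5)
        res = resultant_acceleration(ax, ay, az)
        assert res.samples.max() <= 0.7 * np.sqrt(3) * 1.05

    def test_deterministic_per_seed(self):
        prof = MovementComplexityProfile(0.3, 0.4, 0.3)
        a = generate_acc_channels(prof, 10.0, 100.0, seed=9)
        b = generate_acc_channels(prof, 10.0, 100.0, seed=9)
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.samples, cb.samples)

    def test_bad_weights_rejected(self):
        with pytest.raises(InvalidArgumentError):
            MovementComplexityProfile(0.5, 0.5, 0.5)

    def test_lorenz_trajectory_is_bounded_and_aperiodic(self):
        traj = lorenz_trajectory(3000, dt=0.01, discard=500)
        assert np.all(np.isfinite(traj))
        assert np.abs(traj[:, 0]).max() < 25  # attractor extent
        assert np.std(traj[:, 0]) > 1


class TestCohort:
    def test_default_design_counts(self):
        """10+11+5 subjects x 3 tasks x 3 trials x 6 muscles x 2 sides."""
        cfg = sk.CohortConfig()
        n_units = (
            sum(cfg.group_sizes.values())
            * len(cfg.tasks) * cfg.trials_per_task
            * len(cfg.muscles) * len(cfg.sides)
        )
        assert n_units == 26 * 3 * 3 * 12 == 2808

    def test_minimal_cohort_counts_and_labels(self):
        cfg = sk.CohortConfig(
            group_sizes={"novice": 1, "intermediate": 1, "expert": 1},
            tasks=("pegboard",), trials_per_task=1, muscles=("ECU",), sides=("left",),
            task_durations=scaled_durations("pegboard", 8.0, 8.0, 8.0),
            seed=2,
        )
        recs = generate_cohort(cfg)
        assert len(recs) == 3
        assert sorted(r.skill for r in recs) == ["expert", "intermediate", "novice"]
        for r in recs:
            assert r.mvc_value > 0
            assert r.baseline_emg.duration <= r.emg.duration

    def test_cohort_reproducible_from_seed(self):
        cfg = sk.CohortConfig(
            group_sizes={"novice": 1, "intermediate": 1, "expert": 1},
            tasks=("pegboard",), trials_per_task=1, muscles=("ECU",), sides=("left",),
            task_durations=scaled_durations("pegboard", 8.0, 8.0, 8.0),
            seed=4,
        )
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        for ra, rb in zip(a, b):
            assert ra.key == rb.key
            assert np.array_equal(ra.emg.samples, rb.emg.samples)
            assert np.array_equal(ra.acc_x.samples, rb.acc_x.samples)
            assert ra.mvc_value == rb.mvc_value

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidArgumentError):
            sk.CohortConfig(group_sizes={"novice": 0, "intermediate": 1, "expert": 1})

    def test_group_separation_directions(self):
        """Workload, activity time and complexity order by skill group.

        With the default skill templates, one-sided rank-sum comparisons
        on 20 subjects per group must show novice CMW above intermediate
        above expert, novice activity time above the others, and novice
        multiscale entropy above expert.
        """
        cfg = sk.CohortConfig(
            group_sizes={"novice": 20, "intermediate": 20, "expert": 20},
            tasks=("pegboard",), trials_per_task=1, muscles=("ECU",), sides=("left",),
            task_durations=scaled_durations("pegboard", 27.0, 21.0, 17.0),
            seed=31,
        )
        recs = generate_cohort(cfg)
        vals: dict[str, dict[str, list[float]]] = {
            k: {"cmw": [], "total_time": [], "mse": []} for k in sk.SKILLS
        }
        for r in recs:
            env = preprocess_emg(r.emg, r.mvc_value)
            base = preprocess_emg(r.baseline_emg, r.mvc_value)
            vals[r.skill]["cmw"].append(cumulative_muscular_workload(env))
            vals[r.skill]["total_time"].append(
                detect_activity(env, compute_threshold(base)).total_time
            )
            res = resultant_acceleration(r.acc_x, r.acc_y, r.acc_z)
            vals[r.skill]["mse"].append(multiscale_entropy(res.samples)[1])

        def greater(feature, a, b):
            p = stats.mannwhitneyu(
                vals[a][feature], vals[b][feature], alternative="greater"
            ).pvalue
            assert p < 0.05, f"{feature}: {a} not > {b} (p={p:.3g})"

        greater("cmw", "novice", "intermediate")
        greater("cmw", "intermediate", "expert")
        greater("total_time", "novice", "intermediate")
        greater("total_time", "novice", "expert")
        greater("mse", "novice", "expert")


class TestDatasetIO:
    def _cohort(self, seed=6):
        cfg = sk.CohortConfig(
            group_sizes={"novice": 1, "intermediate": 1, "expert": 1},
            tasks=("knot_tying",), trials_per_task=1, muscles=("biceps",), sides=("right",),
            task_durations=scaled_durations("knot_tying", 6.0, 6.0, 6.0),
            seed=seed,
        )
        return generate_cohort(cfg)

    def test_round_trip_identity(self, tmp_path):
        recs = self._cohort()
        write_dataset(recs, tmp_path)
        back = read_dataset(tmp_path)
        assert len(back) == len(recs)
        for a, b in zip(recs, back):
            assert a.key == b.key
            assert a.skill == b.skill
            assert a.mvc_value == b.mvc_value
            assert np.array_equal(a.emg.samples, b.emg.samples)
            assert np.array_equal(a.acc_x.samples, b.acc_x.samples)
            assert np.array_equal(a.acc_y.samples, b.acc_y.samples)
            assert np.array_equal(a.acc_z.samples, b.acc_z.samples)
            assert np.array_equal(a.baseline_emg.samples, b.baseline_emg.samples)
            assert a.emg.fs == b.emg.fs and a.acc_x.fs == b.acc_x.fs

    def test_missing_channel_file_reported(self, tmp_path):
        recs = self._cohort()
        write_dataset(recs, tmp_path)
        victim = next(tmp_path.glob("*_acc.csv"))
        victim.unlink()
        with pytest.raises(CorruptDatasetError, match=victim.name):
            read_dataset(tmp_path)

    def test_empty_cohort_round_trips(self, tmp_path):
        write_dataset([], tmp_path)
        assert read_dataset(tmp_path) == []
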