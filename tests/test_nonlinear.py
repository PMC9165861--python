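"""Nonlinear estimators against brute-force oracles and known dynamics."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from surgskill.nonlinear import (
    NonlinearParams,
    acc_feature_vector,
    approximate_entropy,
    coarse_grain,
    correlation_dimension,
    correlation_dimension_from_points,
    correlation_sum,
    delay_embed,
    generalized_hurst,
    lyapunov_rosenstein,
    lyapunov_wolf,
    multiscale_entropy,
    resultant_acceleration,
    sample_entropy,
)
from surgskill.synth import LORENZ_LARGEST_LYAPUNOV, generate_acc_channels, lorenz_trajectory
from surgskill.types import (
    InvalidArgumentError,
    MovementComplexityProfile,
    SensorChannelSeries,
    UndefinedResultError,
)


# -- independent brute-force oracles --------------------------------------


def apen_brute(x: np.ndarray, m: int, r: float) -> float:
    n = len(x)

    def phi(mm: int) -> float:
        nt = n - mm + 1
        tem = [x[i: i + mm] for i in range(nt)]
        total = 0.0
        for i in range(nt):
            c = sum(1 for j in range(nt) if np.max(np.abs(tem[i] - tem[j])) <= r)
            total += np.log(c / nt)
        return total / nt

    return phi(m) - phi(m + 1)


def sampen_brute(x: np.ndarray, m: int, r: float) -> float:
    n = len(x)
    nt = n - m
    a = b = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            if np.max(np.abs(x[i: i + m] - x[j: j + m])) <= r:
                b += 1
            if np.max(np.abs(x[i: i + m + 1] - x[j: j + m + 1])) <= r:
                a += 1
    return -np.log(a / b)


def corr_sum_brute(points: np.ndarray, r: float) -> float:
    n = len(points)
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(points[i] - points[j]) < r:
                count += 1
    return 2.0 * count / (n * (n - 1))


# -- tests ----------------------------------------------------------------


class TestResultant:
    def test_pythagorean(self):
        mk = lambda v, k: SensorChannelSeries(np.array([v], float), 100.0, k)  # noqa: E731
        res = resultant_acceleration(mk(3, "acc_x"), mk(4, "acc_y"), mk(0, "acc_z"))
        assert res.samples[0] == 5.0
        res = resultant_acceleration(mk(1, "acc_x"), mk(1, "acc_y"), mk(1, "acc_z"))
        assert res.samples[0] == pytest.approx(np.sqrt(3))
        res = resultant_acceleration(mk(0, "acc_x"), mk(0, "acc_y"), mk(0, "acc_z"))
        assert res.samples[0] == 0.0

    def test_mismatched_lengths_rejected(self):
        a = SensorChannelSeries(np.zeros(10), 100.0, "acc_x")
        b = SensorChannelSeries(np.zeros(11), 100.0, "acc_y")
        with pytest.raises(InvalidArgumentError):
            resultant_acceleration(a, b, a)


class TestDelayEmbed:
    def test_examples(self):
        pts = delay_embed(np.array([1.0, 2, 3, 4]), m=2, tau=1)
        assert np.array_equal(pts, [[1, 2], [2, 3], [3, 4]])
        pts = delay_embed(np.arange(10.0), m=1, tau=3)
        assert np.array_equal(pts.ravel(), np.arange(10.0))
        assert delay_embed(np.arange(100.0), m=3, tau=5).shape == (90, 3)

    def test_too_short_states_requirement(self):
        with pytest.raises(InvalidArgumentError, match="needs"):
            delay_embed(np.arange(5.0), m=3, tau=3)


class TestCorrelationSum:
    def test_identical_points(self):
        pts = np.zeros((2, 2))
        assert correlation_sum(pts, 0.5) == 1.0

    def test_strict_inequality_at_radius(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0]])
        assert correlation_sum(pts, 0.5) == 0.0
        assert correlation_sum(pts, 1.0) == 0.0  # tie at exactly r excluded
        assert correlation_sum(pts, 1.0001) == 1.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(size=(50, 2))
        for r in (0.05, 0.2, 0.5):
            assert correlation_sum(pts, r) == corr_sum_brute(pts, r)

    def test_monotone_in_radius(self):
        rng = np.random.default_rng(8)
        pts = rng.standard_normal((100, 3))
        radii = np.geomspace(0.1, 3.0, 10)
        cs = [correlation_sum(pts, r) for r in radii]
        assert all(b >= a for a, b in zip(cs, cs[1:]))


class TestCorrelationDimension:
    def test_line_segment_dimension_one(self):
        rng = np.random.default_rng(1)
        pts = np.column_stack([rng.uniform(0, 1, 2000), np.zeros(2000)])
        assert correlation_dimension_from_points(pts) == pytest.approx(1.0, abs=0.15)

    def test_square_dimension_two(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 1, size=(2000, 2))
        assert correlation_dimension_from_points(pts) == pytest.approx(2.0, abs=0.2)

    def test_constant_series_degenerate(self):
        assert correlation_dimension(np.full(500, 2.0)) == 0.0

    def test_offset_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(1200)
        p = NonlinearParams(tau=1)
        assert correlation_dimension(x, p) == pytest.approx(
            correlation_dimension(x + 100.0, p), rel=1e-9
        )


class TestEntropies:
    def test_apen_matches_brute_force(self):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            x = rng.uniform(size=200)
            r = 0.2 * np.std(x)
            assert approximate_entropy(x, 2, r) == pytest.approx(
                apen_brute(x, 2, r), abs=1e-10
            )

    def test_sampen_matches_brute_force(self):
        for seed in range(3):
            rng = np.random.default_rng(seed + 10)
            x = rng.uniform(size=200)
            r = 0.2 * np.std(x)
            assert sample_entropy(x, 2, r) == sampen_brute(x, 2, r)

    def test_constant_series_zero(self):
        x = np.full(100, 1.5)
        assert approximate_entropy(x, 2, 0.1) == pytest.approx(0.0, abs=1e-12)
        assert sample_entropy(x, 2, 0.1) == 0.0

    def test_periodic_series_zero(self):
        x = np.array([1.0, 2.0] * 1000)
        assert approximate_entropy(x, 2, 0.1) == pytest.approx(0.0, abs=1e-6)
        assert sample_entropy(x, 2, 0.1) == pytest.approx(0.0, abs=1e-6)

    def test_no_matches_flagged_not_infinite(self):
        x = np.geomspace(1.0, 1e6, 30)  # exploding spacing: no m-matches
        with pytest.raises(UndefinedResultError):
            sample_entropy(x, 2, 1e-9)

    @settings(max_examples=15, deadline=None)
    @given(seed=st.integers(0, 100), offset=st.floats(-50, 50), scale=st.floats(0.1, 10))
    def test_offset_and_scale_invariance(self, seed, offset, scale):
        """SD-relative tolerance makes entropies affine-invariant."""
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(250)
        r1 = 0.2 * np.std(x)
        y = scale * x + offset
        r2 = 0.2 * np.std(y)
        assert sample_entropy(x, 2, r1) == pytest.approx(sample_entropy(y, 2, r2), rel=1e-6)


class TestMultiscale:
    def test_coarse_grain_examples(self):
        x = np.array([1.0, 1, 2, 2, 3, 3])
        assert np.array_equal(coarse_grain(x, 2), [1, 2, 3])
        assert np.array_equal(coarse_grain(x, 1), x)
        assert coarse_grain(np.arange(10.0), 3).size == 3

    def test_scale_one_identity(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(500)
        mse, _, _ = multiscale_entropy(x, scales=(1,))
        assert mse[0] == sample_entropy(x, 2, 0.2 * np.std(x))

    def test_white_noise_decreasing_over_scales(self):
        """Coarse-graining averages white noise toward regularity."""
        x = np.random.default_rng(7).standard_normal(5000)
        mse, mean_mse, var_mse = multiscale_entropy(x)
        inversions = int(np.sum(np.diff(mse) > 0))
        assert inversions <= 1
        assert mean_mse == pytest.approx(np.nanmean(mse))

    def test_constant_series_all_zero(self):
        mse, mean_mse, var_mse = multiscale_entropy(np.full(300, 4.0))
        assert np.all(mse == 0.0) and mean_mse == 0.0 and var_mse == 0.0


class TestLyapunov:
    def test_rosenstein_logistic_map(self, logistic_map_series):
        """Fully chaotic logistic map has analytic exponent ln 2."""
        p = NonlinearParams(m_embed=2, tau=1, k_min=1, k_max=5, min_sep=10)
        lye, _, _ = lyapunov_rosenstein(logistic_map_series, p, fs=1.0)
        assert lye == pytest.approx(np.log(2), abs=0.07)

    def test_rosenstein_sinusoid_near_zero(self):
        t = np.arange(3000) / 100.0
        lye, _, _ = lyapunov_rosenstein(np.sin(2 * np.pi * 1.5 * t), NonlinearParams(), fs=100.0)
        assert abs(lye) <= 0.05

    def test_rosenstein_lorenz_benchmark(self):
        """Recovers the published Lorenz largest exponent within 25%.

        The expansion range is placed in the linear region of the
        divergence curve (past the early neighbor-relaxation transient,
        before saturation).
        """
        x = lorenz_trajectory(6000, dt=0.01, discard=1000)[:, 0]
        p = NonlinearParams(k_min=50, k_max=300)
        lye, _, _ = lyapunov_rosenstein(x, p, fs=100.0)
        assert lye > 0
        assert lye == pytest.approx(LORENZ_LARGEST_LYAPUNOV, rel=0.25)

    def test_divergence_grows_early_for_chaos(self, logistic_map_series):
        from surgskill.nonlinear import delay_embed, divergence_curve

        pts = delay_embed(logistic_map_series, 2, 1)
        curve = divergence_curve(pts, min_sep=10, k_max=5)
        assert curve[3] > curve[0]

    def test_wolf_logistic_map(self, logistic_map_series):
        p = NonlinearParams(m_embed=2, tau=1, min_sep=10)
        lye = lyapunov_wolf(logistic_map_series, p, fs=1.0)
        assert lye == pytest.approx(np.log(2), rel=0.30)

    def test_wolf_sinusoid_near_zero(self):
        t = np.arange(3000) / 100.0
        lye = lyapunov_wolf(np.sin(2 * np.pi * 1.5 * t), NonlinearParams(), fs=100.0)
        assert lye <= 0.05

    def test_wolf_rosenstein_sign_agreement(self):
        """The two estimators agree in sign on mixed-complexity movement.

        Twenty seeded resultant-acceleration series with Dirichlet-random
        periodic/chaotic/noise mixtures; agreement means equal sign, with
        a +-0.05 dead band counting as zero.
        """
        agree = 0
        for seed in range(20):
            rng = np.random.default_rng(seed + 100)
            prof = MovementComplexityProfile(*rng.dirichlet([1.0, 1.0, 1.0]))
            ax, ay, az = generate_acc_channels(prof, 20.0, 100.0, seed=seed)
            x = resultant_acceleration(ax, ay, az).samples
            lr, _, _ = lyapunov_rosenstein(x, NonlinearParams(), fs=100.0)
            lw = lyapunov_wolf(x, NonlinearParams(), fs=100.0)
            sr = 0 if abs(lr) <= 0.05 else np.sign(lr)
            sw = 0 if abs(lw) <= 0.05 else np.sign(lw)
            agree += (sr == sw) or (0 in (sr, sw))
        assert agree >= 17


class TestHurst:
    def test_iid_noise_half(self):
        hs = [generalized_hurst(np.random.default_rng(s).standard_normal(5000))
              for s in range(50)]
        assert np.mean(hs) == pytest.approx(0.5, abs=0.08)

    def test_linear_ramp_one(self):
        assert generalized_hurst(np.linspace(0, 1, 5000)) == pytest.approx(1.0, abs=0.02)

    def test_random_walk_input_saturates_high(self):
        """A walk treated as increments integrates to a smooth path: H -> 1."""
        walk = np.cumsum(np.random.default_rng(3).standard_normal(5000))
        h = generalized_hurst(walk)
        assert 0.9 <= h <= 1.05

    def test_constant_flagged(self):
        with pytest.raises(UndefinedResultError):
            generalized_hurst(np.full(500, 3.0))


class TestFeatureVector:
    def _recording(self, profile, seed=0, duration=20.0):
        import surgskill as sk
        from surgskill.synth import generate_baseline_emg, generate_emg_channel
        from surgskill.types import MuscleActivationProfile, Recording

        act = MuscleActivationProfile(0.5, 1.0, 0.4, 8.0, duration)
        emg = generate_emg_channel(act, 2000.0, seed=seed)
        ax, ay, az = generate_acc_channels(profile, duration, 100.0, seed=seed)
        return Recording(
            subject_id="S1", skill="novice", task="pegboard", trial=1,
            muscle="ECU", side="left", emg=emg, acc_x=ax, acc_y=ay, acc_z=az,
            baseline_emg=generate_baseline_emg(act, 2000.0, 5.0, seed=seed),
            mvc_value=400.0,
        )

    def test_constant_acceleration_flags(self):
        from surgskill.types import Recording
        from surgskill.synth import generate_baseline_emg, generate_emg_channel
        from surgskill.types import MuscleActivationProfile

        act = MuscleActivationProfile(0.5, 1.0, 0.4, 8.0, 10.0)
        emg = generate_emg_channel(act, 2000.0, seed=1)
        const = SensorChannelSeries(np.full(1000, 0.5), 100.0, "acc_x")
        rec = Recording(
            subject_id="S1", skill="novice", task="pegboard", trial=1,
            muscle="ECU", side="left", emg=emg,
            acc_x=const,
            acc_y=SensorChannelSeries(np.full(1000, 0.5), 100.0, "acc_y"),
            acc_z=SensorChannelSeries(np.full(1000, 0.5), 100.0, "acc_z"),
            baseline_emg=generate_baseline_emg(act, 2000.0, 5.0, seed=1),
            mvc_value=400.0,
        )
        feats = acc_feature_vector(rec)
        assert feats["Apen"] == 0.0 and feats["Sample_Entropy"] == 0.0
        assert feats["Correlation_Dimension"] == 0.0
        assert np.isnan(feats["Rosenstein_Lye"])  # flagged absent, not zeroed

    def test_identical_recordings_identical_vectors(self):
        prof = MovementComplexityProfile(0.3, 0.4, 0.3)
        a = acc_feature_vector(self._recording(prof, seed=4))
        b = acc_feature_vector(self._recording(prof, seed=4))
        assert a == b

    def test_complexity_ordering(self):
        """Noisier movement scores higher on every entropy feature."""
        regular = acc_feature_vector(
            self._recording(MovementComplexityProfile(0.9, 0.1, 0.0), seed=2)
        )
        complex_ = acc_feature_vector(
            self._recording(MovementComplexityProfile(0.1, 0.3, 0.6), seed=2)
        )
        for key in ("Apen", "Sample_Entropy", "MSE"):
            assert complex_[key] > regular[key]
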