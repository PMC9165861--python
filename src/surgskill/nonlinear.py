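"""Nonlinear movement-variability features from triaxial acceleration.

All features operate on the resultant acceleration magnitude
sqrt(ax^2 + ay^2 + az^2):

* approximate entropy (ApEn) and sample entropy (SampEn) — regularity
  statistics counting Chebyshev-matching templates of length m and m+1
  within tolerance r (ApEn includes self-matches, SampEn excludes them);
* multiscale entropy (MSE) — SampEn of coarse-grained (window-averaged)
  copies of the series at scale factors 1..10, with r held fixed at
  r_frac * SD of the original series;
* Grassberger-Procaccia correlation dimension — log-log slope of the
  pairwise correlation sum C(r) over a scaling region of radii;
* largest Lyapunov exponent by Rosenstein's nearest-neighbor divergence
  method (with short- and long-range fits) and by Wolf's trajectory
  tracking method;
* generalized Hurst exponent H(q) from q-th order structure-function
  scaling, with the series treated as increments (cumulatively summed
  first), so iid noise scores H ~ 0.5.

None of the tolerance/embedding choices come for free from the data;
defaults (m=2 for entropies, m=3 for geometry, r=0.2*SD, lag from the
first minimum of the auto mutual information) are exposed in
:class:`NonlinearParams` and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .types import (
    InvalidArgumentError,
    Recording,
    SensorChannelSeries,
    UndefinedResultError,
)

logger = logging.getLogger(__name__)

ACC_TRIAL_FEATURES = (
    "Apen",
    "Sample_Entropy",
    "MSE",
    "Var_MSE",
    "Rosenstein_Lye",
    "Short_Lye",
    "Long_Lye",
    "Wolf_Lye",
    "Correlation_Dimension",
    "Generalized_Hurst_Exp",
)


@dataclass(frozen=True)
class ResultantSeries:
    """Non-negative resultant acceleration magnitude (g)."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", arr)
        if self.fs <= 0:
            raise InvalidArgumentError("fs must be positive")
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise InvalidArgumentError("resultant samples must be finite and >= 0")


@dataclass(frozen=True)
class NonlinearParams:
    """Tunable parameters for the nonlinear estimators.

    ``tau=None`` selects the embedding lag from the first minimum of the
    average mutual information (falling back to the first zero crossing
    of the autocorrelation).  ``min_sep=None`` uses the mean period — the
    reciprocal of the power-weighted mean frequency — as the Theiler
    temporal-separation window.  ``k_min``/``k_max`` bound the Rosenstein
    divergence-curve fit; when unset the window is [1, fs] samples.
    """

    m_entropy: int = 2
    m_embed: int = 3
    tau: int | None = None
    r_frac: float = 0.2
    scales: tuple[int, ...] = tuple(range(1, 11))
    k_min: int | None = None
    k_max: int | None = None
    min_sep: int | None = None
    radius_quantiles: tuple[float, float] = (0.02, 0.25)
    n_radii: int = 12
    max_points: int = 1500
    hurst_q: float = 2.0
    hurst_max_lag: int = 19
    wolf_evolve: int = 1
    wolf_eps_frac: float = 0.2

    def __post_init__(self) -> None:
        if self.m_entropy < 1 or self.m_embed < 1:
            raise InvalidArgumentError("embedding dimensions must be >= 1")
        if self.r_frac <= 0:
            raise InvalidArgumentError("r_frac must be positive")
        if any(s < 1 for s in self.scales):
            raise InvalidArgumentError("all scales must be >= 1")
        if self.k_min is not None and self.k_max is not None and self.k_min >= self.k_max:
            raise InvalidArgumentError("k_min must be < k_max")


def resultant_acceleration(
    acc_x: SensorChannelSeries,
    acc_y: SensorChannelSeries,
    acc_z: SensorChannelSeries,
) -> ResultantSeries:
    """Samplewise Euclidean magnitude of the three acceleration axes."""
    n = acc_x.samples.size
    if acc_y.samples.size != n or acc_z.samples.size != n:
        raise InvalidArgumentError("acceleration axes must have equal lengths")
    if not (acc_x.fs == acc_y.fs == acc_z.fs):
        raise InvalidArgumentError("acceleration axes must share a sampling rate")
    mag = np.sqrt(acc_x.samples**2 + acc_y.samples**2 + acc_z.samples**2)
    return ResultantSeries(samples=mag, fs=acc_x.fs)


# -- state-space reconstruction ------------------------------------------


def delay_embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    """Delay-coordinate embedding: row i = (x_i, x_{i+tau}, ..., x_{i+(m-1)tau})."""
    x = np.asarray(x, dtype=float)
    if m < 1 or tau < 1:
        raise InvalidArgumentError("m and tau must be >= 1")
    n_emb = x.size - (m - 1) * tau
    if n_emb < 1:
        raise InvalidArgumentError(
            f"series of length {x.size} too short for m={m}, tau={tau} "
            f"(needs > {(m - 1) * tau} samples)"
        )
    return np.column_stack([x[i * tau : i * tau + n_emb] for i in range(m)])


def auto_embedding_lag(x: np.ndarray, max_lag: int | None = None) -> int:
    """Embedding lag from the first minimum of the average mutual information.

    Falls back to the first zero crossing of the autocorrelation, then
    to 1 for very short or featureless series.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if max_lag is None:
        max_lag = max(2, min(100, n // 10))
    if n < 20 or np.ptp(x) == 0:
        return 1
    bins = 16
    edges = np.linspace(x.min(), x.max(), bins + 1)
    digit = np.clip(np.digitize(x, edges) - 1, 0, bins - 1)

    def ami(lag: int) -> float:
        a, b = digit[:-lag], digit[lag:]
        joint = np.zeros((bins, bins))
        np.add.at(joint, (a, b), 1.0)
        joint /= joint.sum()
        px = joint.sum(axis=1)
        py = joint.sum(axis=0)
        nz = joint > 0
        return float(np.sum(joint[nz] * np.log(joint[nz] / (px[:, None] * py[None, :])[nz])))

    prev = ami(1)
    for lag in range(2, max_lag + 1):
        cur = ami(lag)
        if cur > prev:
            return lag - 1
        prev = cur
    # fallback: first zero crossing of the autocorrelation
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    if denom > 0:
        for lag in range(1, max_lag + 1):
            if np.dot(xc[:-lag], xc[lag:]) / denom <= 0:
                return lag
    return max_lag


def mean_period_samples(x: np.ndarray, fs: float = 1.0) -> int:
    """Mean period (reciprocal of the power-weighted mean frequency), in samples."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    power = spec[1:]
    if power.sum() <= 0:
        return 1
    mean_freq = float(np.sum(freqs[1:] * power) / power.sum())
    if mean_freq <= 0:
        return 1
    return max(1, int(round(fs / mean_freq)))


# -- correlation dimension ------------------------------------------------


def correlation_sum(points: np.ndarray, r: float) -> float:
    """Grassberger-Procaccia correlation sum C(r).

    Fraction of ordered pairs i<j whose Euclidean distance is strictly
    below r (the Heaviside convention H(u)=1 for u>0, u = r - distance:
    ties at exactly r do not count).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] < 2:
        raise InvalidArgumentError("correlation_sum needs at least 2 points")
    if r <= 0:
        raise InvalidArgumentError("radius must be positive")
    d = _pairwise_distances(points)
    return float(np.count_nonzero(d < r)) / d.size


def _pairwise_distances(points: np.ndarray) -> np.ndarray:
    """Condensed upper-triangle Euclidean distances."""
    return pdist(points, metric="euclidean")


def correlation_dimension_from_points(
    points: np.ndarray,
    radii: np.ndarray | None = None,
    radius_quantiles: tuple[float, float] = (0.02, 0.25),
    n_radii: int = 12,
) -> float:
    """Least-squares slope of log C(r) vs log r over a scaling region.

    The default radius grid is geometric between the given quantiles of
    the pairwise-distance distribution, so C(r) is never zero at the
    lower end of a non-degenerate cloud.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    d = _pairwise_distances(points)
    if np.all(d == 0):
        logger.warning("correlation dimension of a single-point attractor set to 0")
        return 0.0
    if radii is None:
        lo = float(np.quantile(d[d > 0], radius_quantiles[0]))
        hi = float(np.quantile(d[d > 0], radius_quantiles[1]))
        if not (0 < lo < hi):
            raise UndefinedResultError("degenerate pairwise-distance distribution")
        radii = np.geomspace(lo, hi, n_radii)
    radii = np.asarray(radii, dtype=float)
    if radii.size < 5:
        raise InvalidArgumentError("need at least 5 radii for a slope fit")
    counts = np.array([np.count_nonzero(d < r) for r in radii], dtype=float)
    cs = counts / d.size
    ok = cs > 0
    if ok.sum() < 5:
        raise UndefinedResultError("correlation sums vanish over the scaling region")
    slope = np.polyfit(np.log(radii[ok]), np.log(cs[ok]), 1)[0]
    return float(slope)


def correlation_dimension(x: np.ndarray, params: NonlinearParams | None = None,
                          seed: int = 0) -> float:
    """Correlation dimension of a scalar series via delay embedding.

    Embedded points are evenly subsampled to ``params.max_points`` to
    bound the O(N^2) pair count.
    """
    params = params or NonlinearParams()
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        logger.warning("constant series: correlation dimension 0 by convention")
        return 0.0
    tau = params.tau or auto_embedding_lag(x)
    pts = delay_embed(x, params.m_embed, tau)
    if pts.shape[0] > params.max_points:
        idx = np.linspace(0, pts.shape[0] - 1, params.max_points).astype(int)
        pts = pts[idx]
    return correlation_dimension_from_points(
        pts, radius_quantiles=params.radius_quantiles, n_radii=params.n_radii
    )


# -- entropies ------------------------------------------------------------


def _templates(x: np.ndarray, m: int, n_templates: int) -> np.ndarray:
    return np.column_stack([x[i : i + n_templates] for i in range(m)])


def _chebyshev_match_counts(x: np.ndarray, m: int, r: float, n_templates: int) -> np.ndarray:
    """Per-template counts of Chebyshev matches (including self) at length m.

    Counts templates within distance <= r (inclusive) of each of the
    first ``n_templates`` length-m templates, via a KD-tree in the
    Chebyshev norm.
    """
    templ = _templates(x, m, n_templates)
    tree = cKDTree(templ)
    return np.asarray(
        tree.query_ball_point(templ, r, p=np.inf, return_length=True), dtype=np.int64
    )


def _chebyshev_pair_count(x: np.ndarray, m: int, r: float, n_templates: int) -> int:
    """Unordered template pairs (i < j) within Chebyshev distance <= r."""
    templ = _templates(x, m, n_templates)
    tree = cKDTree(templ)
    total = tree.count_neighbors(tree, r, p=np.inf)  # ordered pairs incl. self
    return (int(total) - n_templates) // 2


def approximate_entropy(x: np.ndarray, m: int = 2, r_abs: float | None = None) -> float:
    """Approximate entropy: Phi_m - Phi_{m+1}, self-matches included.

    Phi_m is the mean over templates of log(C_i), where C_i is the
    fraction of templates within Chebyshev distance r of template i.
    """
    x = np.asarray(x, dtype=float)
    if r_abs is None:
        r_abs = 0.2 * float(np.std(x))
    if r_abs <= 0:
        raise InvalidArgumentError("tolerance r must be positive")
    n = x.size
    if n < 3 * m:
        raise InvalidArgumentError(f"series too short for ApEn with m={m}")

    def phi(mm: int) -> float:
        nt = n - mm + 1
        counts = _chebyshev_match_counts(x, mm, r_abs, nt)
        return float(np.mean(np.log(counts / nt)))

    return phi(m) - phi(m + 1)


def sample_entropy(x: np.ndarray, m: int = 2, r_abs: float | None = None) -> float:
    """Sample entropy: -ln(A/B) with self-matches excluded.

    B counts template pairs matching at length m, A at length m+1, both
    over the first N-m templates.  Raises :class:`UndefinedResultError`
    when either count is zero rather than substituting infinity.
    """
    x = np.asarray(x, dtype=float)
    if r_abs is None:
        r_abs = 0.2 * float(np.std(x))
    if r_abs <= 0:
        raise InvalidArgumentError("tolerance r must be positive")
    n = x.size
    if n < 3 * m:
        raise InvalidArgumentError(f"series too short for SampEn with m={m}")
    nt = n - m  # common template count for both lengths
    b = _chebyshev_pair_count(x, m, r_abs, nt)
    a = _chebyshev_pair_count(x, m + 1, r_abs, nt)
    if b == 0:
        raise UndefinedResultError("no template matches at length m; SampEn undefined")
    if a == 0:
        raise UndefinedResultError("no template matches at length m+1; SampEn undefined")
    return float(-np.log(a / b))


def coarse_grain(x: np.ndarray, scale: int) -> np.ndarray:
    """Non-overlapping window means; output length floor(N / scale)."""
    x = np.asarray(x, dtype=float)
    if scale < 1:
        raise InvalidArgumentError("scale must be >= 1")
    if x.size < scale:
        raise InvalidArgumentError("series shorter than the coarse-graining scale")
    n_out = x.size // scale
    return x[: n_out * scale].reshape(n_out, scale).mean(axis=1)


def multiscale_entropy(
    x: np.ndarray,
    m: int = 2,
    r_frac: float = 0.2,
    scales: tuple[int, ...] = tuple(range(1, 11)),
) -> tuple[np.ndarray, float, float]:
    """Sample entropy of coarse-grained series at each scale factor.

    The tolerance r is fixed at ``r_frac * SD`` of the *original* series
    for every scale (the standard convention).  Scales where SampEn is
    undefined are reported as NaN and excluded from the mean/variance
    (population variance over the defined scales).

    Returns ``(per_scale, mean_mse, var_mse)``.
    """
    x = np.asarray(x, dtype=float)
    r_abs = r_frac * float(np.std(x))
    out = np.full(len(scales), np.nan)
    if r_abs == 0:  # constant series: perfectly regular at every scale
        out[:] = 0.0
        return out, 0.0, 0.0
    for i, s in enumerate(scales):
        cg = coarse_grain(x, s)
        try:
            out[i] = sample_entropy(cg, m=m, r_abs=r_abs)
        except (UndefinedResultError, InvalidArgumentError) as exc:
            logger.warning("MSE scale %d undefined: %s", s, exc)
    defined = out[~np.isnan(out)]
    if defined.size == 0:
        raise UndefinedResultError("sample entropy undefined at every scale")
    if defined.size < len(scales):
        logger.warning("MSE defined on %d/%d scales", defined.size, len(scales))
    return out, float(defined.mean()), float(defined.var())


# -- Lyapunov exponents ---------------------------------------------------


def _resolution_floor(points: np.ndarray) -> float:
    """Distances below this are treated as duplicates (numerical floor).

    Noise-free periodic signals reproduce state-space points to machine
    precision; pairing those as neighbors would make the log-divergence
    curve pure rounding noise.
    """
    extent = float(np.linalg.norm(points.max(axis=0) - points.min(axis=0)))
    return 1e-8 * max(extent, 1.0)


def _nearest_neighbors(points: np.ndarray, min_sep: int) -> np.ndarray:
    """Index of each point's nearest Euclidean neighbor with |i - j| > min_sep.

    Neighbors closer than the numerical resolution floor are skipped.
    Returns -1 where no valid neighbor exists.
    """
    n = points.shape[0]
    eps = _resolution_floor(points)
    tree = cKDTree(points)
    k = min(n, 4 * min_sep + 10)
    dist, idx = tree.query(points, k=k)
    nn = np.full(n, -1, dtype=np.int64)
    rows = np.arange(n)
    valid = (np.abs(idx - rows[:, None]) > min_sep) & (dist > eps)
    has = valid.any(axis=1)
    first = np.argmax(valid, axis=1)
    nn[has] = idx[rows[has], first[has]]
    # brute-force fallback for rows whose k nearest were all invalid
    for i in np.flatnonzero(~has):
        d = np.linalg.norm(points - points[i], axis=1)
        d[(np.abs(np.arange(n) - i) <= min_sep) | (d <= eps)] = np.inf
        j = int(np.argmin(d))
        if np.isfinite(d[j]):
            nn[i] = j
    return nn


def divergence_curve(
    points: np.ndarray, min_sep: int, k_max: int
) -> np.ndarray:
    """Rosenstein mean log-divergence curve d(k), k = 0..k_max.

    d(k) is the mean over reference points of the log distance between
    each point and its nearest neighbor after k steps.  Pairs that start
    at exactly zero distance are skipped.
    """
    n = points.shape[0]
    if n <= k_max + min_sep + 1:
        raise InvalidArgumentError("too few embedded points for the expansion range")
    nn = _nearest_neighbors(points, min_sep)
    valid = nn >= 0
    if valid.sum() < 0.5 * n:
        raise UndefinedResultError("no valid neighbor for more than half of the points")
    curve = np.full(k_max + 1, np.nan)
    for k in range(k_max + 1):
        i = np.flatnonzero(valid)
        i = i[(i + k < n) & (nn[i] + k < n)]
        if i.size == 0:
            break
        d = np.linalg.norm(points[i + k] - points[nn[i] + k], axis=1)
        d = d[d > 0]
        if d.size == 0:
            continue
        curve[k] = float(np.mean(np.log(d)))
    return curve


def _fit_slope(curve: np.ndarray, k_lo: int, k_hi: int, dt: float) -> float:
    ks = np.arange(k_lo, k_hi + 1)
    ks = ks[(ks >= 0) & (ks < curve.size)]
    vals = curve[ks]
    ok = ~np.isnan(vals)
    if ok.sum() < 2:
        raise UndefinedResultError("divergence curve too short for the requested fit")
    slope = np.polyfit(ks[ok] * dt, vals[ok], 1)[0]
    return float(slope)


def lyapunov_rosenstein(
    x: np.ndarray,
    params: NonlinearParams | None = None,
    fs: float = 1.0,
) -> tuple[float, float, float]:
    """Largest Lyapunov exponent by Rosenstein's method, in 1/s.

    Returns ``(lye, lye_short, lye_long)``: the slope of a degree-1
    least-squares fit to the mean log-divergence curve over the full
    expansion range [k_min, k_max], plus fits restricted to the short
    (0 - 0.5 mean periods) and long (0.5 - 2 mean periods) sub-ranges,
    the convention used in movement-variability analysis.
    """
    params = params or NonlinearParams()
    x = np.asarray(x, dtype=float)
    tau = params.tau or auto_embedding_lag(x)
    pts = delay_embed(x, params.m_embed, tau)
    mp = params.min_sep if params.min_sep is not None else mean_period_samples(x, fs)
    mp = max(1, int(mp))
    k_min = params.k_min if params.k_min is not None else 1
    k_max = params.k_max if params.k_max is not None else int(round(fs))
    k_max = max(k_min + 1, min(k_max, pts.shape[0] - mp - 2))
    curve = divergence_curve(pts, mp, max(k_max, 2 * mp))
    dt = 1.0 / fs
    lye = _fit_slope(curve, k_min, k_max, dt)
    short_hi = max(k_min + 1, mp // 2)
    lye_short = _fit_slope(curve, k_min, short_hi, dt)
    long_lo = max(k_min + 1, mp // 2)
    long_hi = max(long_lo + 1, min(2 * mp, curve.size - 1))
    lye_long = _fit_slope(curve, long_lo, long_hi, dt)
    return lye, lye_short, lye_long


def lyapunov_wolf(
    x: np.ndarray,
    params: NonlinearParams | None = None,
    fs: float = 1.0,
) -> float:
    """Largest Lyapunov exponent by Wolf's trajectory-tracking method.

    Follows a fiducial trajectory, evolving the separation to its nearest
    neighbor for ``wolf_evolve`` steps, accumulating log divergence
    ratios, and replacing the neighbor whenever the separation exceeds
    ``wolf_eps_frac`` times the attractor extent.  Positive for chaotic
    series, near zero or negative for periodic ones.
    """
    params = params or NonlinearParams()
    x = np.asarray(x, dtype=float)
    tau = params.tau or auto_embedding_lag(x)
    pts = delay_embed(x, params.m_embed, tau)
    n = pts.shape[0]
    mp = params.min_sep if params.min_sep is not None else mean_period_samples(x, fs)
    mp = max(1, int(mp))
    evolve = max(1, int(params.wolf_evolve))
    if n <= mp + evolve + 2:
        raise UndefinedResultError("too few embedded points for Wolf tracking")
    extent = float(np.linalg.norm(pts.max(axis=0) - pts.min(axis=0)))
    eps_max = params.wolf_eps_frac * extent
    eps_min = _resolution_floor(pts)
    tree = cKDTree(pts)

    def find_neighbor(i: int) -> int:
        k = min(n, 2 * mp + 20)
        dist, idx = tree.query(pts[i], k=k)
        for d, j in zip(np.atleast_1d(dist), np.atleast_1d(idx)):
            if d > eps_min and abs(int(j) - i) > mp and int(j) + evolve < n:
                return int(j)
        d = np.linalg.norm(pts - pts[i], axis=1)
        bad = (np.abs(np.arange(n) - i) <= mp) | (d <= eps_min) | (np.arange(n) + evolve >= n)
        d[bad] = np.inf
        j = int(np.argmin(d))
        return j if np.isfinite(d[j]) else -1

    i = 0
    j = find_neighbor(i)
    if j < 0:
        raise UndefinedResultError("no valid starting neighbor for Wolf tracking")
    total_log = 0.0
    total_steps = 0
    while i + evolve < n:
        d0 = float(np.linalg.norm(pts[i] - pts[j]))
        if d0 == 0:
            j = find_neighbor(i)
            if j < 0:
                break
            continue
        i2, j2 = i + evolve, j + evolve
        if j2 >= n:
            j = find_neighbor(i)
            if j < 0:
                break
            continue
        d1 = float(np.linalg.norm(pts[i2] - pts[j2]))
        if d1 > 0:
            total_log += np.log(d1 / d0)
            total_steps += evolve
        i = i2
        if d1 > eps_max or d1 == 0:
            j = find_neighbor(i)
            if j < 0:
                break
        else:
            j = j2
    if total_steps == 0:
        raise UndefinedResultError("Wolf tracking accumulated no divergence steps")
    return float(total_log / (total_steps / fs))


# -- generalized Hurst exponent ------------------------------------------


def generalized_hurst(
    x: np.ndarray, q: float = 2.0, max_lag: int = 19
) -> float:
    """Generalized Hurst exponent H(q) from structure-function scaling.

    The series is treated as increments: it is mean-centered and
    cumulatively summed, then K_q(lag) = mean |y(t+lag) - y(t)|^q is fit
    as lag^(qH) over lags 1..max_lag.  With this convention iid noise
    scores H ~ 0.5 and a linear ramp scores exactly 1.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 100:
        raise InvalidArgumentError("generalized_hurst requires at least 100 samples")
    if np.ptp(x) == 0:
        raise UndefinedResultError("constant series has no scaling exponent")
    y = np.cumsum(x - x.mean())
    lags = np.arange(1, max_lag + 1)
    kq = np.empty(lags.size)
    for i, lag in enumerate(lags):
        diff = y[lag:] - y[:-lag]
        kq[i] = np.mean(np.abs(diff) ** q)
    if np.any(kq <= 0):
        raise UndefinedResultError("structure function vanishes at some lag")
    slope = np.polyfit(np.log(lags), np.log(kq), 1)[0]
    return float(slope / q)


# -- per-recording feature vector ----------------------------------------


def acc_feature_vector(
    recording: Recording, params: NonlinearParams | None = None
) -> dict[str, float]:
    """All nonlinear features of one recording's resultant acceleration.

    Any estimator whose result is undefined for this input yields NaN
    (flagged absent) rather than a silent zero.
    """
    params = params or NonlinearParams()
    res = resultant_acceleration(recording.acc_x, recording.acc_y, recording.acc_z)
    x = res.samples
    fs = res.fs
    r_abs = params.r_frac * float(np.std(x))
    out: dict[str, float] = {name: float("nan") for name in ACC_TRIAL_FEATURES}
    if np.ptp(x) == 0:
        out["Apen"] = 0.0
        out["Sample_Entropy"] = 0.0
        out["MSE"] = 0.0
        out["Var_MSE"] = 0.0
        out["Correlation_Dimension"] = 0.0
        logger.warning("constant resultant series: entropy features 0, others absent")
        return out
    try:
        out["Apen"] = approximate_entropy(x, m=params.m_entropy, r_abs=r_abs)
    except (UndefinedResultError, InvalidArgumentError) as exc:
        logger.warning("ApEn undefined: %s", exc)
    try:
        out["Sample_Entropy"] = sample_entropy(x, m=params.m_entropy, r_abs=r_abs)
    except (UndefinedResultError, InvalidArgumentError) as exc:
        logger.warning("SampEn undefined: %s", exc)
    try:
        _, out["MSE"], out["Var_MSE"] = multiscale_entropy(
            x, m=params.m_entropy, r_frac=params.r_frac, scales=params.scales
        )
    except (UndefinedResultError, InvalidArgumentError) as exc:
        logger.warning("MSE undefined: %s", exc)
    try:
        out["Correlation_Dimension"] = correlation_dimension(x, params)
    except (UndefinedResultError, InvalidArgumentError) as exc:
        logger.warning("correlation dimension undefined: %s", exc)
    try:
        lye, s, l = lyapunov_rosenstein(x, params, fs)
        out["Rosenstein_Lye"], out["Short_Lye"], out["Long_Lye"] = lye, s, l
    except (UndefinedResultError, InvalidArgumentError) as exc:
        logger.warning("Rosenstein Lyapunov undefined: %s", exc)
    try:
        out["Wolf_Lye"] = lyapunov_wolf(x, params, fs)
    except (UndefinedResultError, InvalidArgumentError) as exc:
        logger.warning("Wolf Lyapunov undefined: %s", exc)
    try:
        out["Generalized_Hurst_Exp"] = generalized_hurst(
            x, q=params.hurst_q, max_lag=params.hurst_max_lag
        )
    except (UndefinedResultError, InvalidArgumentError) as exc:
        logger.warning("generalized Hurst undefined: %s", exc)
    return out
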