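"""Nonlinear movement-variability features on signals with known answers.

Three reference signals probe the estimators: a sinusoid (regular,
zero Lyapunov exponent, low entropy), the Lorenz chaotic flow (positive
exponent ~0.91 per unit time), and white noise (high entropy).  The same
features are then shown for a simulated movement mixture.
"""

import numpy as np

import surgskill as sk
from surgskill.nonlinear import (
    NonlinearParams,
    lyapunov_rosenstein,
    multiscale_entropy,
    resultant_acceleration,
    sample_entropy,
)
from surgskill.synth import lorenz_trajectory

fs = 100.0
t = np.arange(3000) / fs
signals = {
    "sinusoid": np.sin(2 * np.pi * 1.5 * t),
    "lorenz_x": lorenz_trajectory(3000, dt=0.01, discard=1000)[:, 0],
    "white_noise": np.random.default_rng(0).standard_normal(3000),
}

print(f"{'signal':>12s} {'SampEn':>8s} {'mean MSE':>9s} {'LyE (1/s)':>10s}")
for name, x in signals.items():
    se = sample_entropy(x)
    _, mean_mse, _ = multiscale_entropy(x)
    params = NonlinearParams(k_min=50, k_max=300) if name == "lorenz_x" else NonlinearParams()
    lye, _, _ = lyapunov_rosenstein(x, params, fs=fs)
    print(f"{name:>12s} {se:8.3f} {mean_mse:9.3f} {lye:10.3f}")

print(
    "\nThe sinusoid is maximally regular (entropies near 0, LyE ~ 0); the"
    "\nLorenz flow has structured unpredictability (positive LyE near the"
    "\npublished 0.906/s at this sampling); white noise maximizes entropy."
)

prof = sk.MovementComplexityProfile(0.4, 0.35, 0.25)
ax, ay, az = sk.generate_acc_channels(prof, 30.0, fs, seed=1)
res = resultant_acceleration(ax, ay, az)
print(f"\nsimulated movement mixture (40% periodic / 35% chaotic / 25% noise):")
print(f"  SampEn of resultant acceleration = {sample_entropy(res.samples):.3f}")
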