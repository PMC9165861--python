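"""Preprocess one EMG channel and compute the muscular-workload features.

The chain: detrend -> 20-500 Hz band-pass -> 60 Hz notch -> 6-sample RMS
rectification -> 4th-order 5 Hz low-pass -> division by the MVC
reference.  From the resulting envelope: cumulative muscular workload
(CMW, the time integral), average work per second (AWS), total activity
time above a baseline-derived threshold (mean + 5 SD), RMS, range, and
the dominant firing frequency of the filtered signal.
"""

import surgskill as sk
from surgskill.emg_features import emg_feature_vector
from surgskill.synth import generate_baseline_emg, generate_emg_channel
from surgskill.types import MuscleActivationProfile, Recording

profile = MuscleActivationProfile(
    burst_rate=0.5,          # bursts per second
    burst_duration_mean=1.0,  # s
    burst_amplitude=0.45,     # fraction of MVC
    baseline_noise_sd=8.0,    # uV
    task_duration=20.0,       # s
)
emg = generate_emg_channel(profile, fs=2000.0, seed=7)
baseline = generate_baseline_emg(profile, fs=2000.0, duration=5.0, seed=7)
ax, ay, az = sk.generate_acc_channels(
    sk.MovementComplexityProfile(0.4, 0.35, 0.25), 20.0, 100.0, seed=7
)
rec = Recording(
    subject_id="demo", skill="intermediate", task="pegboard", trial=1,
    muscle="ECU", side="left", emg=emg, acc_x=ax, acc_y=ay, acc_z=az,
    baseline_emg=baseline, mvc_value=400.0,
)

features = emg_feature_vector(rec)
print("linear EMG features for one 20 s recording:")
for name, value in features.as_dict().items():
    print(f"  {name:>13s} = {value:.4g}")
print(
    "\nCMW is in MVC-fraction-seconds (total normalized work); AWS = CMW /"
    "\ntrial duration; TotalTime is seconds between first onset and last"
    "\ncessation of supra-threshold activity; DominantFreq (Hz) is the peak"
    "\nof the filtered EMG power spectrum."
)
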