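"""Generate a small synthetic surgical-task cohort and write it to disk.

Each recording unit is one (subject, task, trial, muscle, side) with a
2000 Hz surface-EMG channel, a 100 Hz triaxial accelerometer, a resting
baseline segment and an MVC reference.  Skill templates make novices
work harder (larger, longer EMG bursts) and move more irregularly
(noisier acceleration mixtures) than experts.
"""

import tempfile
from pathlib import Path

import surgskill as sk

cfg = sk.CohortConfig(
    group_sizes={"novice": 2, "intermediate": 2, "expert": 2},
    tasks=("pegboard",),
    trials_per_task=2,
    muscles=("ECU",),
    sides=("left",),
    task_durations={
        "novice": {"pegboard": 20.0},
        "intermediate": {"pegboard": 16.0},
        "expert": {"pegboard": 13.0},
    },
    seed=42,
)
recordings = sk.generate_cohort(cfg)
print(f"generated {len(recordings)} recordings "
      f"(= 6 subjects x 2 trials x 1 muscle x 1 side)")

rec = recordings[0]
print(f"\nfirst unit: subject={rec.subject_id} skill={rec.skill} "
      f"task={rec.task} trial={rec.trial} muscle={rec.muscle}/{rec.side}")
print(f"  EMG: {rec.emg.samples.size} samples @ {rec.emg.fs:g} Hz "
      f"({rec.emg.duration:.1f} s), MVC reference {rec.mvc_value:.1f} uV")
print(f"  acc: {rec.acc_x.samples.size} samples @ {rec.acc_x.fs:g} Hz")

out = Path(tempfile.mkdtemp()) / "cohort"
manifest = sk.write_dataset(recordings, out)
back = sk.read_dataset(out)
print(f"\nwrote dataset to {out} and read back {len(back)} recordings; "
      "text serialization round-trips every sample exactly")
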