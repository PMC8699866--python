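"""Simulate a short PCG recording, preprocess it, and recover the cardiac states.

Builds a clean 30 s LVDD-like phonocardiogram, trains the HSMM segmenter on a
handful of labelled simulations, decodes the four-state path and reports how
well it matches the simulator's ground truth.
"""

import numpy as np

from pcglvdd import (
    default_config,
    extract_frames,
    preprocess,
    segment_states,
    simulate_recording,
    train_segmenter,
)
from pcglvdd.segment import resample_states

# training simulations (labels come from the simulator)
train = [simulate_recording(default_config(lab, duration=30.0, noise_snr=np.inf,
                                           seed=s, heart_rate_mean=hr), f"{lab}{s}")
         for s, (lab, hr) in enumerate([("lvdd", 60), ("control", 66),
                                        ("lvdd", 72), ("control", 78)])]
model = train_segmenter(train)

rec = simulate_recording(default_config("lvdd", duration=30.0, noise_snr=np.inf, seed=99), "demo")
prepared = preprocess(rec)                    # 1000 Hz, denoised, peak-normalized
states = segment_states(prepared, model)      # per-sample S1/systole/S2/diastole
frames = extract_frames(prepared, states)     # 1.6 s windows at S1 onsets

truth = resample_states(rec.true_states, 1000.0)
n = min(len(states), len(truth))
acc = np.mean(states.labels[:n] == truth.labels[:n])

print(f"recording: {rec.duration:.0f} s at {rec.sampling_rate:.0f} Hz, "
      f"class {rec.class_label}")
print(f"per-sample state accuracy vs ground truth: {acc:.3f}")
print(f"detected S1 onsets: {len(states.onsets('S1'))}, analysis frames: {len(frames)}")
# accuracy ~0.95 on clean input; each frame is 1600 samples starting on an S1 onset
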