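"""Encode a synthetic EEG trial into spatio-temporal blocks.

Generates one 62-channel trial, lifts a sample onto the 9x9 electrode
grid, interpolates it densely, and windows the trial into 3D blocks.
"""

import numpy as np

from eegcube import (SynthConfig, build_blocks, frame_from_sample,
                     generate_trial, interpolate_frame, load_montage)

montage = load_montage("seed62")
cfg = SynthConfig(trial_duration_s=10.0, seed=7)
trial = generate_trial(cfg, subject=0, session=0, label=1, trial=0)
print(f"trial: {trial.n_channels} channels x {trial.n_samples} samples "
      f"at {trial.fs:.0f} Hz, label {trial.label}")

sparse = frame_from_sample(trial, t=100, montage=montage)
dense = interpolate_frame(sparse, montage, epsilon=1.0)
node_err = np.abs(dense.values[sparse.mask] - sparse.values[sparse.mask]).max()
print(f"sparse frame: {int(sparse.mask.sum())} occupied cells of 81; "
      f"after RBF interpolation the node values are reproduced to {node_err:.2e}")

blocks = build_blocks(trial, montage, w=200, stride=200)
print(f"{len(blocks)} one-second blocks of shape {blocks[0].frames.shape}")
print("Each block is a 200 x 64 x 64 stack of interpolated frames — the "
      "3D input the CNN consumes (after triplication to 3 channels).")
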