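"""Build the 3D depthwise-separable backbone and extract deep features.

Shows the reference stage shapes at width 1.0, then runs a scaled-down
backbone (width 0.25) on random blocks and taps Dense-1 features.
"""

import numpy as np

from eegcube.nn import (BackboneConfig, HeadConfig, attach_head,
                        build_backbone, propagate_shapes)

print("reference architecture (width 1.0, input 3x200x64x64):")
for name, shape in propagate_shapes(BackboneConfig()):
    print(f"  {name:8s} {shape}")

cfg = BackboneConfig(width_multiplier=0.25, input_shape=(3, 50, 32, 32), seed=0)
backbone = build_backbone(cfg)
x = np.random.default_rng(0).normal(size=(4, 3, 50, 32, 32)).astype(np.float32)
backbone.calibrate_bn(x)  # fresh backbones need BN statistics calibrated
model = attach_head(backbone, HeadConfig(n_classes=3, seed=0))

pooled = backbone.forward(x)
feats = model.features(x)
probs = model.predict_proba(x)
print(f"\npooled features: {pooled.shape} (width 0.25 -> 256 channels)")
print(f"Dense-1 deep features: {feats.shape} — these feed the hybrid heads")
print(f"class probabilities (softmax rows sum to 1): {probs.sum(axis=1)}")
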