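"""Shifted-window attention on a tiny volume: partition, mask, attend.

Builds an 8x8x8 feature volume, splits it into 2x2x2 windows, shows the
shift mask that keeps attention inside pre-shift regions after the cyclic
roll, and runs both the unshifted (W-MSA-3D) and shifted (SW-MSA-3D) passes.
"""

import numpy as np

import swinunet3d as s

rng = np.random.default_rng(0)
x = rng.normal(size=(1, 8, 8, 8, 16)).astype(np.float32)

spec = s.WindowSpec.half_shift((2, 2, 2))  # window 2, shift 1 per axis
windows = s.partition_windows(x, s.WindowSpec(spec.window))
print(f"volume {x.shape} -> {windows.n_windows} windows of "
      f"{windows.tokens_per_window} tokens")

mask = s.build_shift_mask(x.shape[1:4], spec)
masked_pairs = int((mask < 0).sum())
print(f"shift mask: {mask.shape[0]} windows, {masked_pairs} of "
      f"{mask.size} token pairs forbidden after the cyclic shift")

att = s.WindowAttention(dim=16, heads=4, rng=np.random.default_rng(1))
y_plain = s.w_msa_3d(x, spec, att)
y_shift = s.sw_msa_3d(x, spec, att)
print(f"W-MSA-3D output {y_plain.shape}, SW-MSA-3D output {y_shift.shape}")
print(f"max |shifted - unshifted| = {np.abs(y_shift - y_plain).max():.4f} "
      "(nonzero: the shifted pass mixes neighboring windows)")
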