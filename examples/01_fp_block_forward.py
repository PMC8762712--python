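"""Run one FP-block on a small feature tensor, step by step.

Builds a 16-channel input, pushes it through the pointwise expansion, the
depthwise filter pairs with instance normalisation and rectification, the
elementwise product, and the projection + residual, printing the tensor
shapes and the invariants that hold along the way.
"""

import numpy as np

from fpnets import (FPBlockConfig, depthwise_filter, feature_product,
                    fp_block_forward, init_fp_block, instance_stats,
                    pointwise_combine)

rng = np.random.default_rng(0)

config = FPBlockConfig(d_in=16, d_out=32, q=1.0, stride=2)
params = init_fp_block(config, seed=42)
t0 = rng.random((32, 32, 16))

t1 = pointwise_combine(t0, params.expansion)
rv = depthwise_filter(t1[:, :, 0], params.filters_v[0], stride=config.stride)
rg = depthwise_filter(t1[:, :, 0], params.filters_g[0], stride=config.stride)
sv, sg = instance_stats(rv), instance_stats(rg)
t2_map0 = feature_product(rv, rg, sv, sg)
out = fp_block_forward(t0, params, config)

print(f"T0  {t0.shape}  -> T1 {t1.shape}   (1x1 combination + ReLU, {config.n_pairs} maps)")
print(f"map 0 filtered: mu_v={sv.mu:+.4f} sigma_v={sv.sigma:.4f}  "
      f"mu_g={sg.mu:+.4f} sigma_g={sg.sigma:.4f}")
print(f"T2 map 0 {t2_map0.shape}: min={t2_map0.min():.4f} (product of rectified "
      f"terms, never negative), sparsity={np.mean(t2_map0 == 0):.0%} zeros")
print(f"Tout {out.shape}  (stride-2 block: 32x32x16 -> 16x16x32, no residual "
      "because shapes differ)")
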