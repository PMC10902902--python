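"""Encode a signed weight matrix on a differential crossbar and multiply.

Each weight becomes a pair of conductances read out as their difference,
so the analog vector-matrix product matches the dense numpy product;
quantizing to 256 programming levels adds a bounded error.
"""

import numpy as np

from memlstm import program_weights, read_weights, vmm

rng = np.random.default_rng(0)
W = rng.normal(size=(8, 4))
v = rng.normal(size=8)

ideal = program_weights(W, levels=None)           # continuous conductances
print("round-trip error (continuous):",
      f"{np.max(np.abs(read_weights(ideal) - W)):.2e}")
print("vmm vs dense product:         ",
      f"{np.max(np.abs(vmm(ideal, v) - W.T @ v)):.2e}")

quant = program_weights(W, levels=256)            # 8-bit programming
bound = (quant.g_max - quant.g_min) / 255 / quant.scale  # in weight units
print("quantization error:           ",
      f"{np.max(np.abs(read_weights(quant) - W)):.2e} (bound {bound:.2e})")

noisy = program_weights(W, levels=256, noise_sigma=0.1, seed=1)
print("with 10% programming noise:   ",
      f"{np.max(np.abs(read_weights(noisy) - W)):.2e}")

# The continuous encoding is exact to floating precision; quantization
# and programming noise are the two nonidealities that later degrade
# memristive network inference.
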