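"""Traveling-wave PCA on a stride-aligned activity cube.

Builds an analytic plane-wave cube (one cycle per stride traveling along
the body axis), decomposes it, and contrasts the wave-restricted variance
explained with a phase-shuffled control.
"""

import math

import numpy as np

from pongscope import waves as wv

nx, ny, nb = 40, 12, 24
x, y = np.arange(nx) * 2.0, np.arange(ny) * 2.0
phase = (np.arange(nb) + 0.5) * 2 * math.pi / nb
k = 2 * math.pi / 60.0  # one wave cycle per 60 µm
vals = (1 + 0.5 * np.cos(k * x[:, None, None] - phase[None, None, :]))
vals = vals * np.ones((1, ny, 1))
cube = wv.StrideAlignedCube(values=vals, counts=vals,
                            dwell=np.ones_like(vals), x=x, y=y, n_strides=6)

d = wv.wave_pca(cube)
d = wv.wave_variance_explained(cube, d)
print(f"variance in PC1+PC2  : {d.var_share_pc12:.3f}")
print(f"fitted |k|           : {np.linalg.norm(d.k_vec):.4f} µm⁻¹ "
      f"(true {k:.4f})")
print(f"wave var. explained  : {d.variance_explained:.3f} "
      "(≥ 0.95 marks a clean traveling wave)")

rng = np.random.default_rng(0)
ds = wv.wave_pca(cube)
amp, psi = np.abs(ds.g), np.angle(ds.g)
flat = psi[ds.valid]
psi[ds.valid] = flat[rng.permutation(flat.size)]
ds.g = amp * np.exp(1j * psi)
ds = wv.wave_variance_explained(cube, ds)
print(f"shuffled control     : {ds.variance_explained:.3f} "
      "(same amplitudes, scrambled phases: the plane-wave constraint fails, "
      "so the statistic is specific to spatially ordered waves)")
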