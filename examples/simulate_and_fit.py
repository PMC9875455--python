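"""Simulate a noiseless LV phantom acquisition and verify exact tensor recovery.

Builds the default annular left-ventricle phantom (five 2x2x5 mm short-axis
slices, +60/-60 degree transmural helix ramp), simulates the five-shell,
16-direction acquisition without noise, fits the b=1000 shell, and compares
the fitted eigensystem against the prescribed ground truth.
"""

import math

import numpy as np

import cardiodti as cd

spec = cd.PhantomSpec()
mask, tensors, frame = cd.build_phantom(spec)
protocol = cd.DiffusionProtocol.default()
ds = cd.simulate_dwi(tensors, protocol, spec.s0, math.inf, 0, voxel_size=spec.voxel_size)

tf = cd.fit_tensor_loglinear(ds.signal, protocol, 1000.0, mask)
eigs = cd.eigen_decompose(tf)

ev_err = np.abs(np.sort(eigs.evals[mask], axis=-1)[:, ::-1] - np.array(spec.eigenvalues)).max()
print(f"phantom voxels:                  {int(mask.sum())}")
print(f"true eigenvalues (mm^2/s):       {spec.eigenvalues}")
print(f"max eigenvalue recovery error:   {ev_err:.3e} mm^2/s")
print("-> the log-linear fit inverts noiseless Stejskal-Tanner signals exactly;")
print("   any error is floating-point rounding.")
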