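"""Compute the six cardiac DTI indices on a noisy phantom acquisition.

Simulates the default phantom at SNR 20, fits the b=1000 shell, builds the
wall coordinate frame from the mask alone (as on real data), and prints the
mid-slice summary of MD, FA, HA, E2A, TA and the HA transmural gradient.
"""

import dataclasses

import cardiodti as cd

spec = dataclasses.replace(cd.PhantomSpec(), snr=20.0, seed=42)
protocol = cd.DiffusionProtocol.default()
ds = cd.make_dataset(spec, protocol)

tf = cd.fit_tensor_loglinear(ds.signal, protocol, 1000.0, ds.mask)
eigs = cd.eigen_decompose(tf)
frame = cd.compute_wall_frame(ds.mask, spec.voxel_size)
maps = cd.compute_index_maps(eigs, frame)
summ = cd.slice_summary(maps, frame, spec.grid_shape[2] // 2)

units = {"FA": "", "MD": "mm^2/s", "HA": "deg", "E2A": "deg", "TA": "deg", "HA_gradient": "deg/%trans"}
for name, (value, n) in summ.items():
    print(f"{name:12s} {value: .5g} {units[name]:10s} (n={n} voxels)")
print("-> MD ~ 0.7e-3 mm^2/s and FA ~ 0.32 match the phantom's prescribed")
print("   eigenvalues; the HA gradient ~ -1.2 deg/%trans is the -120 degree")
print("   helix ramp spread over 100% of the wall; E2A ~ 35 deg is the")
print("   prescribed sheetlet angle. Noise biases FA and E2A slightly upward.")
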