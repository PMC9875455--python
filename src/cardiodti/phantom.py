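"""Synthetic ex-vivo left-ventricle phantom and diffusion signal simulator.

The phantom is an annular short-axis myocardium replicated over a few
slices (an ex-vivo heart does not move, so slices are analytic copies).
Each voxel's primary eigenvector follows the classic transmural helix-angle
ramp: HA varies linearly with transmural depth from ``ha_endo`` at the
endocardium to ``ha_epi`` at the epicardium, lying in the local
circumferential–longitudinal (tangent) plane. The secondary eigenvector is
placed at a prescribed sheetlet angle (E2A) within the plane orthogonal to
the fiber, and the tensor is reconstructed as sum_i L_i E_i E_i^T.

Signals follow the monoexponential Stejskal–Tanner model with Rician
magnitude noise: |S + n1 + i n2| with n1, n2 ~ N(0, (S0/SNR)^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, ParameterError
from .protocol import DiffusionProtocol
from .tensor import TensorField
from .wallframe import WallFrame, ring_partition

__all__ = ["PhantomSpec", "DwiDataset", "build_phantom", "simulate_dwi", "make_dataset"]


@dataclass
class PhantomSpec:
    """Ground-truth parameters of the annular LV phantom.

    Defaults emulate the ex-vivo acquisitions this package models: 2x2x5 mm
    voxels, five short-axis slices, a +60/-60 degree transmural helix ramp,
    eigenvalues giving MD = 0.7e-3 mm^2/s and FA ~ 0.32, and a constant
    sheetlet angle of 35 degrees.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 5)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 5.0)  # mm
    center: tuple[float, float] | None = None  # voxel coords; grid centre if None
    inner_radius: float = 12.0  # mm
    outer_radius: float = 30.0  # mm
    ha_endo: float = 60.0  # degrees
    ha_epi: float = -60.0  # degrees
    eigenvalues: tuple[float, float, float] = (0.95e-3, 0.65e-3, 0.5e-3)  # mm^2/s
    e2a: float = 35.0  # degrees, constant across the wall
    s0: float = 1000.0
    snr: float = math.inf  # S0 / sigma of each Gaussian noise component
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inner_radius >= self.outer_radius:
            raise ParameterError("inner radius must be smaller than outer radius")
        l1, l2, l3 = self.eigenvalues
        if not (l1 >= l2 >= l3 > 0):
            raise ParameterError("eigenvalues must satisfy L1 >= L2 >= L3 > 0")
        if not self.snr > 0:
            raise ParameterError("SNR must be positive (inf for noiseless)")
        if self.s0 <= 0:
            raise ParameterError("S0 must be positive")
        for ha in (self.ha_endo, self.ha_epi):
            if not -90.0 <= ha <= 90.0:
                raise ParameterError("helix angles must lie in [-90, 90] degrees")

    @property
    def center_vox(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        nx, ny, _ = self.grid_shape
        return ((nx - 1) / 2.0, (ny - 1) / 2.0)


@dataclass
class DwiDataset:
    """A simulated (or loaded) multi-shell DWI acquisition.

    ``signal`` is (X, Y, Z, n_volumes) ordered as the protocol's volume
    table. Ground truth (``truth_tensors``, ``truth_frame``, ``spec``) is
    present for synthetic data only.
    """

    signal: np.ndarray
    protocol: DiffusionProtocol
    mask: np.ndarray
    voxel_size: tuple[float, float, float]
    truth_tensors: TensorField | None = None
    truth_frame: WallFrame | None = None
    spec: PhantomSpec | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.signal.shape[-1] != self.protocol.n_volumes:
            raise ParameterError(
                f"volume count {self.signal.shape[-1]} != protocol volumes {self.protocol.n_volumes}"
            )
        if self.mask.shape != self.signal.shape[:-1]:
            raise ParameterError("mask shape must match the signal grid")


def build_phantom(spec: PhantomSpec) -> tuple[np.ndarray, TensorField, WallFrame]:
    """Construct the annulus mask and analytic ground-truth fields.

    Returns (mask, tensors, frame). Depth is the analytic radial position
    (r - r_inner) / (r_outer - r_inner), so the prescribed helix ramp is
    exact; the frame uses the analytic centre, not a mask centroid.
    """
    nx, ny, nz = spec.grid_shape
    cx, cy = spec.center_vox
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    dx = (ii - cx) * spec.voxel_size[0]
    dy = (jj - cy) * spec.voxel_size[1]
    r = np.hypot(dx, dy)
    sl_mask = (r >= spec.inner_radius) & (r <= spec.outer_radius)
    if not sl_mask.any():
        raise GeometryError("annulus is empty on this grid: check radii vs grid extent")
    mask = np.repeat(sl_mask[:, :, None], nz, axis=2)

    with np.errstate(invalid="ignore"):
        rad2d = np.stack([np.where(r > 0, dx / r, 0.0), np.where(r > 0, dy / r, 0.0)], axis=-1)
    depth2d = np.where(sl_mask, (r - spec.inner_radius) / (spec.outer_radius - spec.inner_radius), np.nan)

    shape = (nx, ny, nz)
    radial = np.zeros(shape + (3,))
    circ = np.zeros(shape + (3,))
    longi = np.zeros(shape + (3,))
    depth = np.full(shape, np.nan)
    valid = np.zeros(shape, bool)
    for z in range(nz):
        radial[:, :, z, 0] = np.where(sl_mask, rad2d[..., 0], 0.0)
        radial[:, :, z, 1] = np.where(sl_mask, rad2d[..., 1], 0.0)
        longi[:, :, z, 2] = np.where(sl_mask, 1.0, 0.0)
        depth[:, :, z] = np.where(sl_mask, depth2d, np.nan)
        valid[:, :, z] = sl_mask
    # circumferential = longitudinal x radial
    circ = np.cross(longi, radial)
    ring = ring_partition(depth)
    frame = WallFrame(
        radial=radial, circumferential=circ, longitudinal=longi,
        depth=depth, ring=ring, mask=mask, valid=valid,
    )

    ha = np.deg2rad(spec.ha_endo + (spec.ha_epi - spec.ha_endo) * depth)
    e2a = np.deg2rad(np.full(shape, float(spec.e2a)))
    cos_ha, sin_ha = np.cos(ha)[..., None], np.sin(ha)[..., None]
    e1 = cos_ha * circ + sin_ha * longi
    # cross-myocyte tangent axis: in the tangent plane, orthogonal to E1
    w = np.cross(e1, radial)
    cos_a, sin_a = np.cos(e2a)[..., None], np.sin(e2a)[..., None]
    e2 = cos_a * w + sin_a * radial
    e3 = np.cross(e1, e2)

    l1, l2, l3 = spec.eigenvalues
    mats = (
        l1 * e1[..., :, None] * e1[..., None, :]
        + l2 * e2[..., :, None] * e2[..., None, :]
        + l3 * e3[..., :, None] * e3[..., None, :]
    )
    mats = np.where(mask[..., None, None], mats, 0.0)
    tensors = TensorField.from_matrices(mats, mask, ln_s0=np.log(spec.s0))
    return mask, tensors, frame


def simulate_dwi(
    tensors: TensorField,
    protocol: DiffusionProtocol,
    s0: float,
    snr: float,
    seed: int,
    *,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    frame: WallFrame | None = None,
    spec: PhantomSpec | None = None,
) -> DwiDataset:
    """Simulate the multi-shell magnitude acquisition for a tensor field.

    Noiseless signal per volume is S0 exp(-b g^T D g) inside the mask (S0
    for b=0 volumes) and 0 outside; Rician noise |S + n1 + i n2| with
    n1, n2 ~ N(0, (S0/SNR)^2) is applied independently per voxel and
    volume. ``snr=inf`` gives the noiseless magnitude signal. Fully
    reproducible given ``seed``.
    """
    if s0 <= 0:
        raise ParameterError("S0 must be positive")
    if not snr > 0:
        raise ParameterError("SNR must be positive (inf for noiseless)")
    bvals, bvecs = protocol.volume_table()
    mats = tensors.matrices()
    mask = tensors.mask
    # g^T D g for every voxel x volume
    quad = np.einsum("vi,...ij,vj->...v", bvecs, mats, bvecs)
    clean = np.where(mask[..., None], s0 * np.exp(-bvals * quad), 0.0)
    if math.isinf(snr):
        signal = clean
    else:
        sigma = s0 / snr
        rng = np.random.default_rng(seed)
        n1 = rng.normal(0.0, sigma, clean.shape)
        n2 = rng.normal(0.0, sigma, clean.shape)
        signal = np.hypot(clean + n1, n2)
    return DwiDataset(
        signal=signal, protocol=protocol, mask=mask.copy(),
        voxel_size=voxel_size, truth_tensors=tensors, truth_frame=frame, spec=spec,
    )


def make_dataset(spec: PhantomSpec, protocol: DiffusionProtocol | None = None) -> DwiDataset:
    """Convenience: build the phantom and simulate its acquisition."""
    protocol = protocol or DiffusionProtocol.default()
    mask, tensors, frame = build_phantom(spec)
    return simulate_dwi(
        tensors, protocol, spec.s0, spec.snr, spec.seed,
        voxel_size=spec.voxel_size, frame=frame, spec=spec,
    )
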