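"""Local left-ventricular wall coordinates on short-axis slices.

Every masked voxel gets an orthonormal right-handed frame
(radial, circumferential, longitudinal) with longitudinal = slice normal
(+z), radial pointing outward from the slice centroid, and
circumferential = longitudinal x radial. Transmural depth runs from 0 at
the endocardium (cavity side) to 1 at the epicardium and is estimated from
two-sided Euclidean distance transforms; the wall is partitioned into five
equal-depth concentric rings for the helix-angle gradient regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import GeometryError

__all__ = [
    "WallFrame",
    "lv_centroid",
    "local_wall_frame",
    "transmural_depth",
    "ring_partition",
    "compute_wall_frame",
]


@dataclass
class WallFrame:
    """Per-voxel wall coordinate system over a masked grid.

    ``radial``, ``circumferential``, ``longitudinal``: (X, Y, Z, 3) unit
    vectors (orthonormal, right-handed: radial x circumferential =
    longitudinal). ``depth``: transmural depth in [0, 1]; ``ring``: label
    1..n_rings (0 outside the mask); ``valid``: False where the frame is
    undefined (voxel at the centroid).
    """

    radial: np.ndarray
    circumferential: np.ndarray
    longitudinal: np.ndarray
    depth: np.ndarray
    ring: np.ndarray
    mask: np.ndarray
    valid: np.ndarray
    n_rings: int = 5


def lv_centroid(mask: np.ndarray, slice_index: int, voxel_size=(1.0, 1.0, 1.0)) -> np.ndarray:
    """In-plane centroid (physical x, y) of the masked voxels of one slice."""
    sl = np.asarray(mask, bool)[:, :, slice_index]
    if not sl.any():
        raise GeometryError(f"slice {slice_index}: mask is empty")
    ii, jj = np.nonzero(sl)
    return np.array([ii.mean() * voxel_size[0], jj.mean() * voxel_size[1]])


def local_wall_frame(mask: np.ndarray, voxel_size=(1.0, 1.0, 1.0)) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Radial / circumferential / longitudinal unit vectors per masked voxel.

    Returns (radial, circumferential, longitudinal, valid); vectors are zero
    and ``valid`` False outside the mask or where the voxel coincides with
    the slice centroid (radial undefined).
    """
    mask = np.asarray(mask, bool)
    shape = mask.shape
    radial = np.zeros(shape + (3,))
    circ = np.zeros(shape + (3,))
    longi = np.zeros(shape + (3,))
    valid = np.zeros(shape, bool)
    for z in range(shape[2]):
        sl = mask[:, :, z]
        if not sl.any():
            continue
        c = lv_centroid(mask, z, voxel_size)
        ii, jj = np.nonzero(sl)
        dx = ii * voxel_size[0] - c[0]
        dy = jj * voxel_size[1] - c[1]
        r = np.hypot(dx, dy)
        ok = r > 1e-9
        rad = np.zeros((ii.size, 3))
        rad[ok, 0] = dx[ok] / r[ok]
        rad[ok, 1] = dy[ok] / r[ok]
        lon = np.tile([0.0, 0.0, 1.0], (ii.size, 1))
        # circumferential = longitudinal x radial
        cir = np.cross(lon, rad)
        radial[ii, jj, z] = rad
        circ[ii, jj, z] = cir
        longi[ii, jj, z] = lon
        valid[ii, jj, z] = ok
    return radial, circ, longi, valid


def _slice_depth(sl: np.ndarray, centroid_vox: np.ndarray, voxel_size) -> np.ndarray:
    """Depth for one annular slice via two-sided distance transforms."""
    bg = ~sl
    labels, n = ndimage.label(bg)
    if n < 2:
        raise GeometryError("mask has no interior cavity: cannot define endocardium")
    ci, cj = (int(round(centroid_vox[0])), int(round(centroid_vox[1])))
    ci = np.clip(ci, 0, sl.shape[0] - 1)
    cj = np.clip(cj, 0, sl.shape[1] - 1)
    cavity_label = labels[ci, cj]
    if cavity_label == 0:
        # centroid fell on the mask; take the nearest background pixel
        bi, bj = np.nonzero(bg)
        k = np.argmin((bi - ci) ** 2 + (bj - cj) ** 2)
        cavity_label = labels[bi[k], bj[k]]
    cavity = labels == cavity_label
    outer = bg & ~cavity
    if not outer.any():
        raise GeometryError("mask has no outer background: cannot define epicardium")
    sampling = (voxel_size[0], voxel_size[1])
    d_endo = ndimage.distance_transform_edt(~cavity, sampling=sampling)
    d_epi = ndimage.distance_transform_edt(~outer, sampling=sampling)
    # distances are voxel-centre to voxel-centre; subtract half a voxel per
    # side so depth approximates the analytic interface-to-interface ratio
    half = 0.5 * float(np.mean(sampling))
    de = np.clip(d_endo - half, 0.0, None)
    dp = np.clip(d_epi - half, 0.0, None)
    with np.errstate(invalid="ignore", divide="ignore"):
        depth = np.where(sl, de / np.maximum(de + dp, 1e-12), np.nan)
    return np.clip(depth, 0.0, 1.0, out=depth)


def transmural_depth(mask: np.ndarray, voxel_size=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Transmural depth map: 0 at the endocardial edge, 1 at the epicardial.

    depth = d_endo / (d_endo + d_epi) with d_endo / d_epi the in-plane
    Euclidean distances to the cavity-facing and outer-facing background
    components. NaN outside the mask.
    """
    mask = np.asarray(mask, bool)
    depth = np.full(mask.shape, np.nan)
    for z in range(mask.shape[2]):
        sl = mask[:, :, z]
        if not sl.any():
            continue
        c = lv_centroid(mask, z, voxel_size)
        cv = np.array([c[0] / voxel_size[0], c[1] / voxel_size[1]])
        depth[:, :, z] = _slice_depth(sl, cv, voxel_size)
    return depth


def ring_partition(depth: np.ndarray, n_rings: int = 5) -> np.ndarray:
    """Label masked voxels 1..n_rings by equal-width depth bins.

    Bins are left-closed / right-open except the last ([0.8, 1] for five
    rings), so depth 0.4 falls in ring 3. 0 outside the mask.
    """
    ring = np.zeros(depth.shape, dtype=np.int8)
    inside = np.isfinite(depth)
    ring[inside] = np.minimum((depth[inside] * n_rings).astype(int), n_rings - 1) + 1
    return ring


def compute_wall_frame(mask: np.ndarray, voxel_size=(1.0, 1.0, 1.0), n_rings: int = 5) -> WallFrame:
    """Full wall frame: vectors, depth and ring labels in one pass."""
    radial, circ, longi, valid = local_wall_frame(mask, voxel_size)
    depth = transmural_depth(mask, voxel_size)
    ring = ring_partition(depth, n_rings)
    empty = [r for r in range(1, n_rings + 1) if not (ring == r).any()]
    if empty:
        warnings.warn(f"empty transmural rings: {empty}", stacklevel=2)
    return WallFrame(
        radial=radial,
        circumferential=circ,
        longitudinal=longi,
        depth=depth,
        ring=ring,
        mask=np.asarray(mask, bool).copy(),
        valid=valid,
        n_rings=n_rings,
    )
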