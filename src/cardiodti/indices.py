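"""The six DTI indices: MD, FA, HA, E2A, TA and the HA transmural gradient.

Angle conventions (eigenvectors are axes — every angle is invariant to a
sign flip of the eigenvector):

* HA: project E1 onto the circumferential–longitudinal (wall tangent)
  plane; signed angle of the projection from the circumferential axis,
  positive toward +longitudinal, folded into [-90, 90] degrees.
* TA: project E1 onto the circumferential–radial (short-axis) plane;
  signed angle from circumferential toward +radial, folded into [-90, 90].
* E2A: project E2 onto the cross-myocyte plane (spanned by the radial axis
  and the in-tangent-plane axis orthogonal to the fiber projection);
  absolute angle of that projection from the tangent-plane axis, in
  [0, 90].

The HA transmural gradient is the OLS slope of ring-mean HA against
transmural depth in percent (ring centres 10, 30, ..., 90 %trans by
default), reported in degrees per %trans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import AnalysisError
from .tensor import EigenSystem
from .wallframe import WallFrame

__all__ = [
    "IndexMaps",
    "mean_diffusivity",
    "fractional_anisotropy",
    "helix_angle",
    "transverse_angle",
    "e2_angle",
    "ha_transmural_gradient",
    "compute_index_maps",
    "slice_summary",
]

INDEX_NAMES = ("FA", "MD", "HA", "E2A", "HA_gradient", "TA")

_PROJ_TOL = 1e-6


@dataclass
class IndexMaps:
    """Voxelwise index maps (NaN where invalid) plus per-index validity."""

    md: np.ndarray
    fa: np.ndarray
    ha: np.ndarray
    ta: np.ndarray
    e2a: np.ndarray
    valid_scalar: np.ndarray  # MD / FA validity
    valid_ha: np.ndarray
    valid_ta: np.ndarray
    valid_e2a: np.ndarray
    mask: np.ndarray


def mean_diffusivity(eigs: EigenSystem) -> np.ndarray:
    """MD = (L1 + L2 + L3) / 3, mm^2/s; NaN outside valid voxels."""
    md = eigs.evals.mean(axis=-1)
    return np.where(eigs.valid, md, np.nan)


def fractional_anisotropy(eigs: EigenSystem) -> np.ndarray:
    """FA = sqrt(3/2) * ||L - MD|| / ||L||, with FA = 0 for a zero tensor."""
    lam = eigs.evals
    md = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(((lam - md) ** 2).sum(axis=-1))
    den = np.sqrt((lam**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return np.where(eigs.valid, fa, np.nan)


def _fold(deg: np.ndarray) -> np.ndarray:
    """Fold an angle in degrees into [-90, 90) modulo 180."""
    return (deg + 90.0) % 180.0 - 90.0


def _signed_plane_angle(vec, axis_zero, axis_pos, valid_in):
    """Signed, folded angle of vec's projection onto span(axis_zero, axis_pos)."""
    a = np.einsum("...i,...i->...", vec, axis_zero)
    b = np.einsum("...i,...i->...", vec, axis_pos)
    norm = np.hypot(a, b)
    ok = valid_in & (norm > _PROJ_TOL)
    with np.errstate(invalid="ignore", divide="ignore"):
        ang = _fold(np.degrees(np.arctan2(b, a)))
    return np.where(ok, ang, np.nan), ok


def helix_angle(e1: np.ndarray, frame: WallFrame) -> tuple[np.ndarray, np.ndarray]:
    """HA map (degrees, signed) and its validity.

    Invalid where the frame is undefined or E1 is (numerically) radial.
    """
    return _signed_plane_angle(e1, frame.circumferential, frame.longitudinal, frame.valid)


def transverse_angle(e1: np.ndarray, frame: WallFrame) -> tuple[np.ndarray, np.ndarray]:
    """TA map (degrees, signed, positive toward +radial) and validity."""
    return _signed_plane_angle(e1, frame.circumferential, frame.radial, frame.valid)


def e2_angle(e1: np.ndarray, e2: np.ndarray, frame: WallFrame) -> tuple[np.ndarray, np.ndarray]:
    """E2A map (degrees, absolute, [0, 90]) and validity.

    The cross-myocyte plane is spanned by the radial axis and
    w = fiber_projection x radial (the tangent-plane axis orthogonal to the
    in-plane fiber direction); E2A is the absolute angle of E2's projection
    onto that plane, measured from w toward radial.
    """
    rad = frame.radial
    f = e1 - np.einsum("...i,...i->...", e1, rad)[..., None] * rad
    fn = np.linalg.norm(f, axis=-1)
    ok = frame.valid & (fn > _PROJ_TOL)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = f / np.maximum(fn, 1e-300)[..., None]
    w = np.cross(f, rad)
    a = np.abs(np.einsum("...i,...i->...", e2, w))
    b = np.abs(np.einsum("...i,...i->...", e2, rad))
    norm = np.hypot(a, b)
    ok &= norm > _PROJ_TOL
    with np.errstate(invalid="ignore"):
        ang = np.degrees(np.arctan2(b, a))
    return np.where(ok, ang, np.nan), ok


def ha_transmural_gradient(
    ha: np.ndarray,
    ha_valid: np.ndarray,
    frame: WallFrame,
    slice_index: int,
    *,
    abscissa: str = "ring_center",
) -> float:
    """OLS slope of ring-mean HA vs transmural depth (%), deg per %trans.

    ``abscissa``: "ring_center" regresses against the nominal ring centres
    (10, 30, 50, 70, 90 %trans for five rings); "ring_mean_depth" uses each
    ring's observed mean depth instead. Requires >= 2 non-empty rings.
    """
    ring = frame.ring[:, :, slice_index]
    vals = ha[:, :, slice_index]
    ok = ha_valid[:, :, slice_index]
    xs, ys = [], []
    n = frame.n_rings
    for r in range(1, n + 1):
        sel = (ring == r) & ok
        if not sel.any():
            warnings.warn(f"slice {slice_index}: ring {r} has no valid HA voxels", stacklevel=2)
            continue
        ys.append(vals[sel].mean())
        if abscissa == "ring_center":
            xs.append((r - 0.5) / n * 100.0)
        elif abscissa == "ring_mean_depth":
            xs.append(float(np.nanmean(frame.depth[:, :, slice_index][sel])) * 100.0)
        else:
            raise ValueError(f"unknown abscissa mode: {abscissa!r}")
    if len(xs) < 2:
        raise AnalysisError(f"slice {slice_index}: need >= 2 usable rings for the HA gradient")
    slope = np.polyfit(np.asarray(xs), np.asarray(ys), 1)[0]
    return float(slope)


def compute_index_maps(eigs: EigenSystem, frame: WallFrame) -> IndexMaps:
    """All voxelwise index maps from an eigensystem and wall frame."""
    md = mean_diffusivity(eigs)
    fa = fractional_anisotropy(eigs)
    ha, v_ha = helix_angle(eigs.e1, frame)
    ta, v_ta = transverse_angle(eigs.e1, frame)
    e2a, v_e2a = e2_angle(eigs.e1, eigs.e2, frame)
    valid_scalar = eigs.valid & eigs.mask
    return IndexMaps(
        md=md, fa=fa, ha=ha, ta=ta, e2a=e2a,
        valid_scalar=valid_scalar,
        valid_ha=v_ha & valid_scalar,
        valid_ta=v_ta & valid_scalar,
        valid_e2a=v_e2a & valid_scalar,
        mask=eigs.mask.copy(),
    )


def slice_summary(
    maps: IndexMaps,
    frame: WallFrame,
    slice_index: int,
    *,
    gradient_abscissa: str = "ring_center",
) -> dict[str, tuple[float, int]]:
    """Per-slice summary: mean of each index over valid voxels.

    Returns ``{index name: (value, n voxels)}``; the HA transmural gradient
    is a per-slice scalar (n = number of HA voxels entering the ring
    means). Entries with zero valid voxels are reported as (nan, 0).
    """
    z = slice_index
    out: dict[str, tuple[float, int]] = {}
    for name, arr, valid in (
        ("FA", maps.fa, maps.valid_scalar),
        ("MD", maps.md, maps.valid_scalar),
        ("HA", maps.ha, maps.valid_ha),
        ("E2A", maps.e2a, maps.valid_e2a),
        ("TA", maps.ta, maps.valid_ta),
    ):
        sel = valid[:, :, z]
        n = int(sel.sum())
        out[name] = (float(arr[:, :, z][sel].mean()) if n else float("nan"), n)
    try:
        grad = ha_transmural_gradient(maps.ha, maps.valid_ha, frame, z, abscissa=gradient_abscissa)
        out["HA_gradient"] = (grad, out["HA"][1])
    except AnalysisError:
        out["HA_gradient"] = (float("nan"), 0)
    return out
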