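"""On-disk dataset layout: NIfTI volumes + FSL-style bval/bvec + sidecar.

A dataset directory contains::

    dwi.nii     4D signal volume (x, y, z, volume)
    dwi.bval    one row of b-values, one entry per volume
    dwi.bvec    three rows (x, y, z), one column per volume; zero for b=0
    mask.nii    uint8 myocardium mask
    truth.json  (synthetic data only) the phantom parameters; ground truth
                is regenerated exactly via build_phantom on read

NIfTI files are written uncompressed so repeated runs are byte-identical.
The volume ordering matches ``DiffusionProtocol.volume_table()``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import FormatError
from .phantom import DwiDataset, PhantomSpec, build_phantom
from .protocol import DiffusionProtocol

__all__ = ["write_dataset", "read_dataset"]

_B0_TOL = 1.0  # b-values below this count as b=0


def _affine(voxel_size) -> np.ndarray:
    return np.diag([voxel_size[0], voxel_size[1], voxel_size[2], 1.0])


def write_dataset(ds: DwiDataset, path: str | Path) -> Path:
    """Write a dataset directory; returns the directory path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    aff = _affine(ds.voxel_size)
    nib.save(nib.Nifti1Image(ds.signal.astype(np.float64), aff), path / "dwi.nii")
    nib.save(nib.Nifti1Image(ds.mask.astype(np.uint8), aff), path / "mask.nii")
    bvals, bvecs = ds.protocol.volume_table()
    np.savetxt(path / "dwi.bval", bvals[None, :], fmt="%.17g")
    np.savetxt(path / "dwi.bvec", bvecs.T, fmt="%.17g")
    if ds.spec is not None:
        spec_dict = dataclasses.asdict(ds.spec)
        spec_dict["snr"] = "inf" if np.isinf(ds.spec.snr) else ds.spec.snr
        (path / "truth.json").write_text(json.dumps(spec_dict, indent=2, sort_keys=True))
    return path


def _protocol_from_tables(bvals: np.ndarray, bvecs: np.ndarray) -> DiffusionProtocol:
    """Rebuild a protocol from per-volume tables (b0 volumes first)."""
    is_b0 = bvals < _B0_TOL
    n_b0 = int(is_b0.sum())
    if n_b0 < 1:
        raise FormatError("no b=0 volume in bval file")
    shells: list[float] = []
    dirs: dict[float, list[np.ndarray]] = {}
    for b, g in zip(bvals[~is_b0], bvecs[~is_b0]):
        if b not in dirs:
            shells.append(b)
            dirs[b] = []
        dirs[b].append(g)
    return DiffusionProtocol(
        tuple(shells), tuple(np.asarray(dirs[b]) for b in shells), n_b0
    )


def read_dataset(path: str | Path) -> DwiDataset:
    """Read a dataset directory written by :func:`write_dataset`.

    Raises :class:`FormatError` when bval/bvec lengths disagree with the
    number of volumes in the NIfTI image.
    """
    path = Path(path)
    img = nib.load(path / "dwi.nii")
    signal = np.asarray(img.dataobj, dtype=np.float64)
    if signal.ndim != 4:
        raise FormatError("dwi.nii must be 4D (x, y, z, volume)")
    voxel_size = tuple(float(v) for v in img.header.get_zooms()[:3])
    mask = np.asarray(nib.load(path / "mask.nii").dataobj).astype(bool)

    bvals = np.atleast_1d(np.loadtxt(path / "dwi.bval"))
    bvecs = np.loadtxt(path / "dwi.bvec")
    if bvecs.ndim == 1:
        bvecs = bvecs[:, None]
    if bvecs.shape[0] != 3:
        raise FormatError("dwi.bvec must have 3 rows (x, y, z)")
    n_vol = signal.shape[-1]
    if bvals.size != n_vol or bvecs.shape[1] != n_vol:
        raise FormatError(
            f"bval/bvec entries ({bvals.size}/{bvecs.shape[1]}) do not match "
            f"the {n_vol} volumes in dwi.nii"
        )
    protocol = _protocol_from_tables(bvals, bvecs.T)

    spec = truth_tensors = truth_frame = None
    truth_path = path / "truth.json"
    if truth_path.exists():
        raw = json.loads(truth_path.read_text())
        raw["snr"] = np.inf if raw["snr"] == "inf" else raw["snr"]
        raw["grid_shape"] = tuple(raw["grid_shape"])
        raw["voxel_size"] = tuple(raw["voxel_size"])
        raw["eigenvalues"] = tuple(raw["eigenvalues"])
        if raw.get("center") is not None:
            raw["center"] = tuple(raw["center"])
        spec = PhantomSpec(**raw)
        _, truth_tensors, truth_frame = build_phantom(spec)

    return DwiDataset(
        signal=signal,
        protocol=protocol,
        mask=mask,
        voxel_size=voxel_size,
        truth_tensors=truth_tensors,
        truth_frame=truth_frame,
        spec=spec,
    )
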