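"""Per-voxel diffusion tensor estimation and diagonalization.

The signal model is monoexponential (Stejskal–Tanner):

    S(b, g) = S0 * exp(-b * g^T D g)

so ln S is linear in (ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) and the tensor is
estimated by ordinary least squares on log-signals, one shell at a time
together with the shared b=0 volume(s). Noiseless data are recovered
exactly; no positivity constraint is imposed during the fit — negative
eigenvalues are clamped to zero afterwards and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ProtocolError
from .protocol import DiffusionProtocol

__all__ = ["TensorField", "EigenSystem", "design_matrix", "fit_tensor_loglinear", "eigen_decompose"]

#: order of the six unique tensor coefficients everywhere in the package
COEFF_NAMES = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")


@dataclass
class TensorField:
    """Symmetric diffusion tensors over a masked grid.

    ``coeffs[..., :]`` holds (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) in mm^2/s;
    ``ln_s0`` is the fitted (or prescribed) log reference signal; ``valid``
    marks voxels whose fit succeeded (finite, non-degenerate signals).
    """

    coeffs: np.ndarray  # (X, Y, Z, 6)
    ln_s0: np.ndarray  # (X, Y, Z)
    mask: np.ndarray  # (X, Y, Z) bool
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = self.mask.copy()

    def matrices(self) -> np.ndarray:
        """Full (X, Y, Z, 3, 3) symmetric matrices."""
        c = self.coeffs
        out = np.empty(c.shape[:-1] + (3, 3), dtype=float)
        out[..., 0, 0] = c[..., 0]
        out[..., 1, 1] = c[..., 1]
        out[..., 2, 2] = c[..., 2]
        out[..., 0, 1] = out[..., 1, 0] = c[..., 3]
        out[..., 0, 2] = out[..., 2, 0] = c[..., 4]
        out[..., 1, 2] = out[..., 2, 1] = c[..., 5]
        return out

    @classmethod
    def from_matrices(cls, mats: np.ndarray, mask: np.ndarray, ln_s0: np.ndarray | float = 0.0) -> "TensorField":
        coeffs = np.stack(
            [mats[..., 0, 0], mats[..., 1, 1], mats[..., 2, 2],
             mats[..., 0, 1], mats[..., 0, 2], mats[..., 1, 2]],
            axis=-1,
        )
        ln_s0_arr = np.broadcast_to(np.asarray(ln_s0, dtype=float), mask.shape).copy()
        return cls(coeffs, ln_s0_arr, np.asarray(mask, bool))


@dataclass
class EigenSystem:
    """Per-voxel eigensystem of the diffusion tensor.

    ``evals[..., k]`` are L1 >= L2 >= L3 (mm^2/s); ``evecs[..., :, k]`` is the
    unit eigenvector Ek (its sign is arbitrary — all angle computations treat
    eigenvectors as axes). ``clamped`` marks voxels whose negative
    eigenvalues were clamped to zero.
    """

    evals: np.ndarray  # (X, Y, Z, 3), descending
    evecs: np.ndarray  # (X, Y, Z, 3, 3), column k = Ek
    mask: np.ndarray
    valid: np.ndarray
    clamped: np.ndarray

    @property
    def e1(self) -> np.ndarray:
        return self.evecs[..., :, 0]

    @property
    def e2(self) -> np.ndarray:
        return self.evecs[..., :, 1]

    @property
    def e3(self) -> np.ndarray:
        return self.evecs[..., :, 2]


def design_matrix(protocol: DiffusionProtocol, shell: float | None = None) -> np.ndarray:
    """b-matrix design mapping (ln S0, Dxx..Dyz) to log-signals.

    Row for a volume with b-value b and direction g = (gx, gy, gz):

        [1, -b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz, -2b gy gz]

    If ``shell`` is given, only the b=0 volumes and that shell's volumes are
    included (the per-shell fit the package uses throughout). Raises
    :class:`ProtocolError` if the matrix has rank < 7 (directions too
    degenerate to determine a tensor).
    """
    bvals, bvecs = protocol.volume_table()
    if shell is not None:
        idx = protocol.shell_volumes(shell)
        bvals, bvecs = bvals[idx], bvecs[idx]
    gx, gy, gz = bvecs[:, 0], bvecs[:, 1], bvecs[:, 2]
    X = np.column_stack(
        [
            np.ones_like(bvals),
            -bvals * gx * gx,
            -bvals * gy * gy,
            -bvals * gz * gz,
            -2 * bvals * gx * gy,
            -2 * bvals * gx * gz,
            -2 * bvals * gy * gz,
        ]
    )
    if X.shape[0] < 7 or np.linalg.matrix_rank(X) < 7:
        raise ProtocolError(
            "design matrix rank-deficient: need >=7 volumes with directions spanning 3D"
        )
    return X


def _floor_signals(signals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Replace non-positive signals by half the voxel's smallest positive one.

    Returns (floored signals, per-voxel validity); voxels with no positive
    signal at all are invalid.
    """
    s = signals.copy()
    pos = s > 0
    any_pos = pos.any(axis=-1)
    with np.errstate(invalid="ignore"):
        smallest = np.min(np.where(pos, s, np.inf), axis=-1)
    floor = 0.5 * np.where(any_pos, smallest, 1.0)
    bad = ~pos
    s[bad] = np.broadcast_to(floor[..., None], s.shape)[bad]
    return s, any_pos


def fit_tensor_loglinear(
    signals: np.ndarray,
    protocol: DiffusionProtocol,
    shell: float,
    mask: np.ndarray,
    *,
    weighted: bool = False,
) -> TensorField:
    """Fit one tensor per masked voxel from one shell plus the b=0 volume(s).

    Parameters
    ----------
    signals
        4D array (X, Y, Z, n_volumes) ordered as ``protocol.volume_table()``.
    shell
        The b-value of the shell to fit (each shell is fitted independently,
        sharing the b=0 reference, mirroring acquisitions performed as
        separate single-shell series).
    weighted
        If True, a second weighted-least-squares pass with weights equal to
        the squared predicted signals (WLS); default is plain OLS on logs.
    """
    if signals.shape[-1] != protocol.n_volumes:
        raise ProtocolError(
            f"signal volume count {signals.shape[-1]} != protocol volumes {protocol.n_volumes}"
        )
    X = design_matrix(protocol, shell)
    idx = protocol.shell_volumes(shell)
    sub = signals[..., idx]
    vox = np.asarray(mask, bool)
    s_m, valid_m = _floor_signals(sub[vox])  # (N, V)

    y = np.log(s_m)
    beta = np.linalg.lstsq(X, y.T, rcond=None)[0]  # (7, N)
    if weighted:
        w = np.exp(X @ beta)  # predicted signals, (V, N)
        # per-voxel weighted normal equations, vectorised
        Xw = X[None, :, :] * (w.T[:, :, None] ** 2)
        lhs = np.einsum("nvi,vj->nij", Xw, X)
        rhs = np.einsum("nvi,nv->ni", Xw, y)
        beta = np.linalg.solve(lhs, rhs[..., None])[..., 0].T

    finite = np.isfinite(beta).all(axis=0)
    valid_m &= finite

    shape = mask.shape
    coeffs = np.zeros(shape + (6,))
    ln_s0 = np.zeros(shape)
    valid = np.zeros(shape, bool)
    coeffs[vox] = beta[1:].T
    ln_s0[vox] = beta[0]
    valid[vox] = valid_m
    return TensorField(coeffs=coeffs, ln_s0=ln_s0, mask=vox.copy(), valid=valid)


def eigen_decompose(tf: TensorField) -> EigenSystem:
    """Diagonalize each voxel tensor into L1 >= L2 >= L3 and E1..E3.

    Negative eigenvalues are clamped to 0 and the voxel flagged ``clamped``;
    non-finite tensors are flagged invalid.
    """
    mats = tf.matrices()
    vox = tf.mask
    m = mats[vox]
    finite = np.isfinite(m).all(axis=(-2, -1))
    m_safe = np.where(finite[:, None, None], m, np.eye(3))
    w, v = np.linalg.eigh(m_safe)  # ascending
    w = w[:, ::-1]
    v = v[:, :, ::-1]
    clamped_m = (w < 0).any(axis=-1)
    w = np.clip(w, 0.0, None)

    shape = vox.shape
    evals = np.zeros(shape + (3,))
    evecs = np.zeros(shape + (3, 3))
    valid = np.zeros(shape, bool)
    clamped = np.zeros(shape, bool)
    evals[vox] = w
    evecs[vox] = v
    valid[vox] = finite & tf.valid[vox]
    clamped[vox] = clamped_m & finite
    return EigenSystem(evals=evals, evecs=evecs, mask=vox.copy(), valid=valid, clamped=clamped)
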