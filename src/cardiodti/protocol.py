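"""Diffusion acquisition protocol: b-values, gradient tables, b0 handling.

A protocol is the contract shared by the simulator and the tensor fit: it
fixes the volume ordering (all b=0 volumes first, then each shell's
directions in order) that both the 4D signal array and the FSL-style
bval/bvec files follow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .errors import ProtocolError

__all__ = ["DiffusionProtocol", "electrostatic_directions", "DEFAULT_BVALUES"]

#: Shells used throughout the ex-vivo acquisitions this package emulates.
DEFAULT_BVALUES = (200.0, 400.0, 600.0, 800.0, 1000.0)

_UNIT_TOL = 1e-8


def _repulsion_energy_grad(x: np.ndarray) -> np.ndarray:
    """Gradient of the antipodally-symmetric electrostatic energy.

    E = sum_{i<j} 1/|xi-xj| + 1/|xi+xj|; antipodal term makes the set a
    set of axes (diffusion directions are sign-free).
    """
    d = x[:, None, :] - x[None, :, :]
    s = x[:, None, :] + x[None, :, :]
    dn = np.linalg.norm(d, axis=-1)
    sn = np.linalg.norm(s, axis=-1)
    np.fill_diagonal(dn, np.inf)
    np.fill_diagonal(sn, np.inf)
    g = -(d / dn[..., None] ** 3).sum(axis=1) - (s / sn[..., None] ** 3).sum(axis=1)
    return g


@lru_cache(maxsize=8)
def _cached_directions(n: int, seed: int, iterations: int) -> tuple[tuple[float, ...], ...]:
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    step = 0.01
    for _ in range(iterations):
        g = _repulsion_energy_grad(x)
        # project gradient onto the tangent plane of each point
        g -= (g * x).sum(axis=1, keepdims=True) * x
        x -= step * g / max(n, 1)
        x /= np.linalg.norm(x, axis=1, keepdims=True)
    # canonical sign (first nonzero component positive) and stable order
    sign = np.where(np.abs(x[:, 0]) > 1e-12, np.sign(x[:, 0]), np.sign(x[:, 1] + 1e-30))
    x *= sign[:, None]
    order = np.lexsort((x[:, 2], x[:, 1], x[:, 0]))
    return tuple(tuple(float(v) for v in row) for row in x[order])


def electrostatic_directions(n: int, *, seed: int = 7, iterations: int = 2000) -> np.ndarray:
    """Return ``n`` unit diffusion directions spread by electrostatic repulsion.

    Deterministic given (n, seed, iterations): projected gradient descent on
    the sphere from a fixed pseudo-random start. Directions are axes (sign
    is irrelevant to diffusion weighting) and are canonically signed/sorted.
    """
    if n < 6:
        raise ProtocolError(f"need at least 6 directions for a tensor fit, got {n}")
    return np.asarray(_cached_directions(n, seed, iterations), dtype=float)


@dataclass(eq=False)
class DiffusionProtocol:
    """Multi-shell diffusion protocol.

    Parameters
    ----------
    bvalues
        One b-value per shell, s/mm^2, all > 0.
    directions
        One (n_i, 3) array of unit gradient directions per shell.
    n_b0
        Number of unweighted (b=0) reference volumes, >= 1.
    """

    bvalues: tuple[float, ...]
    directions: tuple[np.ndarray, ...] = field(repr=False)
    n_b0: int = 1

    def __post_init__(self) -> None:
        self.bvalues = tuple(float(b) for b in self.bvalues)
        self.directions = tuple(np.asarray(d, dtype=float) for d in self.directions)
        if len(self.bvalues) != len(self.directions):
            raise ProtocolError("one direction set required per shell")
        if self.n_b0 < 1:
            raise ProtocolError("at least one b=0 volume is required")
        if any(b <= 0 for b in self.bvalues):
            raise ProtocolError("shell b-values must be positive")
        for d in self.directions:
            if d.ndim != 2 or d.shape[1] != 3 or d.shape[0] < 1:
                raise ProtocolError("direction sets must be (n, 3) arrays")
            norms = np.linalg.norm(d, axis=1)
            if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
                raise ProtocolError("gradient directions must be unit-norm (tol 1e-8)")

    # -- volume bookkeeping -------------------------------------------------

    @property
    def n_volumes(self) -> int:
        return self.n_b0 + sum(d.shape[0] for d in self.directions)

    def volume_table(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-volume (bvals, bvecs): b0 volumes first, then shells in order.

        bvecs rows for b=0 volumes are zero, matching the FSL convention.
        """
        bvals = np.concatenate(
            [np.zeros(self.n_b0)]
            + [np.full(d.shape[0], b) for b, d in zip(self.bvalues, self.directions)]
        )
        bvecs = np.vstack([np.zeros((self.n_b0, 3))] + list(self.directions))
        return bvals, bvecs

    def shell_volumes(self, b: float) -> np.ndarray:
        """Indices of the b=0 volumes plus the requested shell's volumes."""
        if b not in self.bvalues:
            raise ProtocolError(f"shell b={b} not in protocol shells {self.bvalues}")
        bvals, _ = self.volume_table()
        return np.flatnonzero((bvals == 0) | (bvals == b))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DiffusionProtocol):
            return NotImplemented
        return (
            self.bvalues == other.bvalues
            and self.n_b0 == other.n_b0
            and len(self.directions) == len(other.directions)
            and all(np.array_equal(a, b) for a, b in zip(self.directions, other.directions))
        )

    @classmethod
    def default(
        cls,
        bvalues: tuple[float, ...] = DEFAULT_BVALUES,
        n_directions: int = 16,
        n_b0: int = 1,
    ) -> "DiffusionProtocol":
        """Protocol emulating the ex-vivo study: 16 directions per shell, one b0."""
        dirs = electrostatic_directions(n_directions)
        return cls(tuple(bvalues), tuple(dirs.copy() for _ in bvalues), n_b0)
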