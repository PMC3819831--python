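"""Control-lattice construction and control-point revision.

A :class:`ControlLattice` is one level of the deformation hierarchy: a
uniform mesh of control-point displacement vectors (units: voxels of the
image grid) overlaid on the image domain, with exactly one margin control
point beyond each boundary (conceptual indices -1 .. N+1 per axis, stored
with a +1 offset).  Grid size per axis is therefore

    ceil(domain_extent / spacing) + 3.

Spacing may differ per axis: clinical voxel grids are anisotropic, and the
isotropic mesh is the special case of equal per-axis spacing.  Hierarchical
refinement (spacing halved per level) lives in :mod:`mgrefine.deformation`,
which owns the multilevel container.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["ControlLattice", "create_lattice", "move_control_point", "as_spacing"]


def as_spacing(spacing: float | Sequence[float], ndim: int) -> tuple[float, ...]:
    """Normalise a scalar or per-axis spacing to a validated tuple."""
    if np.isscalar(spacing):
        sp = (float(spacing),) * ndim
    else:
        sp = tuple(float(s) for s in spacing)  # type: ignore[union-attr]
        if len(sp) != ndim:
            raise ValueError(
                f"spacing has {len(sp)} components for a {ndim}-D domain"
            )
    for s in sp:
        if not s > 0:
            raise ValueError(f"control-point spacing must be positive, got {s}")
    return sp


@dataclass(frozen=True)
class ControlLattice:
    """One level's mesh of control-point displacement vectors.

    Attributes
    ----------
    level : int
        1-based level in the hierarchy (spacing halves per level).
    spacing : tuple of float
        Control spacing per axis, in voxels.
    displacements : ndarray, shape ``grid_shape + (ndim,)``
        Displacement vector per control point, in voxels.  Storage index g
        along an axis holds conceptual control point g - 1, so index 0 is
        the -1 margin point.
    domain_shape : tuple of int
        Image voxel counts (X, Y[, Z]).
    """

    level: int
    spacing: tuple[float, ...]
    displacements: np.ndarray
    domain_shape: tuple[int, ...]

    def __post_init__(self) -> None:
        ndim = len(self.domain_shape)
        expected = expected_grid_shape(self.domain_shape, self.spacing)
        if self.displacements.shape != expected + (ndim,):
            raise ValueError(
                f"displacement array shape {self.displacements.shape} does not "
                f"match grid {expected} + vector dim {ndim}"
            )
        if not np.all(np.isfinite(self.displacements)):
            raise ValueError("control displacements must be finite")

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.displacements.shape[:-1]

    @property
    def ndim(self) -> int:
        return len(self.domain_shape)


def expected_grid_shape(
    domain_shape: Sequence[int], spacing: Sequence[float]
) -> tuple[int, ...]:
    """Control-point count per axis: interior cells plus the +/-1 margins."""
    return tuple(
        int(math.ceil(extent / sp)) + 3 for extent, sp in zip(domain_shape, spacing)
    )


def create_lattice(
    domain_shape: Sequence[int],
    spacing: float | Sequence[float],
    level: int = 1,
) -> ControlLattice:
    """Build a zero-displacement (identity) lattice over an image domain."""
    domain = tuple(int(s) for s in domain_shape)
    if len(domain) not in (2, 3):
        raise ValueError(f"domain must be 2-D or 3-D, got shape {domain}")
    if any(s < 2 for s in domain):
        raise ValueError(f"domain extents must all be >= 2, got {domain}")
    sp = as_spacing(spacing, len(domain))
    grid = expected_grid_shape(domain, sp)
    disp = np.zeros(grid + (len(domain),), dtype=float)
    return ControlLattice(level=int(level), spacing=sp, displacements=disp,
                          domain_shape=domain)


def move_control_point(
    lattice: ControlLattice, index: Sequence[int], delta: Sequence[float]
) -> ControlLattice:
    """Return a lattice with one control displacement incremented by delta.

    ``index`` is the storage index (0 .. grid_shape-1 per axis; 0 and the
    last index are the margin points).  The input lattice is not mutated.
    """
    idx = tuple(int(i) for i in index)
    if len(idx) != lattice.ndim:
        raise IndexError(
            f"index {idx} has wrong dimensionality for a {lattice.ndim}-D lattice"
        )
    for axis, (i, n) in enumerate(zip(idx, lattice.grid_shape)):
        if not 0 <= i < n:
            raise IndexError(
                f"control-point index {i} out of bounds [0, {n}) on axis {axis}"
            )
    d = np.asarray(delta, dtype=float)
    if d.shape != (lattice.ndim,):
        raise ValueError(f"delta must be a {lattice.ndim}-vector, got shape {d.shape}")
    disp = lattice.displacements.copy()
    disp[idx] += d
    return ControlLattice(
        level=lattice.level,
        spacing=lattice.spacing,
        displacements=disp,
        domain_shape=lattice.domain_shape,
    )
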