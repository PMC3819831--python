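"""Uniform cubic B-spline basis functions and single-level lattice evaluation.

A free-form deformation (FFD) represents a displacement field by a regular
mesh of control-point vectors blended with the four uniform cubic B-spline
basis polynomials

    B0(u) = (1 - u)^3 / 6
    B1(u) = (3 u^3 - 6 u^2 + 4) / 6
    B2(u) = (-3 u^3 + 3 u^2 + 3 u + 1) / 6
    B3(u) = u^3 / 6        for u in [0, 1].

The basis is nonnegative and partitions unity, so the displacement at any
point is a convex combination of the 4 (per axis) nearest control vectors:
moving one control point perturbs the field only inside its local 4-cell
support, which is what makes interactive, point-at-a-time revision viable.

Conventions fixed here and used throughout the package:

* image coordinates are 0-based and voxel-centred;
* lattice units are image coordinates divided by the control spacing, and
  control point 0 sits at image coordinate 0;
* a point x (in lattice units) is anchored at cell index i = floor(x) - 1
  with intra-cell fraction u = x - floor(x) in [0, 1);
* the lattice carries one margin control point beyond each end of the
  domain (conceptual indices -1 .. N+1), stored with a +1 offset so that
  storage index g holds conceptual control point g - 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .lattice import ControlLattice

__all__ = [
    "LatticeCoordinate",
    "cubic_basis",
    "basis_weights",
    "decompose_point",
    "evaluate_level_displacement",
]


@dataclass(frozen=True)
class LatticeCoordinate:
    """Anchor cell index and intra-cell fraction of a point in lattice units.

    ``cell_index`` holds i = floor(x) - 1 per axis (the conceptual index of
    the first control point in the 4-point support); ``fraction`` holds
    u = x - floor(x) per axis, always in [0, 1).
    """

    cell_index: tuple[int, ...]
    fraction: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.cell_index) != len(self.fraction):
            raise ValueError("cell_index and fraction must have equal length")
        for u in self.fraction:
            if not 0.0 <= u < 1.0:
                raise ValueError(f"fraction component {u!r} outside [0, 1)")


def cubic_basis(l: int, u: float) -> float:
    """Evaluate the l-th uniform cubic B-spline basis polynomial at u.

    Parameters
    ----------
    l : int
        Basis index in 0..3.
    u : float
        Intra-cell coordinate in the closed interval [0, 1]; u = 1 is
        accepted so the closed upper domain boundary is well defined
        (B3(1) = 1/6 etc.).
    """
    if l not in (0, 1, 2, 3):
        raise ValueError(f"basis index l={l!r} outside 0..3")
    u = float(u)
    if not 0.0 <= u <= 1.0:
        raise ValueError(f"basis argument u={u!r} outside [0, 1]")
    if l == 0:
        return (1.0 - u) ** 3 / 6.0
    if l == 1:
        return (3.0 * u**3 - 6.0 * u**2 + 4.0) / 6.0
    if l == 2:
        return (-3.0 * u**3 + 3.0 * u**2 + 3.0 * u + 1.0) / 6.0
    return u**3 / 6.0


def basis_weights(u: np.ndarray | float) -> np.ndarray:
    """All four basis weights, vectorised: shape ``u.shape + (4,)``.

    Identical polynomials to :func:`cubic_basis`; the stacked form is the
    work-horse for dense-field rendering.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0.0) or np.any(u > 1.0):
        raise ValueError("basis argument outside [0, 1]")
    u2 = u * u
    u3 = u2 * u
    w = np.empty(u.shape + (4,), dtype=float)
    w[..., 0] = (1.0 - u) ** 3 / 6.0
    w[..., 1] = (3.0 * u3 - 6.0 * u2 + 4.0) / 6.0
    w[..., 2] = (-3.0 * u3 + 3.0 * u2 + 3.0 * u + 1.0) / 6.0
    w[..., 3] = u3 / 6.0
    return w


def decompose_point(point: Sequence[float]) -> LatticeCoordinate:
    """Split a lattice-unit point into anchor cell index and fraction.

    Per axis: cell_index = floor(x) - 1, fraction = x - floor(x).  Any real
    point decomposes; reconstructing ``cell_index + 1 + fraction`` recovers
    the input exactly up to floating round-off.
    """
    cell = []
    frac = []
    for x in point:
        fx = float(np.floor(x))
        u = float(x) - fx
        if u >= 1.0:  # x - floor(x) can round up to 1.0 for tiny negative x
            fx += 1.0
            u = 0.0
        cell.append(int(fx) - 1)
        frac.append(u)
    return LatticeCoordinate(tuple(cell), tuple(frac))


def evaluate_level_displacement(
    lattice: "ControlLattice", point: Sequence[float]
) -> np.ndarray:
    """Tensor-product displacement of one lattice level at an image point.

    ``point`` is in image coordinates (voxels).  The result is the sum over
    the 4x4 (2-D) or 4x4x4 (3-D) neighbouring control displacements, each
    weighted by the product of per-axis cubic basis values; it depends only
    on control points within that support.

    Raises
    ------
    ValueError
        If the point lies outside the lattice domain [0, X) on some axis.
    """
    ndim = len(lattice.domain_shape)
    if len(point) != ndim:
        raise ValueError(
            f"point has {len(point)} coordinates, lattice domain is {ndim}-D"
        )
    bases: list[int] = []
    weights: list[np.ndarray] = []
    for axis, (x, extent, sp) in enumerate(
        zip(point, lattice.domain_shape, lattice.spacing)
    ):
        if not 0.0 <= x < extent:
            raise ValueError(
                f"point coordinate {x!r} outside domain [0, {extent}) on axis {axis}"
            )
        lat = float(x) / sp
        coord = decompose_point((lat,))
        # storage offset: conceptual anchor i maps to storage row i + 1
        bases.append(coord.cell_index[0] + 1)
        weights.append(basis_weights(coord.fraction[0]))

    disp = lattice.displacements
    # gather the 4^ndim support block and contract axis by axis
    block = disp[
        tuple(slice(b, b + 4) for b in bases) + (slice(None),)
    ]
    for w in reversed(weights):
        block = np.tensordot(w, block, axes=([0], [len(block.shape) - 2]))
        # tensordot moved the contracted axis; result axes: remaining spatial + vector
    # after contracting all spatial axes, shape is (ndim,)
    return np.asarray(block, dtype=float)
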