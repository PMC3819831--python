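"""Multilevel deformation: per-level transforms summed into the total field.

The total local transform is a hierarchy of control lattices with spacing
halved at each level,

    T_local(x) = sum_i T_local^i(x),

so coarse levels carry large-area corrections and fine levels small local
ones.  Refinement appends a zero-initialised finer lattice and leaves every
existing level untouched — the hierarchy retains all levels and the dense
field is bit-identical across a refinement.  After refining, coarse levels
are treated as read-only by convention (editing one triggers a warning, not
an error: the workflow permits revisiting a coarse grid, it is just usually
a sign the wrong level is selected).

The field is a DISPLACEMENT field: control vectors are displacements added
to the identity, so an all-zero hierarchy is the identity map and per-level
summation is well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .bspline import basis_weights, evaluate_level_displacement
from .lattice import ControlLattice, create_lattice, move_control_point

__all__ = [
    "MultilevelDeformation",
    "DenseField",
    "refine",
    "total_displacement",
    "render_dense_field",
]

_HALVING_RTOL = 1e-12


@dataclass(frozen=True)
class DenseField:
    """Displacement vector per voxel (units: voxels), rendered from a hierarchy."""

    vectors: np.ndarray  # shape domain_shape + (ndim,)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("dense field contains non-finite values")

    @property
    def domain_shape(self) -> tuple[int, ...]:
        return self.vectors.shape[:-1]


@dataclass(frozen=True)
class MultilevelDeformation:
    """Ordered list of control lattices whose displacements sum per Eq. above."""

    levels: tuple[ControlLattice, ...]
    domain_shape: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.levels) < 1:
            raise ValueError("a deformation needs at least one level")
        for lat in self.levels:
            if lat.domain_shape != self.domain_shape:
                raise ValueError(
                    f"level {lat.level} domain {lat.domain_shape} differs from "
                    f"deformation domain {self.domain_shape}"
                )
        for coarse, fine in zip(self.levels, self.levels[1:]):
            for cs, fs in zip(coarse.spacing, fine.spacing):
                if abs(fs - cs / 2.0) > _HALVING_RTOL * cs:
                    raise ValueError(
                        f"spacing must halve per level, got {cs} -> {fs}"
                    )

    @classmethod
    def initial(
        cls, domain_shape: Sequence[int], spacing: float | Sequence[float]
    ) -> "MultilevelDeformation":
        """Single-level identity deformation at the given initial spacing."""
        lat = create_lattice(domain_shape, spacing, level=1)
        return cls(levels=(lat,), domain_shape=lat.domain_shape)

    @property
    def ndim(self) -> int:
        return len(self.domain_shape)

    @property
    def finest(self) -> ControlLattice:
        return self.levels[-1]

    def refined(self) -> "MultilevelDeformation":
        """Append a zero-initialised lattice at half the finest spacing."""
        new_spacing = tuple(s / 2.0 for s in self.finest.spacing)
        if any(s < 1.0 for s in new_spacing):
            raise ValueError(
                f"refusing to refine: halved spacing {new_spacing} is below one "
                "voxel, a grid finer than the image is meaningless"
            )
        lat = create_lattice(self.domain_shape, new_spacing,
                             level=self.finest.level + 1)
        return MultilevelDeformation(levels=self.levels + (lat,),
                                     domain_shape=self.domain_shape)

    def with_moved_control_point(
        self, level: int, index: Sequence[int], delta: Sequence[float]
    ) -> "MultilevelDeformation":
        """Apply :func:`mgrefine.lattice.move_control_point` to one level.

        ``level`` is 1-based.  Editing a level coarser than the finest one
        after refinement warns (see module docstring) but proceeds.
        """
        if not 1 <= level <= len(self.levels):
            raise IndexError(
                f"level {level} does not exist (deformation has "
                f"{len(self.levels)} level(s))"
            )
        if level < len(self.levels):
            warnings.warn(
                f"editing coarse level {level} after refinement to level "
                f"{len(self.levels)}; coarse grids are normally frozen",
                stacklevel=2,
            )
        new_levels = list(self.levels)
        new_levels[level - 1] = move_control_point(self.levels[level - 1],
                                                   index, delta)
        return MultilevelDeformation(levels=tuple(new_levels),
                                     domain_shape=self.domain_shape)

    def displacement_at(self, point: Sequence[float]) -> np.ndarray:
        return total_displacement(self, point)

    def dense_field(self) -> DenseField:
        return render_dense_field(self)


def refine(deformation: MultilevelDeformation) -> MultilevelDeformation:
    """Functional alias for :meth:`MultilevelDeformation.refined`."""
    return deformation.refined()


def total_displacement(
    deformation: MultilevelDeformation, point: Sequence[float]
) -> np.ndarray:
    """Sum of per-level displacements at one image point (voxels)."""
    out = np.zeros(deformation.ndim, dtype=float)
    for lat in deformation.levels:
        out += evaluate_level_displacement(lat, point)
    return out


def _axis_weight_matrix(
    coords: np.ndarray, spacing: float, grid_size: int
) -> np.ndarray:
    """Dense (n_points, grid_size) matrix of cubic weights along one axis.

    Row p scatters the four basis weights of coordinate p onto the storage
    columns floor(x/spacing) .. +3; the separable dense render contracts
    these per-axis matrices against the control grid.
    """
    lat = np.asarray(coords, dtype=float) / spacing
    base = np.floor(lat).astype(int)  # storage column of the anchor (i + 1)
    u = lat - base
    w = basis_weights(u)  # (n, 4)
    mat = np.zeros((lat.shape[0], grid_size), dtype=float)
    rows = np.arange(lat.shape[0])
    for l in range(4):
        mat[rows, base + l] += w[:, l]
    return mat


def displacement_on_grid(
    deformation: MultilevelDeformation,
    axis_coords: Sequence[np.ndarray],
) -> np.ndarray:
    """Displacements on the Cartesian product of per-axis coordinate vectors.

    Separable evaluation: one weight matrix per axis, contracted against the
    control grid.  Bit-compatible (to ~1e-12) with per-point evaluation via
    :func:`total_displacement`; used for dense rendering and for restricting
    work to a control point's support region.
    """
    ndim = deformation.ndim
    if len(axis_coords) != ndim:
        raise ValueError("need one coordinate vector per axis")
    for axis, (c, extent) in enumerate(zip(axis_coords, deformation.domain_shape)):
        c = np.asarray(c, dtype=float)
        if c.size and (c.min() < 0.0 or c.max() >= extent):
            raise ValueError(
                f"coordinates outside domain [0, {extent}) on axis {axis}"
            )
    out_shape = tuple(len(np.atleast_1d(c)) for c in axis_coords) + (ndim,)
    out = np.zeros(out_shape, dtype=float)
    for lat in deformation.levels:
        mats = [
            _axis_weight_matrix(np.atleast_1d(np.asarray(c, dtype=float)),
                                sp, g)
            for c, sp, g in zip(axis_coords, lat.spacing, lat.grid_shape)
        ]
        if ndim == 2:
            out += np.einsum("xi,yj,ijc->xyc", mats[0], mats[1],
                             lat.displacements, optimize=True)
        else:
            out += np.einsum("xi,yj,zk,ijkc->xyzc", mats[0], mats[1], mats[2],
                             lat.displacements, optimize=True)
    return out


def render_dense_field(deformation: MultilevelDeformation) -> DenseField:
    """Displacement at every voxel centre of the domain."""
    coords = [np.arange(n, dtype=float) for n in deformation.domain_shape]
    return DenseField(vectors=displacement_on_grid(deformation, coords))
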