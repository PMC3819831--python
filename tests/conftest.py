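"""Shared fixtures and independent oracles for the test suite.

The brute-force oracles here deliberately avoid the package's own
anchor/fraction decomposition: the weight of control point c at lattice
coordinate t is the CENTERED cardinal cubic B-spline N(t - c),

    N(s) = (4 - 6 s^2 + 3 |s|^3) / 6   for |s| <= 1
    N(s) = (2 - |s|)^3 / 6             for 1 < |s| <= 2
    N(s) = 0                            otherwise,

summed over ALL control points of the lattice, so agreement with the
package is a genuine cross-check of the tensor-product evaluation.
"""

import numpy as np
import pytest

from mgrefine import ControlLattice, MultilevelDeformation, create_lattice


def centered_cubic(s: float) -> float:
    s = abs(float(s))
    if s <= 1.0:
        return (4.0 - 6.0 * s**2 + 3.0 * s**3) / 6.0
    if s <= 2.0:
        return (2.0 - s) ** 3 / 6.0
    return 0.0


def brute_force_displacement(lattice: ControlLattice, point) -> np.ndarray:
    """All-control-points summation with independently coded weights."""
    ndim = lattice.ndim
    out = np.zeros(ndim)
    lat_coords = [p / sp for p, sp in zip(point, lattice.spacing)]
    for storage in np.ndindex(lattice.grid_shape):
        weight = 1.0
        for axis in range(ndim):
            conceptual = storage[axis] - 1
            weight *= centered_cubic(lat_coords[axis] - conceptual)
            if weight == 0.0:
                break
        if weight != 0.0:
            out += weight * lattice.displacements[storage]
    return out


def random_lattice(rng: np.random.Generator, ndim: int) -> ControlLattice:
    """Small random lattice (<= 8 control points per axis)."""
    shape = tuple(int(rng.integers(8, 24)) for _ in range(ndim))
    spacing = tuple(float(rng.uniform(4.0, 10.0)) for _ in range(ndim))
    lat = create_lattice(shape, spacing)
    disp = rng.uniform(-3.0, 3.0, size=lat.displacements.shape)
    return ControlLattice(
        level=1, spacing=lat.spacing, displacements=disp, domain_shape=shape
    )


def random_deformation(
    rng: np.random.Generator,
    domain_shape,
    spacing,
    n_levels: int = 1,
    magnitude: float = 2.0,
) -> MultilevelDeformation:
    d = MultilevelDeformation.initial(domain_shape, spacing)
    for _ in range(n_levels - 1):
        d = d.refined()
    levels = []
    for lat in d.levels:
        disp = rng.uniform(-magnitude, magnitude, size=lat.displacements.shape)
        levels.append(
            ControlLattice(
                level=lat.level,
                spacing=lat.spacing,
                displacements=disp,
                domain_shape=lat.domain_shape,
            )
        )
    return MultilevelDeformation(levels=tuple(levels), domain_shape=d.domain_shape)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
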