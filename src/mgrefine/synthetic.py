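"""Phantom image pairs with known ground-truth multilevel deformations.

Clinical refinement sessions start from a reference scan and a coarsely
registered transformed scan.  This module builds the test-bench analogue:
a structured phantom (smooth background plus ellipsoidal "organs" with
distinct intensities and sharp, partial-volume-softened boundaries) and a
seeded ground-truth deformation, so that replay and SSD-guided revision can
be measured against a known answer without any patient data.

The truth deformation pins the three outermost control layers per side to
zero.  At a lattice-integer border voxel the cubic support reduces to three
control points, so this keeps the image border exactly fixed, the warp
overlap mask full, and SSD comparisons clean — a deliberate idealisation of
clinical reality that isolates the algorithmic behaviour under test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .deformation import (
    MultilevelDeformation,
    displacement_on_grid,
    render_dense_field,
)
from .lattice import as_spacing, create_lattice, ControlLattice, expected_grid_shape
from .session import RevisionEvent, RevisionSession
from .warping import ScalarImage, warp_image

__all__ = [
    "SyntheticCase",
    "generate_phantom",
    "generate_truth_deformation",
    "make_case",
    "ground_truth_session",
]

BACKGROUND_RANGE = (20.0, 80.0)
BLOB_INTENSITY_RANGE = (120.0, 255.0)
EDGE_SIGMA = 1.0  # voxels of partial-volume rolloff on blob boundaries
PINNED_LAYERS = 3  # zeroed control layers per side of the truth lattice


@dataclass(frozen=True)
class SyntheticCase:
    """Reference/transformed pair linked by a known deformation."""

    reference: ScalarImage
    transformed: ScalarImage
    truth: MultilevelDeformation
    valid_mask: np.ndarray
    seed: int


def generate_phantom(
    shape: Sequence[int], n_blobs: int = 6, seed: int = 0
) -> ScalarImage:
    """Smooth background plus ellipsoidal structures, intensities in [0, 255].

    The blobs provide the distinctive edges and salient objects that visual
    revision keys on; a 1-voxel Gaussian rolloff emulates partial-volume
    blur at acquisition while leaving the boundaries sharp at the scale of
    the deformations used.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) not in (2, 3):
        raise ValueError(f"phantom must be 2-D or 3-D, got shape {shape}")
    if any(s < 32 for s in shape):
        raise ValueError(f"phantom extents must all be >= 32, got {shape}")
    if n_blobs < 1:
        raise ValueError(f"need at least one blob, got {n_blobs}")
    rng = np.random.default_rng(seed)

    # background: low-frequency noise, rescaled to a dim band
    noise = rng.standard_normal(shape)
    bg = ndimage.gaussian_filter(noise, sigma=[s / 8.0 for s in shape])
    lo, hi = BACKGROUND_RANGE
    span = bg.max() - bg.min()
    if span > 0:
        bg = lo + (bg - bg.min()) / span * (hi - lo)
    else:  # pragma: no cover - degenerate RNG draw
        bg = np.full(shape, (lo + hi) / 2.0)

    img = bg
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    intensities = np.linspace(*BLOB_INTENSITY_RANGE, n_blobs)
    rng.shuffle(intensities)
    for b in range(n_blobs):
        center = [rng.uniform(0.25 * s, 0.75 * s) for s in shape]
        radii = [rng.uniform(0.05 * s, 0.12 * s) for s in shape]
        r2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
        img = np.where(r2 <= 1.0, intensities[b], img)
    img = ndimage.gaussian_filter(img, sigma=EDGE_SIGMA)
    return ScalarImage(data=np.clip(img, 0.0, 255.0))


def generate_truth_deformation(
    shape: Sequence[int],
    spacing: float | Sequence[float],
    max_magnitude: float,
    seed: int = 0,
    n_levels: int = 1,
) -> MultilevelDeformation:
    """Seeded random deformation with border control layers pinned to zero.

    Control displacements are uniform in [-max_magnitude, +max_magnitude]
    per axis.  ``max_magnitude`` must stay below half the control spacing —
    beyond that the warp risks folding and the case stops being a clean
    recovery target.  With two levels the magnitude budget is split so the
    total still respects the bound of the finer spacing.
    """
    shape = tuple(int(s) for s in shape)
    sp = as_spacing(spacing, len(shape))
    if max_magnitude < 0:
        raise ValueError(f"max_magnitude must be >= 0, got {max_magnitude}")
    if n_levels not in (1, 2):
        raise ValueError("truth deformations use 1 or 2 levels")
    finest = min(sp) / (2 ** (n_levels - 1))
    if max_magnitude >= finest / 2.0:
        raise ValueError(
            f"max_magnitude {max_magnitude} must be < half the finest control "
            f"spacing ({finest / 2.0}) to avoid folding"
        )
    rng = np.random.default_rng(seed)
    levels = []
    level_mag = max_magnitude / n_levels
    cur_spacing = sp
    for level in range(1, n_levels + 1):
        lat = create_lattice(shape, cur_spacing, level=level)
        disp = rng.uniform(-level_mag, level_mag, size=lat.displacements.shape)
        for axis in range(len(shape)):
            sl = [slice(None)] * (len(shape) + 1)
            sl[axis] = slice(0, PINNED_LAYERS)
            disp[tuple(sl)] = 0.0
            sl[axis] = slice(-PINNED_LAYERS, None)
            disp[tuple(sl)] = 0.0
        levels.append(
            ControlLattice(level=level, spacing=cur_spacing,
                           displacements=disp, domain_shape=shape)
        )
        cur_spacing = tuple(s / 2.0 for s in cur_spacing)
    return MultilevelDeformation(levels=tuple(levels), domain_shape=shape)


def make_case(
    shape: Sequence[int],
    spacing: float | Sequence[float] = 16.0,
    max_magnitude: float = 4.0,
    seed: int = 0,
    n_blobs: int = 6,
    n_levels: int = 1,
    interpolation: str = "linear",
) -> SyntheticCase:
    """Reference phantom, ground-truth deformation, and the warped pair."""
    root = np.random.SeedSequence(seed)
    phantom_seed, truth_seed = (int(s) % (2**31) for s in
                                root.generate_state(2, dtype=np.uint64))
    reference = generate_phantom(shape, n_blobs=n_blobs, seed=phantom_seed)
    truth = generate_truth_deformation(
        shape, spacing, max_magnitude, seed=truth_seed, n_levels=n_levels
    )
    transformed, valid = warp_image(reference, truth, interpolation=interpolation)
    return SyntheticCase(
        reference=reference,
        transformed=transformed,
        truth=truth,
        valid_mask=valid,
        seed=int(seed),
    )


def _inverse_field(truth: MultilevelDeformation, iterations: int = 10) -> np.ndarray:
    """Dense inverse displacement: Dinv(x) = -T(x + Dinv(x)), by fixed point.

    Replay warps the TRANSFORMED image, so undoing a known forward warp T
    needs the inverse displacement, not just -T: the first-order guess
    -T leaves the second-order residual T(x - T(x)) - T(x).  The fixed
    point converges fast because the cases generated here keep |T| well
    below the control spacing.
    """
    from scipy import ndimage

    shape = truth.domain_shape
    fwd = render_dense_field(truth).vectors
    grid = np.stack(
        np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij"),
        axis=-1,
    )
    inv = -fwd
    for _ in range(iterations):
        sample = grid + inv
        for axis, extent in enumerate(shape):
            np.clip(sample[..., axis], 0.0, extent - 1.0, out=sample[..., axis])
        coords = np.moveaxis(sample, -1, 0)
        fwd_at = np.stack(
            [
                ndimage.map_coordinates(fwd[..., c], coords, order=1, mode="nearest")
                for c in range(len(shape))
            ],
            axis=-1,
        )
        inv = -fwd_at
    return inv


def _fit_lattice_coefficients(
    field: np.ndarray, domain_shape: tuple[int, ...], spacing: tuple[float, ...]
) -> np.ndarray:
    """Least-squares control displacements reproducing a dense field.

    The dense render is separable (per-axis weight matrices W contracted
    against the control grid), so the normal equations factor per axis:
    solve (W_x^T W_x) ... applied along each grid axis of W^T field.
    """
    from .deformation import _axis_weight_matrix

    ndim = len(domain_shape)
    grid = expected_grid_shape(domain_shape, spacing)
    mats = [
        _axis_weight_matrix(np.arange(n, dtype=float), sp, g)
        for n, sp, g in zip(domain_shape, spacing, grid)
    ]
    if ndim == 2:
        b = np.einsum("xi,yj,xyc->ijc", mats[0], mats[1], field, optimize=True)
    else:
        b = np.einsum("xi,yj,zk,xyzc->ijkc", mats[0], mats[1], mats[2], field,
                      optimize=True)
    coeffs = b
    for axis, m in enumerate(mats):
        a = m.T @ m
        moved = np.moveaxis(coeffs, axis, 0)
        flat = moved.reshape(moved.shape[0], -1)
        solved = np.linalg.solve(a, flat).reshape(moved.shape)
        coeffs = np.moveaxis(solved, 0, axis)
    return coeffs


def ground_truth_session(
    case: SyntheticCase, interpolation: str = "linear"
) -> RevisionSession:
    """Session whose drags undo the case's deformation.

    The replayed deformation must be the INVERSE of the truth (replay
    re-warps the transformed image), so the session is built by inverting
    the truth field by fixed point and least-squares fitting each level's
    control displacements to it — coarse level to the inverse, finer level
    to the remaining residual, with a refine event in between.  Drags carry
    content motions, i.e. the negated stored values (content in the
    transformed image sits at roughly -truth and must move back by +truth).
    """
    events: list[RevisionEvent] = []
    shape = case.truth.domain_shape
    target = _inverse_field(case.truth)
    for i, lat in enumerate(case.truth.levels, start=1):
        if i > 1:
            events.append(RevisionEvent(kind="refine"))
        coeffs = _fit_lattice_coefficients(target, shape, lat.spacing)
        fitted = ControlLattice(
            level=i, spacing=lat.spacing, displacements=coeffs, domain_shape=shape
        )
        level_field = displacement_on_grid(
            MultilevelDeformation(levels=(fitted,), domain_shape=shape),
            [np.arange(n, dtype=float) for n in shape],
        )
        target = target - level_field
        for index in np.ndindex(fitted.grid_shape):
            vec = coeffs[index]
            if np.any(vec != 0.0):
                events.append(
                    RevisionEvent(
                        kind="drag", level=i, index=index,
                        content_motion=tuple(float(-v) for v in vec),
                    )
                )
    return RevisionSession(
        initial_spacing=case.truth.levels[0].spacing,
        events=events,
        metadata={"interpolation": interpolation, "source": "ground-truth"},
    )
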