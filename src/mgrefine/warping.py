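"""Image container and backward warping by a multilevel deformation.

Warping is backward (pull-back) resampling: each output voxel x samples the
input image at x + T_local(x).  Backward mapping leaves no holes; its one
quirk is that adding displacement d at a control point moves image CONTENT
by approximately -d, which is why the session layer records drags as
desired content motion and negates them before touching the lattice.

Samples falling outside the closed input grid bounds are filled with 0 and
flagged invalid in the returned mask; the mask is the overlap region that
the SSD metric restricts to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .deformation import MultilevelDeformation, render_dense_field

__all__ = ["ScalarImage", "warp_image", "INTERPOLATION_ORDERS"]

INTERPOLATION_ORDERS = {"nearest": 0, "linear": 1, "cubic": 3}


@dataclass(frozen=True)
class ScalarImage:
    """n-D (2 or 3) grid of intensities with voxel spacing and origin.

    ``voxel_spacing`` is physical (e.g. mm per voxel) and is carried through
    I/O untouched; all deformation arithmetic happens in voxel units.
    """

    data: np.ndarray
    voxel_spacing: tuple[float, ...] = ()
    origin: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim not in (2, 3):
            raise ValueError(f"images must be 2-D or 3-D, got {arr.ndim}-D")
        if not np.all(np.isfinite(arr)):
            raise ValueError("image intensities must be finite")
        object.__setattr__(self, "data", arr)
        spacing = self.voxel_spacing or (1.0,) * arr.ndim
        origin = self.origin or (0.0,) * arr.ndim
        if len(spacing) != arr.ndim or len(origin) != arr.ndim:
            raise ValueError("voxel_spacing/origin dimensionality mismatch")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"voxel spacing must be positive, got {spacing}")
        object.__setattr__(self, "voxel_spacing", tuple(float(s) for s in spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in origin))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim


def as_array(image: "ScalarImage | np.ndarray") -> np.ndarray:
    """Intensity array of a ScalarImage, or the array itself."""
    if isinstance(image, ScalarImage):
        return image.data
    return np.asarray(image, dtype=float)


def warp_image(
    image: ScalarImage,
    deformation: MultilevelDeformation,
    interpolation: str = "linear",
    input_mask: np.ndarray | None = None,
) -> tuple[ScalarImage, np.ndarray]:
    """Backward-warp an image by a deformation.

    Returns the warped image and a boolean validity mask: a voxel is valid
    iff its sample coordinate x + T(x) lies inside the closed input grid
    bounds [0, extent-1] on every axis.  Invalid voxels are filled with 0.
    A zero deformation with nearest or linear interpolation reproduces the
    input bit-identically.

    ``input_mask`` marks which voxels of the INPUT image carry real data
    (e.g. the overlap mask of an upstream warp, whose outside is fill, not
    anatomy).  Output voxels whose sample touches unmasked input are then
    flagged invalid too, so SSD over the returned mask honours the overlap
    of both images.
    """
    if interpolation not in INTERPOLATION_ORDERS:
        raise ValueError(
            f"unknown interpolation {interpolation!r}; "
            f"choose from {sorted(INTERPOLATION_ORDERS)}"
        )
    if image.shape != deformation.domain_shape:
        raise ValueError(
            f"image shape {image.shape} does not match deformation domain "
            f"{deformation.domain_shape}"
        )
    field_vec = render_dense_field(deformation).vectors
    grid = np.stack(
        np.meshgrid(*[np.arange(n, dtype=float) for n in image.shape],
                    indexing="ij"),
        axis=-1,
    )
    sample = grid + field_vec
    mask = np.ones(image.shape, dtype=bool)
    for axis, extent in enumerate(image.shape):
        c = sample[..., axis]
        mask &= (c >= 0.0) & (c <= extent - 1.0)
    coords = np.moveaxis(sample, -1, 0)
    warped = ndimage.map_coordinates(
        image.data,
        coords,
        order=INTERPOLATION_ORDERS[interpolation],
        mode="constant",
        cval=0.0,
    )
    if input_mask is not None:
        input_mask = np.asarray(input_mask, dtype=bool)
        if input_mask.shape != image.shape:
            raise ValueError(
                f"input_mask shape {input_mask.shape} does not match image "
                f"{image.shape}"
            )
        covered = ndimage.map_coordinates(
            input_mask.astype(float), coords, order=1, mode="constant", cval=0.0
        )
        mask &= covered >= 1.0 - 1e-9
    warped[~mask] = 0.0
    return (
        ScalarImage(data=warped, voxel_spacing=image.voxel_spacing,
                    origin=image.origin),
        mask,
    )
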