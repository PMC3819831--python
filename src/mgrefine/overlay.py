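"""RGB misregistration display and the SSD metric that supervises revision.

RGB model: the reference image occupies the green band, the transformed
image the red and blue bands.  Where the two (jointly rescaled) images
agree the three bands are equal and the pixel is gray; where the reference
is brighter the pixel trends green, where the transformed image is brighter
it trends purple.  Gray therefore *means* registered, and the colored
residue is exactly the misregistration a user should go after.

SSD is the mean squared intensity difference over the voxels in a mask,

    SSD = (1/n) * sum_mask (I_ref - I_trans)^2,

with n the number of masked voxels.  The mask defaults to everything but in
practice is the warp overlap (validity mask) intersected with an optional
ROI: out-of-overlap voxels carry the fill value, not anatomy, and must not
count.  The variance of the squared differences is exposed alongside the
mean as an auxiliary spread statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .warping import ScalarImage, as_array

__all__ = [
    "RgbOverlay",
    "joint_rescale",
    "rgb_overlay",
    "ssd",
    "ssd_stats",
    "misregistration_mask",
]

DISPLAY_MAX = 255.0


@dataclass(frozen=True)
class RgbOverlay:
    """8-bit RGB fusion image; channel order (..., [R, G, B])."""

    rgb: np.ndarray

    def __post_init__(self) -> None:
        if self.rgb.shape[-1] != 3 or self.rgb.dtype != np.uint8:
            raise ValueError("overlay must be a uint8 array with a final RGB axis")

    @property
    def red(self) -> np.ndarray:
        return self.rgb[..., 0]

    @property
    def green(self) -> np.ndarray:
        return self.rgb[..., 1]

    @property
    def blue(self) -> np.ndarray:
        return self.rgb[..., 2]


def joint_rescale(
    reference: "ScalarImage | np.ndarray", transformed: "ScalarImage | np.ndarray"
) -> tuple[np.ndarray, np.ndarray]:
    """Min-max rescale BOTH images to [0, 255] on a shared scale.

    The shared scale is what makes gray meaningful: equal raw intensities
    map to equal display values, so R=G=B iff the images agree.
    """
    a = as_array(reference)
    b = as_array(transformed)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: reference {a.shape} vs transformed {b.shape}")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi == lo:
        mid = np.full(a.shape, DISPLAY_MAX / 2.0)
        return mid, mid.copy()
    scale = DISPLAY_MAX / (hi - lo)
    return (a - lo) * scale, (b - lo) * scale


def rgb_overlay(
    reference: "ScalarImage | np.ndarray", transformed: "ScalarImage | np.ndarray"
) -> RgbOverlay:
    """Fuse reference (green band) and transformed (red + blue bands)."""
    g, rb = joint_rescale(reference, transformed)
    rgb = np.stack([rb, g, rb], axis=-1)
    return RgbOverlay(rgb=np.clip(np.rint(rgb), 0, 255).astype(np.uint8))


def _masked_sq_diff(
    reference: "ScalarImage | np.ndarray",
    transformed: "ScalarImage | np.ndarray",
    mask: np.ndarray | None,
) -> np.ndarray:
    a = as_array(reference)
    b = as_array(transformed)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: reference {a.shape} vs transformed {b.shape}")
    if mask is None:
        mask = np.ones(a.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != a.shape:
        raise ValueError(f"mask shape {mask.shape} does not match images {a.shape}")
    if not mask.any():
        raise ValueError("SSD is undefined on an empty mask (no overlap/ROI voxels)")
    d = a[mask] - b[mask]
    return d * d

def ssd(
    reference: "ScalarImage | np.ndarray",
    transformed: "ScalarImage | np.ndarray",
    mask: np.ndarray | None = None,
) -> float:
    """Mean squared intensity difference over the masked voxels."""
    return float(np.mean(_masked_sq_diff(reference, transformed, mask)))


def ssd_stats(
    reference: "ScalarImage | np.ndarray",
    transformed: "ScalarImage | np.ndarray",
    mask: np.ndarray | None = None,
) -> tuple[float, float]:
    """(mean, variance) of the squared differences over the mask."""
    sq = _masked_sq_diff(reference, transformed, mask)
    return float(np.mean(sq)), float(np.var(sq))


def misregistration_mask(
    reference: "ScalarImage | np.ndarray",
    transformed: "ScalarImage | np.ndarray",
    threshold: float,
) -> np.ndarray:
    """Boolean mask of display-scale disagreement above a threshold.

    The machine stand-in for "the pixels that appear green or purple":
    true where the jointly rescaled images differ by more than ``threshold``
    display units (0..255).
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    g, rb = joint_rescale(reference, transformed)
    return np.abs(g - rb) > threshold
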