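"""Readers/writers for the image formats touched, and unit conversion.

Grayscale 2-D images travel as PNG (8/16-bit) or TIFF; 3-D volumes as
NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd).  Dense displacement fields
are written as multi-channel TIFF (2-D) or multi-component NIfTI (3-D)
with the component order equal to the image axis order.  RGB overlays are
8-bit PNG, or a per-slice PNG series for volumes.

Arrays are kept in (x, y[, z]) axis order matching the NIfTI convention;
MetaImage files (stored z-fastest-last by SimpleITK) are transposed on the
way in and out.  Displacements everywhere in the package are in voxels;
:func:`voxels_to_mm` / :func:`mm_to_voxels` convert to and from physical
units via the image's voxel spacing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .deformation import DenseField
from .overlay import RgbOverlay
from .warping import ScalarImage, INTERPOLATION_ORDERS

__all__ = [
    "RunConfig",
    "read_image",
    "write_image",
    "read_dense_field",
    "voxels_to_mm",
    "mm_to_voxels",
]

IMAGE_EXTENSIONS = (".png", ".tif", ".tiff", ".nii", ".nii.gz", ".mha", ".mhd")


@dataclass(frozen=True)
class RunConfig:
    """Validated run-wide options shared by the CLI subcommands."""

    interpolation: str = "linear"
    initial_spacing: float = 16.0
    display_threshold: float = 10.0
    output_dir: str = "."
    verbosity: int = 0

    def __post_init__(self) -> None:
        if self.interpolation not in INTERPOLATION_ORDERS:
            raise ValueError(
                f"config error: interpolation={self.interpolation!r} is not one "
                f"of {sorted(INTERPOLATION_ORDERS)}"
            )
        if self.initial_spacing <= 0:
            raise ValueError(
                f"config error: initial_spacing={self.initial_spacing} must be > 0"
            )
        if self.display_threshold < 0:
            raise ValueError(
                f"config error: display_threshold={self.display_threshold} "
                "must be >= 0"
            )
        if self.verbosity < 0:
            raise ValueError(f"config error: verbosity={self.verbosity} must be >= 0")


def _extension(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def read_image(path: "str | Path") -> ScalarImage:
    """Load a grayscale image or volume; spacing/origin from header if present."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    ext = _extension(path)
    try:
        if ext == ".png":
            import imageio.v3 as iio

            arr = np.asarray(iio.imread(path))
            if arr.ndim != 2:
                raise ValueError(
                    "PNG input must be single-channel grayscale; convert color "
                    "images to grayscale first"
                )
            return ScalarImage(data=arr.astype(float))
        if ext in (".tif", ".tiff"):
            import tifffile

            arr = np.asarray(tifffile.imread(path))
            if arr.ndim != 2:
                raise ValueError(
                    "TIFF image input must be a single 2-D grayscale plane"
                )
            return ScalarImage(data=arr.astype(float))
        if ext in (".nii", ".nii.gz"):
            import nibabel as nib

            img = nib.load(str(path))
            arr = np.asarray(img.get_fdata(), dtype=float)
            zooms = img.header.get_zooms()[: arr.ndim]
            return ScalarImage(data=arr, voxel_spacing=tuple(float(z) for z in zooms))
        if ext in (".mha", ".mhd"):
            import SimpleITK as sitk

            img = sitk.ReadImage(str(path))
            arr = sitk.GetArrayFromImage(img).T.astype(float)
            return ScalarImage(
                data=arr,
                voxel_spacing=tuple(float(s) for s in img.GetSpacing()),
                origin=tuple(float(o) for o in img.GetOrigin()),
            )
    except ValueError:
        raise
    except Exception as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc
    raise IOError(
        f"unknown image extension {ext!r} for {path}; "
        f"supported: {', '.join(IMAGE_EXTENSIONS)}"
    )


def _write_scalar(image: ScalarImage, path: Path) -> None:
    ext = _extension(path)
    data = image.data
    if ext == ".png":
        import imageio.v3 as iio

        if data.min() < 0 or data.max() > 65535:
            raise IOError(
                f"cannot write {path}: PNG needs intensities in [0, 65535]"
            )
        dtype = np.uint8 if data.max() <= 255 else np.uint16
        iio.imwrite(path, np.rint(data).astype(dtype))
    elif ext in (".tif", ".tiff"):
        import tifffile

        integral = np.all(np.rint(data) == data)
        if integral and data.min() >= 0 and data.max() <= 65535:
            tifffile.imwrite(path, data.astype(np.uint16))
        else:
            tifffile.imwrite(path, data.astype(np.float32))
    elif ext in (".nii", ".nii.gz"):
        import nibabel as nib

        affine = np.diag(list(image.voxel_spacing) + [1.0])
        nib.save(nib.Nifti1Image(data.astype(np.float32), affine), str(path))
    elif ext in (".mha", ".mhd"):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(data.T)
        img.SetSpacing(tuple(image.voxel_spacing))
        img.SetOrigin(tuple(image.origin))
        sitk.WriteImage(img, str(path))
    else:
        raise IOError(f"unknown image extension {ext!r} for {path}")


def _write_overlay(overlay: RgbOverlay, path: Path) -> None:
    import imageio.v3 as iio

    ext = _extension(path)
    if ext != ".png":
        raise IOError(f"RGB overlays are written as PNG, not {ext!r} ({path})")
    if overlay.rgb.ndim == 3:  # 2-D image + channel axis
        iio.imwrite(path, overlay.rgb)
    else:  # volume: one PNG per slice along the last spatial axis
        stem = path.with_suffix("")
        for k in range(overlay.rgb.shape[2]):
            iio.imwrite(Path(f"{stem}_{k:04d}.png"), overlay.rgb[:, :, k, :])


def _write_dense_field(field: DenseField, path: Path) -> None:
    ext = _extension(path)
    vec = field.vectors
    ndim = vec.shape[-1]
    if ndim == 2 and ext in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, vec.astype(np.float32))
    elif ndim == 3 and ext in (".nii", ".nii.gz"):
        import nibabel as nib

        nib.save(nib.Nifti1Image(vec.astype(np.float32), np.eye(4)), str(path))
    else:
        raise IOError(
            f"dense {ndim}-D fields are written as "
            f"{'multi-channel TIFF' if ndim == 2 else 'multi-component NIfTI'}, "
            f"not {ext!r} ({path})"
        )


def write_image(
    payload: "ScalarImage | RgbOverlay | DenseField", path: "str | Path"
) -> None:
    """Write a scalar image, RGB overlay, or dense field; format by extension."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(payload, ScalarImage):
        _write_scalar(payload, path)
    elif isinstance(payload, RgbOverlay):
        _write_overlay(payload, path)
    elif isinstance(payload, DenseField):
        _write_dense_field(payload, path)
    else:
        raise TypeError(f"cannot write object of type {type(payload).__name__}")


def read_dense_field(path: "str | Path") -> DenseField:
    """Read a dense displacement field written by :func:`write_image`."""
    path = Path(path)
    ext = _extension(path)
    try:
        if ext in (".tif", ".tiff"):
            import tifffile

            vec = np.asarray(tifffile.imread(path), dtype=float)
        elif ext in (".nii", ".nii.gz"):
            import nibabel as nib

            vec = np.asarray(nib.load(str(path)).get_fdata(), dtype=float)
        else:
            raise IOError(f"unknown dense-field extension {ext!r} for {path}")
    except IOError:
        raise
    except Exception as exc:
        raise IOError(f"cannot read dense field {path}: {exc}") from exc
    return DenseField(vectors=vec)


def voxels_to_mm(displacement: np.ndarray, image: ScalarImage) -> np.ndarray:
    """Convert voxel-unit displacement vectors to millimetres."""
    return np.asarray(displacement, dtype=float) * np.asarray(image.voxel_spacing)


def mm_to_voxels(displacement: np.ndarray, image: ScalarImage) -> np.ndarray:
    """Convert millimetre displacement vectors to voxel units."""
    return np.asarray(displacement, dtype=float) / np.asarray(image.voxel_spacing)
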