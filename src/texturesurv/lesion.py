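"""The lesion-image container and its on-disk formats.

A lesion is a 2-D grid of stored CT intensities together with a boolean
region-of-interest (ROI) mask of the same shape.  Stored values follow the
common offset convention ``stored = HU + 1024`` so that the whole clinically
relevant range is non-negative and fits a 16-bit unsigned image (water = 1024,
air = 24, soft tissue ~ 1050-1120).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

HU_OFFSET = 1024


@dataclass
class LesionImage:
    """A 2-D lesion image plus ROI mask.

    Parameters
    ----------
    pixels
        2-D array of stored intensities (``HU + 1024``), non-negative.
    mask
        Boolean array of the same shape; True marks in-ROI pixels.
    pixel_spacing
        In-plane pixel size in mm (informational only).
    """

    pixels: np.ndarray
    mask: np.ndarray
    pixel_spacing: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if self.mask.shape != self.pixels.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != pixels shape {self.pixels.shape}"
            )
        if not self.mask.any():
            raise ValueError("mask must contain at least one pixel")
        if np.min(self.pixels) < 0:
            raise ValueError("stored intensities must be non-negative")

    @property
    def hu(self) -> np.ndarray:
        """Pixel values on the Hounsfield scale (stored - 1024)."""
        return np.asarray(self.pixels, dtype=float) - HU_OFFSET

    @property
    def roi_size(self) -> int:
        """Number of pixels in the ROI mask."""
        return int(self.mask.sum())

    def in_mask_values(self) -> np.ndarray:
        """Stored intensities of the in-ROI pixels, as a flat float array."""
        return np.asarray(self.pixels, dtype=float)[self.mask]


def write_lesion_png(lesion: LesionImage, image_path: str | Path, mask_path: str | Path) -> None:
    """Write a lesion as a 16-bit grayscale PNG plus an 8-bit mask PNG."""
    import imageio.v3 as iio

    px = np.asarray(lesion.pixels)
    if px.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("stored intensities exceed the 16-bit range")
    iio.imwrite(Path(image_path), px.astype(np.uint16))
    iio.imwrite(Path(mask_path), (lesion.mask.astype(np.uint8) * 255))


def read_lesion_png(image_path: str | Path, mask_path: str | Path,
                    pixel_spacing: float | None = None) -> LesionImage:
    """Read a lesion from a 16-bit grayscale PNG and its mask PNG."""
    import imageio.v3 as iio

    px = np.asarray(iio.imread(Path(image_path)))
    mk = np.asarray(iio.imread(Path(mask_path))) > 0
    return LesionImage(pixels=px, mask=mk, pixel_spacing=pixel_spacing)


def write_lesion_stack_nifti(lesions: list[LesionImage], image_path: str | Path,
                             mask_path: str | Path) -> None:
    """Write a cohort of same-shape lesions as a single NIfTI stack (plus masks)."""
    import nibabel as nib

    shapes = {l.pixels.shape for l in lesions}
    if len(shapes) != 1:
        raise ValueError("all lesions must share the same shape for a NIfTI stack")
    img = np.stack([np.asarray(l.pixels, dtype=np.int32) for l in lesions], axis=-1)
    msk = np.stack([l.mask.astype(np.uint8) for l in lesions], axis=-1)
    nib.save(nib.Nifti1Image(img, affine=np.eye(4)), str(image_path))
    nib.save(nib.Nifti1Image(msk, affine=np.eye(4)), str(mask_path))


def read_lesion_stack_nifti(image_path: str | Path, mask_path: str | Path) -> list[LesionImage]:
    """Read a cohort written by :func:`write_lesion_stack_nifti`."""
    import nibabel as nib

    img = np.asarray(nib.load(str(image_path)).dataobj)
    msk = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    return [LesionImage(pixels=img[..., k], mask=msk[..., k]) for k in range(img.shape[-1])]
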