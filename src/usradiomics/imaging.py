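"""ROI handling for B-mode ultrasound images.

Images arrive as 8-bit grayscale or RGB rasters together with a binary
mask delineating the tumor.  The unit everything downstream works on is
the :class:`RoiPatch`: the masked pixels of the tumor, cropped to the
mask's bounding box, z-normalized within the ROI so that texture is
comparable across patients and scanners.  Before co-occurrence /
run-length matrices are built, intensities are quantized to a small
number of gray levels (:class:`QuantizedPatch`).

Conventions: row-major arrays, origin top-left, 0-based indices; masks
are 0/1 rasters; bounding boxes are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "GrayImage",
    "RoiMask",
    "RoiPatch",
    "QuantizedPatch",
    "to_grayscale",
    "read_image",
    "read_mask",
    "extract_roi",
    "normalize_patch",
    "quantize",
    "load_manifest",
]

#: ITU-R BT.601 luma weights ("eliminate hue and saturation, retain luminance").
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: Sentinel bin index for pixels outside the ROI in a QuantizedPatch.
MASKED_OUT = 0


class FormatError(ValueError):
    """Raised for unsupported image formats (bit depth / channel count)."""


@dataclass(frozen=True)
class GrayImage:
    """Single-channel 8-bit intensity image."""

    pixels: np.ndarray  # 2-D float array with values in [0, 255]

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=float)
        if p.ndim != 2 or p.shape[0] < 2 or p.shape[1] < 2:
            raise FormatError(f"grayscale image must be 2-D and >= 2x2, got shape {p.shape}")
        if not np.all(np.isfinite(p)):
            raise FormatError("non-finite pixel values")
        if p.min() < 0 or p.max() > 255:
            raise FormatError("pixel values outside [0, 255]")
        object.__setattr__(self, "pixels", p)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class RoiMask:
    """Binary tumor mask; one 4-connected component, >= 16 pixels."""

    pixels: np.ndarray  # 2-D bool array

    def __post_init__(self) -> None:
        m = np.asarray(self.pixels).astype(bool)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        if m.sum() < 16:
            raise ValueError(f"mask has {int(m.sum())} foreground pixels; need >= 16")
        from scipy import ndimage

        _, n_comp = ndimage.label(m, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
        if n_comp != 1:
            raise ValueError(f"mask must have exactly one 4-connected component, found {n_comp}")
        object.__setattr__(self, "pixels", m)

    @property
    def area(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class RoiPatch:
    """Tumor intensities cropped to the mask bounding box.

    Pixels where ``mask`` is False never enter any statistic.  After
    :func:`normalize_patch`, masked pixels have mean 0 and SD 1 (or are
    all zero in the degenerate constant case, with ``degenerate`` set).
    """

    pixels: np.ndarray
    mask: np.ndarray
    normalized: bool = False
    degenerate: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", np.asarray(self.pixels, dtype=float))
        object.__setattr__(self, "mask", np.asarray(self.mask).astype(bool))
        if self.pixels.shape != self.mask.shape:
            raise ValueError("pixels and mask shapes differ")

    @property
    def masked_values(self) -> np.ndarray:
        return self.pixels[self.mask]

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class QuantizedPatch:
    """Integer gray-level patch: masked pixels carry bins 1..levels, others 0."""

    pixels: np.ndarray  # 2-D int array; MASKED_OUT where outside ROI
    mask: np.ndarray
    levels: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", np.asarray(self.pixels, dtype=np.int64))
        object.__setattr__(self, "mask", np.asarray(self.mask).astype(bool))
        inside = self.pixels[self.mask]
        if inside.size and (inside.min() < 1 or inside.max() > self.levels):
            raise ValueError("masked bin indices must lie in 1..levels")


def to_grayscale(image: np.ndarray) -> GrayImage:
    """Convert an 8-bit raster (HxW or HxWx3) to a GrayImage.

    RGB is collapsed with the BT.601 luma weights, rounding to the
    nearest integer (ties to even).  Single-channel input passes
    through unchanged.
    """
    arr = np.asarray(image)
    if arr.dtype not in (np.uint8, np.int64, np.int32, np.int16, np.uint16, np.float64, np.float32):
        raise FormatError(f"unsupported dtype {arr.dtype}")
    if arr.ndim == 2:
        return GrayImage(arr.astype(float))
    if arr.ndim == 3 and arr.shape[2] == 3:
        lum = np.rint(arr.astype(float) @ LUMA_WEIGHTS)
        return GrayImage(lum)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        lum = np.rint(arr[..., :3].astype(float) @ LUMA_WEIGHTS)
        return GrayImage(lum)
    raise FormatError(f"unsupported channel layout, shape {arr.shape}")


def read_image(path: str | Path) -> GrayImage:
    """Read a PNG/JPEG image (8-bit gray or RGB) as a GrayImage."""
    with Image.open(path) as im:
        if im.mode not in ("L", "RGB", "RGBA", "P"):
            im = im.convert("RGB")
        elif im.mode == "P":
            im = im.convert("RGB")
        return to_grayscale(np.asarray(im))


def read_mask(path: str | Path) -> RoiMask:
    """Read a PNG mask; any nonzero pixel is foreground."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return RoiMask(arr > 0)


def extract_roi(image: GrayImage, mask: RoiMask) -> RoiPatch:
    """Crop the image to the tight bounding box of the mask."""
    if image.pixels.shape != mask.pixels.shape:
        raise ValueError(
            f"image shape {image.pixels.shape} != mask shape {mask.pixels.shape}"
        )
    rows = np.flatnonzero(mask.pixels.any(axis=1))
    cols = np.flatnonzero(mask.pixels.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    return RoiPatch(image.pixels[r0:r1, c0:c1], mask.pixels[r0:r1, c0:c1])


def normalize_patch(patch: RoiPatch) -> RoiPatch:
    """z-normalize intensities within the ROI: x' = (x - mu) / sigma.

    sigma is the population SD over masked pixels.  A constant patch
    (sigma = 0) maps to all zeros with the degeneracy flag raised.
    Idempotent to numerical precision.
    """
    vals = patch.masked_values
    mu = vals.mean()
    sigma = vals.std()
    out = np.zeros_like(patch.pixels)
    if sigma == 0:
        return RoiPatch(out, patch.mask, normalized=True, degenerate=True)
    out[patch.mask] = (vals - mu) / sigma
    return RoiPatch(out, patch.mask, normalized=True)


def quantize(
    patch: RoiPatch,
    levels: int = 32,
    clip: tuple[float, float] | None = (1.0, 99.0),
) -> QuantizedPatch:
    """Bin masked intensities into 1..levels equal-width gray levels.

    Intensities are first clipped to the ``clip`` percentiles of the
    masked distribution (pass None to disable), then linearly mapped so
    the clipped minimum lands in bin 1 and the maximum in bin ``levels``.
    Pixels outside the mask carry the sentinel 0 and are never counted
    by any texture-matrix builder.
    """
    if levels < 2:
        raise ValueError("need at least 2 gray levels")
    vals = patch.masked_values
    if clip is not None:
        lo, hi = np.percentile(vals, clip)
    else:
        lo, hi = vals.min(), vals.max()
    out = np.full(patch.pixels.shape, MASKED_OUT, dtype=np.int64)
    if hi <= lo:  # constant (degenerate) patch
        out[patch.mask] = 1
        return QuantizedPatch(out, patch.mask, levels)
    clipped = np.clip(vals, lo, hi)
    bins = np.floor((clipped - lo) / (hi - lo) * levels).astype(np.int64) + 1
    out[patch.mask] = np.clip(bins, 1, levels)
    return QuantizedPatch(out, patch.mask, levels)


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV.

    Required columns: patient_id, image, mask, label, cohort
    (training/validation).  Additional covariate columns (age, sex,
    tumor_size_mm, central_lnm, ...) pass through.  Image/mask paths are
    resolved relative to the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"patient_id", "image", "mask", "label", "cohort"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(
            "one representative image per patient is required; "
            f"duplicate patient_id entries: {dupes}"
        )
    base = path.parent
    for col in ("image", "mask"):
        df[col] = df[col].map(lambda p: str((base / p).resolve()) if not Path(p).is_absolute() else p)
    return df
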