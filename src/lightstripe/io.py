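"""TIFF stack I/O with pixel-size metadata.

Single-channel stacks only: 8/16-bit unsigned integer or 32-bit float, one
channel per file, planes along the first axis.  Pixel size travels in the
TIFF resolution tags (pixels per centimeter) and round-trips losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageStack", "StackFormatError", "read_stack", "write_stack"]

_SUPPORTED_DTYPES = (np.uint8, np.uint16, np.float32)


class StackFormatError(ValueError):
    """The file is not a single-channel stack this pipeline can process."""


@dataclass
class ImageStack:
    """A (z, y, x) image stack with its lateral pixel size in µm."""

    data: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise StackFormatError(
                f"expected a 2D image or 3D stack, got {self.data.ndim} dimensions"
            )
        if self.data.dtype not in _SUPPORTED_DTYPES:
            raise StackFormatError(
                f"unsupported dtype {self.data.dtype}; use uint8, uint16 or float32"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]


def _pixel_size_from_tags(page) -> float | None:
    tags = page.tags
    if "XResolution" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0:
        return None
    px_per_unit = num / den
    unit = tags["ResolutionUnit"].value if "ResolutionUnit" in tags else None
    unit = getattr(unit, "value", unit)  # enum → int
    if unit == 3:  # centimeter
        return 1e4 / px_per_unit
    if unit == 2:  # inch
        return 2.54e4 / px_per_unit
    return None


def read_stack(path: str | Path, pixel_size_um: float | None = None) -> ImageStack:
    """Read a single-channel TIFF stack.

    Pixel size comes from the file's resolution tags when present, otherwise
    from the ``pixel_size_um`` argument; with neither, this raises a
    ``StackFormatError`` naming the missing field.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        samples = page.tags.valueof("SamplesPerPixel", 1)
        if samples and samples > 1:
            raise StackFormatError(
                f"{path.name} has {samples} samples per pixel; split multi-channel "
                "images into one single-channel file per channel first"
            )
        data = tif.asarray()
        tag_px = _pixel_size_from_tags(page)

    if data.ndim == 3 and data.shape[-1] in (3, 4) and data.shape[-1] < min(data.shape[:2]):
        raise StackFormatError(
            f"{path.name} looks like a {data.shape[-1]}-channel color image; "
            "split channels into separate single-channel files first"
        )
    if data.dtype == np.int16:
        raise StackFormatError(f"{path.name}: signed 16-bit is unsupported; use uint16")
    if data.dtype == np.float64:
        raise StackFormatError(f"{path.name}: 64-bit float is unsupported; use float32")
    if data.dtype not in _SUPPORTED_DTYPES:
        raise StackFormatError(
            f"{path.name}: unsupported dtype {data.dtype}; use uint8, uint16 or float32"
        )

    px = tag_px if tag_px is not None else pixel_size_um
    if px is None:
        raise StackFormatError(
            f"{path.name} carries no resolution tags and no pixel size was "
            "configured: set pixel_size_um"
        )
    return ImageStack(data, float(px))


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack with resolution tags; lossless round trip with read_stack."""
    path = Path(path)
    # exact rational so the pixel size survives the TIFF RATIONAL tag
    frac = Fraction(1e4 / stack.pixel_size_um).limit_denominator(10**9)
    px_per_cm = (frac.numerator, frac.denominator)
    try:
        tifffile.imwrite(
            path,
            stack.data,
            resolution=(px_per_cm, px_per_cm),
            resolutionunit="CENTIMETER",
            photometric="minisblack",
        )
    except OSError as exc:
        raise OSError(f"failed writing stack to {path}: {exc}") from exc
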