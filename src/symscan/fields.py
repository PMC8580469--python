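"""Strictly positive intensity fields extracted from raster images.

The symmetry measure operates on a positive scalar function μ sampled on a
pixel grid.  This module constructs μ from 8-bit greyscale or RGB images
(luminance, or the relative-greenness channel 2g − r − b + 1 used to pull a
green specimen out of a grey background), enforces positivity with a floor,
and provides block-mean downsampling and simple thresholding.

Coordinate convention used throughout the package: pixel centres sit at
integer coordinates, x increases with column index (rightward), y increases
upward (i.e. y = (nrows − 1 − row)), angles are degrees counterclockwise.
A field's ``centre`` attribute is the (x, y) origin used by rotations and
reflections, in pixel units; it defaults to the geometric image centre.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.color import rgb2gray

__all__ = [
    "IntensityField",
    "BinaryMask",
    "load_intensity",
    "ensure_positive",
    "downsample",
    "threshold_mask",
    "DataError",
    "ModeError",
]

#: default positivity floor on the 0–255 intensity scale
DEFAULT_FLOOR = 1.0


class DataError(ValueError):
    """Raised for non-finite or otherwise unusable input data."""


class ModeError(ValueError):
    """Raised when an intensity mode is incompatible with the image."""


@dataclasses.dataclass
class IntensityField:
    """A strictly positive scalar field μ on a pixel grid.

    Parameters
    ----------
    values
        2-D array of strictly positive reals, indexed ``[row, col]``.
    pixel_size
        Physical length per pixel (default 1).
    centre
        (x, y) coordinates of the rotation/reflection origin, pixel units,
        y measured upward from the bottom row.
    provenance
        One of ``grey``, ``greenness``, ``simulation``, ``fixture``.
    """

    values: np.ndarray
    pixel_size: float = 1.0
    centre: tuple[float, float] | None = None
    provenance: str = "grey"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 2:
            raise ValueError("field must be a 2-D grid at least 2 pixels in each direction")
        if not np.all(np.isfinite(self.values)):
            raise DataError("field contains non-finite values")
        if np.any(self.values <= 0):
            raise ValueError("field values must be strictly positive; apply ensure_positive first")
        if self.centre is None:
            h, w = self.values.shape
            self.centre = ((w - 1) / 2.0, (h - 1) / 2.0)
        cx, cy = self.centre
        h, w = self.values.shape
        if not (0 <= cx <= w - 1 and 0 <= cy <= h - 1):
            raise ValueError(f"centre {self.centre} lies outside the grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray) -> "IntensityField":
        return IntensityField(values, self.pixel_size, self.centre, self.provenance)

    def save(self, path: str | Path) -> None:
        """Write the field to an ``.npz`` array archive."""
        np.savez(
            path,
            values=self.values,
            pixel_size=self.pixel_size,
            centre=np.asarray(self.centre, dtype=float),
            provenance=np.asarray(self.provenance),
        )

    @classmethod
    def load(cls, path: str | Path) -> "IntensityField":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                z["values"],
                float(z["pixel_size"]),
                tuple(z["centre"]),
                str(z["provenance"]),
            )

    def save_png(self, path: str | Path) -> None:
        """Write a 16-bit greyscale PNG preview, min–max scaled."""
        v = self.values
        lo, hi = v.min(), v.max()
        scale = (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)
        Image.fromarray((scale * 65535).astype(np.uint16)).save(path)


@dataclasses.dataclass
class BinaryMask:
    """A {0, 1} grid with the same shape contract as its source field."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        self.values = v.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def ensure_positive(raw: np.ndarray, floor: float = DEFAULT_FLOOR, **field_kw) -> IntensityField:
    """Clamp a raw intensity grid to a strictly positive field.

    Every value below ``floor`` is replaced by ``floor``; the logarithm in
    the divergence is then always defined.  Idempotent.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise DataError("raw grid contains non-finite values")
    return IntensityField(np.maximum(raw, floor), **field_kw)


def load_intensity(path: str | Path, mode: str = "grey", floor: float = DEFAULT_FLOOR) -> IntensityField:
    """Read a raster image and build the intensity function μ.

    ``grey`` mode converts RGB to luminance on the 0–255 scale (greyscale
    files are used as-is); ``greenness`` computes 2g − r − b + 1 in signed
    arithmetic, emphasizing green objects on grey backgrounds.  Both results
    pass through :func:`ensure_positive`.
    """
    try:
        img = Image.open(path)
        img.load()
    except (OSError, FileNotFoundError) as exc:
        raise OSError(f"cannot read image {path!r}: {exc}") from exc

    if img.mode in ("RGB", "RGBA"):
        rgb = np.asarray(img.convert("RGB"), dtype=float)
        if mode == "grey":
            raw = rgb2gray(rgb / 255.0) * 255.0
        elif mode == "greenness":
            r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
            raw = 2.0 * g - r - b + 1.0
        else:
            raise ModeError(f"unknown mode {mode!r}")
    else:
        if mode == "greenness":
            raise ModeError("greenness mode requires an RGB image")
        if mode != "grey":
            raise ModeError(f"unknown mode {mode!r}")
        raw = np.asarray(img.convert("L" if img.mode not in ("I", "I;16", "F") else img.mode), dtype=float)

    return ensure_positive(raw, floor, provenance=mode)


def downsample(field: IntensityField, factor: int) -> IntensityField:
    """Block-mean reduction by an integer factor.

    Block averaging (rather than decimation) preserves the total intensity
    mass that the measure weights by.  Trailing rows/columns that do not
    fill a complete block are dropped.  ``pixel_size`` is multiplied and
    ``centre`` divided by the factor.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return field
    h, w = field.shape
    if factor > min(h, w):
        raise ValueError(f"factor {factor} exceeds grid dimensions {field.shape}")
    hb, wb = h // factor, w // factor
    v = field.values[: hb * factor, : wb * factor]
    blocks = v.reshape(hb, factor, wb, factor).mean(axis=(1, 3))
    cx, cy = field.centre
    # centre maps through the block geometry: block j covers source pixels
    # [j*f, (j+1)*f), its centre at j*f + (f-1)/2 -> new coordinate j.
    new_centre = ((cx - (factor - 1) / 2) / factor, (cy - (factor - 1) / 2) / factor)
    new_centre = (
        float(np.clip(new_centre[0], 0, wb - 1)),
        float(np.clip(new_centre[1], 0, hb - 1)),
    )
    return IntensityField(blocks, field.pixel_size * factor, new_centre, field.provenance)


def threshold_mask(field: IntensityField, threshold: float) -> BinaryMask:
    """Binary mask marking pixels whose intensity exceeds ``threshold``.

    Images where the object is darker than the background should be
    inverted by the caller first.
    """
    return BinaryMask((field.values > threshold).astype(np.uint8))
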