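"""Parametrized transformation families and overlap domains.

A transformation T maps the image plane onto itself; the transformed field
is Tμ(x) = μ(T⁻¹x), resampled by bilinear interpolation.  Samples whose
pre-image falls outside the original grid are *undefined* — never
zero-filled, because the divergence takes a logarithm of the transformed
intensity.  The overlap domain D̃ is the set of pixels where both the
original and the transformed field are defined; a pixel belongs to D̃ only
if all four interpolation neighbours of its pre-image are defined, so the
interpolated value uses no undefined data.

Translations may instead use periodic boundary conditions, in which case
D̃ is the whole grid.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .fields import BinaryMask, IntensityField

__all__ = [
    "TransformSpec",
    "OverlapDomain",
    "apply_transform",
    "reflection_spec",
    "EmptyOverlapError",
    "FAMILIES",
]

FAMILIES = ("identity", "rotation", "reflection", "translation", "rotation_scale")


class EmptyOverlapError(ValueError):
    """The image and its transform share no defined pixels."""


@dataclasses.dataclass(frozen=True)
class TransformSpec:
    """One member of a transformation family.

    ``angle`` is the rotation angle, or the reflection-axis angle from the
    horizontal, in degrees counterclockwise.  ``axis_point`` is an (x, y)
    point the reflection axis passes through; ``centre`` the origin of
    rotation and rescaling (both default to the field's centre when None).
    ``shift`` is a translation in physical units.  ``scale`` is the
    rescaling factor S of the rotation_scale family, applied about
    ``centre`` together with the rotation.
    """

    family: str
    angle: float = 0.0
    axis_point: tuple[float, float] | None = None
    shift: tuple[float, float] = (0.0, 0.0)
    scale: float = 1.0
    centre: tuple[float, float] | None = None
    boundary: str = "crop_intersect"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.scale != 1.0 and self.family != "rotation_scale":
            raise ValueError("scale != 1 only valid for rotation_scale")
        if self.boundary not in ("crop_intersect", "periodic"):
            raise ValueError(f"unknown boundary {self.boundary!r}")
        if self.boundary == "periodic" and self.family not in ("translation", "identity"):
            raise ValueError("periodic boundary only supported for translations")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["axis_point"] = None if self.axis_point is None else list(self.axis_point)
        d["centre"] = None if self.centre is None else list(self.centre)
        d["shift"] = list(self.shift)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TransformSpec":
        d = dict(d)
        for key in ("axis_point", "centre", "shift"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclasses.dataclass
class OverlapDomain:
    """The overlap D̃ between an image and its transform."""

    mask: BinaryMask
    area: float

    @property
    def n_pixels(self) -> int:
        return int(self.mask.values.sum())


def reflection_spec(angle: float, axis_point: tuple[float, float] | None = None) -> TransformSpec:
    """Reflection about the axis at ``angle`` degrees from horizontal through ``axis_point``."""
    return TransformSpec(family="reflection", angle=angle, axis_point=axis_point)


def _inverse_map(field: IntensityField, spec: TransformSpec) -> tuple[np.ndarray, np.ndarray]:
    """Pre-image coordinates (source col, source row) for every output pixel."""
    h, w = field.shape
    cols, rows = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    x = cols
    y = (h - 1) - rows  # y increases upward

    fam = spec.family
    if fam == "identity":
        qx, qy = x, y
    elif fam in ("rotation", "rotation_scale"):
        cx, cy = spec.centre if spec.centre is not None else field.centre
        th = math.radians(spec.angle)
        c, s = math.cos(th), math.sin(th)
        px, py = x - cx, y - cy
        # inverse: rotate by -angle, then divide by the scale factor
        qx = (c * px + s * py) / spec.scale + cx
        qy = (-s * px + c * py) / spec.scale + cy
    elif fam == "reflection":
        ax, ay = spec.axis_point if spec.axis_point is not None else field.centre
        th = math.radians(spec.angle)
        c2, s2 = math.cos(2 * th), math.sin(2 * th)
        px, py = x - ax, y - ay
        qx = c2 * px + s2 * py + ax
        qy = s2 * px - c2 * py + ay
    elif fam == "translation":
        sx, sy = spec.shift[0] / field.pixel_size, spec.shift[1] / field.pixel_size
        qx, qy = x - sx, y - sy
    else:  # pragma: no cover
        raise ValueError(fam)
    return qx, qy


def _bilinear(values: np.ndarray, qx: np.ndarray, qy: np.ndarray, periodic: bool) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear sample at y-up coordinates (qx, qy); returns (samples, defined)."""
    h, w = values.shape
    scol = qx
    srow = (h - 1) - qy
    if periodic:
        scol = np.mod(scol, w)
        srow = np.mod(srow, h)
    else:
        # tolerate float round-off at the domain edge
        eps = 1e-9
        inside = (scol >= -eps) & (scol <= w - 1 + eps) & (srow >= -eps) & (srow <= h - 1 + eps)
        scol = np.clip(scol, 0.0, float(w - 1))
        srow = np.clip(srow, 0.0, float(h - 1))
    c0 = np.floor(scol).astype(int)
    r0 = np.floor(srow).astype(int)
    fc = scol - c0
    fr = srow - r0
    if periodic:
        c0m, c1 = c0 % w, (c0 + 1) % w
        r0m, r1 = r0 % h, (r0 + 1) % h
        defined = np.ones(scol.shape, dtype=bool)
    else:
        defined = inside
        c0m = np.clip(c0, 0, w - 1)
        r0m = np.clip(r0, 0, h - 1)
        c1 = np.clip(c0 + 1, 0, w - 1)
        r1 = np.clip(r0 + 1, 0, h - 1)
    v00 = values[r0m, c0m]
    v01 = values[r0m, c1]
    v10 = values[r1, c0m]
    v11 = values[r1, c1]
    top = v00 * (1 - fc) + v01 * fc
    bot = v10 * (1 - fc) + v11 * fc
    return top * (1 - fr) + bot * fr, defined


def apply_transform(field: IntensityField, spec: TransformSpec) -> tuple[IntensityField, OverlapDomain]:
    """Apply a transformation, returning (Tμ, D̃).

    The transformed field is only meaningful on the overlap mask; outside
    it, values are filled with the field minimum so the result remains a
    valid positive field, but those pixels are excluded from D̃.
    """
    periodic = spec.boundary == "periodic"
    qx, qy = _inverse_map(field, spec)
    samples, defined = _bilinear(field.values, qx, qy, periodic)
    n_def = int(defined.sum())
    if n_def == 0:
        raise EmptyOverlapError(f"transform {spec.family} leaves no overlap with the image")
    fill = field.values.min()
    out = np.where(defined, samples, fill)
    out = np.maximum(out, fill if fill > 0 else np.finfo(float).tiny)
    transformed = field.with_values(out)
    mask = BinaryMask(defined.astype(np.uint8))
    area = n_def * field.pixel_size**2
    return transformed, OverlapDomain(mask=mask, area=area)
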