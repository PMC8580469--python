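"""Baseline asymmetry measures for comparison with transformation information.

Two established measures:

* **Simple Indicator (SI)** for bilateral symmetry: the object mask is cut
  into n bands orthogonal to a reflection axis; in band i the foreground
  area on one side of the axis is Aᵢ, on the other Bᵢ, and

      SI = (1/n) Σᵢ |Aᵢ − Bᵢ| / (Aᵢ + Bᵢ),

  so SI = 0 for a perfectly mirror-symmetric mask and 1 when the object
  lies entirely on one side.  Bands with Aᵢ + Bᵢ = 0 are excluded.

* **ZI**, a landmark-distance measure for rotational symmetry: landmarks
  (e.g. petal tips) are rotated about a centre and each rotated point is
  matched to its nearest original landmark; ZI is the sum of squared
  Euclidean distances of the matched pairs.  Zero exactly at rotations of
  the landmark set onto itself.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .fields import BinaryMask
from .transforms import TransformSpec

__all__ = ["PartitionAreas", "LandmarkSet", "simple_indicator", "zi_rotation", "zi_curve"]


@dataclasses.dataclass
class PartitionAreas:
    """Per-band foreground areas on each side of a reflection axis."""

    A: np.ndarray
    B: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        if self.A.size != self.n or self.B.size != self.n:
            raise ValueError("A and B must each have n entries")
        if (self.A < 0).any() or (self.B < 0).any():
            raise ValueError("areas must be non-negative")

    def indicator(self) -> float:
        tot = self.A + self.B
        keep = tot > 0
        if not keep.any():
            raise ValueError("all bands empty")
        return float(np.mean(np.abs(self.A[keep] - self.B[keep]) / tot[keep]))


@dataclasses.dataclass
class LandmarkSet:
    """Distinct 2-D landmark points with a rotation centre."""

    points: np.ndarray
    centre: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 1 or self.points.shape[1] != 2:
            raise ValueError("need at least one (x, y) landmark")
        if len({tuple(p) for p in self.points.round(12)}) != len(self.points):
            raise ValueError("landmarks must be distinct")

    @classmethod
    def from_csv(cls, path: str | Path, centre: tuple[float, float] = (0.0, 0.0)) -> "LandmarkSet":
        df = pd.read_csv(path)
        if not {"x", "y"} <= set(df.columns):
            raise ValueError("landmark CSV must have 'x' and 'y' columns")
        return cls(df[["x", "y"]].to_numpy(), centre)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.points, columns=["x", "y"]).to_csv(path, index=False)


def partition_areas(mask: BinaryMask, axis: TransformSpec, n: int) -> PartitionAreas:
    """Cut the mask into n equal-width bands along the axis direction.

    The axis is a reflection spec (angle from horizontal, point on the
    axis).  Each foreground pixel gets an along-axis coordinate ξ and a
    signed across-axis coordinate η; bands partition [ξmin, ξmax] and the
    sides are η > 0 vs η < 0 (pixels exactly on the axis are excluded).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if axis.family != "reflection":
        raise ValueError("axis must be a reflection TransformSpec")
    v = mask.values
    rows, cols = np.nonzero(v)
    if rows.size == 0:
        raise ValueError("empty mask")
    h = v.shape[0]
    x = cols.astype(float)
    y = (h - 1) - rows.astype(float)
    ax, ay = axis.axis_point if axis.axis_point is not None else ((v.shape[1] - 1) / 2, (h - 1) / 2)
    th = math.radians(axis.angle)
    ux, uy = math.cos(th), math.sin(th)          # along axis
    px, py = -math.sin(th), math.cos(th)         # across axis
    xi = (x - ax) * ux + (y - ay) * uy
    eta = (x - ax) * px + (y - ay) * py
    lo, hi = xi.min(), xi.max()
    width = (hi - lo) / n if hi > lo else 1.0
    band = np.clip(((xi - lo) / width).astype(int), 0, n - 1)
    A = np.bincount(band[eta > 0], minlength=n).astype(float)
    B = np.bincount(band[eta < 0], minlength=n).astype(float)
    return PartitionAreas(A=A, B=B, n=n)


def simple_indicator(mask: BinaryMask, axis: TransformSpec, n: int = 20) -> float:
    """SI of a binary mask about a reflection axis with n bands."""
    return partition_areas(mask, axis, n).indicator()


def zi_rotation(landmarks: LandmarkSet, angle: float) -> float:
    """Sum of squared nearest-landmark distances after rotating by ``angle`` degrees.

    Each rotated landmark is matched to the nearest *original* landmark
    (ties broken by first index); matching is independent per point, not
    an optimal assignment.
    """
    pts = landmarks.points
    c = np.asarray(landmarks.centre, dtype=float)
    th = math.radians(angle)
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    rotated = (pts - c) @ rot.T + c
    d2 = ((rotated[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    return float(d2.min(axis=1).sum())


def zi_curve(landmarks: LandmarkSet, angles) -> np.ndarray:
    """ZI evaluated over a grid of rotation angles (degrees)."""
    return np.array([zi_rotation(landmarks, a) for a in np.asarray(angles, dtype=float)])
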