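"""Synthetic test patterns with known ground-truth symmetries.

Each fixture emulates a class of biological specimen so the whole pipeline
is exercisable without photographs:

* ``rosette`` — an n-fold arrangement of petal-like radial lobes
  (pentamerous flowers, regular Turing rosettes); ``asymmetry`` adds an
  identical one-sided secondary lobe to every petal, preserving the n-fold
  rotational symmetry while destroying all reflection symmetries.
* ``bilateral_blob`` — a leaf-like shape, mirror-symmetric about an axis
  at ``axis_angle`` degrees from horizontal, asymmetric tip-to-stem.
* ``pentagon_landmarks`` — Gaussian bumps at the vertices of a regular
  pentagon, for landmark-based comparisons.
* ``decussate_whorl`` — opposite leaf pairs at successive levels, each
  level rotated by ``level_rotation`` and shrunk by ``level_scale``
  relative to the previous, giving discrete rotation–rescale
  self-similarity (stem cross-sections).
* ``plane_wave`` — a sinusoid with an integer number of periods across
  the domain, exactly symmetric under wavelength translations
  (``n_fold`` is the period count, ``axis_angle`` the propagation
  direction).

Shapes are rendered with smooth Gaussian edges so that interpolation error
stays far below the asymmetry signal under test.  Seeded pixel noise
(uniform, ``noise_amplitude`` × dynamic range) can be added after
construction.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .baselines import LandmarkSet
from .fields import IntensityField
from .transforms import TransformSpec

__all__ = ["FixtureSpec", "make_fixture", "pentagon_landmark_set"]

KINDS = ("rosette", "bilateral_blob", "pentagon_landmarks", "decussate_whorl", "plane_wave")


@dataclasses.dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic specimen."""

    kind: str
    n_fold: int = 5
    axis_angle: float = 0.0
    level_rotation: float = 90.0
    level_scale: float = 0.6
    n_levels: int = 4
    asymmetry: float = 0.0
    noise_amplitude: float = 0.0
    size: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.size < 64:
            raise ValueError("size must be >= 64")
        if not 0.0 <= self.asymmetry <= 1.0:
            raise ValueError("asymmetry must lie in [0, 1]")
        if not 0.0 < self.level_scale < 1.0:
            raise ValueError("level_scale must lie in (0, 1)")


def _grids(size: int):
    """(X, Y) pixel coordinates relative to the geometric centre, y up."""
    c = (size - 1) / 2.0
    x = np.arange(size, dtype=float) - c
    X = x[None, :]
    Y = x[::-1, None]  # row 0 is the top, y decreases with row index
    return X, Y


def _angular_distance(theta: np.ndarray, phi: float) -> np.ndarray:
    d = np.mod(theta - phi + np.pi, 2 * np.pi) - np.pi
    return d


def _rosette(spec: FixtureSpec) -> np.ndarray:
    X, Y = _grids(spec.size)
    r = np.hypot(X, Y)
    theta = np.arctan2(Y, X)
    r0 = 0.30 * spec.size
    sig_r = 0.08 * spec.size
    sig_arc = 0.07 * spec.size
    out = np.zeros((spec.size, spec.size))
    for k in range(spec.n_fold):
        phi = 2 * np.pi * k / spec.n_fold + np.pi / 2
        arc = _angular_distance(theta, phi) * np.maximum(r, 1e-9)
        out += np.exp(-((r - r0) / sig_r) ** 2 - (arc / sig_arc) ** 2)
        if spec.asymmetry > 0:
            # identical one-sided lobe on every petal: keeps the n-fold
            # rotations exact, breaks every reflection
            arc2 = _angular_distance(theta, phi + 0.5 * 2 * np.pi / spec.n_fold * 0.6) * np.maximum(r, 1e-9)
            out += spec.asymmetry * 0.7 * np.exp(
                -((r - 0.8 * r0) / (0.7 * sig_r)) ** 2 - (arc2 / (0.6 * sig_arc)) ** 2
            )
    out += 0.6 * np.exp(-(r / (0.10 * spec.size)) ** 2)  # central disc
    return out


def _bilateral_blob(spec: FixtureSpec) -> np.ndarray:
    X, Y = _grids(spec.size)
    th = math.radians(spec.axis_angle)
    xi = X * math.cos(th) + Y * math.sin(th)     # along the axis
    eta = -X * math.sin(th) + Y * math.cos(th)   # across the axis
    a = 0.32 * spec.size
    # width profile varies along the axis (widest near the stem end) so the
    # shape has exactly one mirror symmetry
    w = 0.13 * spec.size * (1.0 + 0.45 * np.tanh(-xi / (0.25 * spec.size)))
    return np.exp(-((xi / a) ** 2) - (eta / w) ** 2) * (1.0 + 0.5 * np.tanh(xi / (0.3 * spec.size)))


def pentagon_landmark_set(radius: float = 1.0, centre: tuple[float, float] = (0.0, 0.0),
                          n: int = 5) -> LandmarkSet:
    """Vertices of a regular n-gon (default pentagon), first vertex pointing up."""
    ang = np.pi / 2 + 2 * np.pi * np.arange(n) / n
    pts = np.column_stack([
        centre[0] + radius * np.cos(ang),
        centre[1] + radius * np.sin(ang),
    ])
    return LandmarkSet(points=pts, centre=centre)


def _pentagon_field(spec: FixtureSpec) -> np.ndarray:
    X, Y = _grids(spec.size)
    r0 = 0.33 * spec.size
    sig = 0.06 * spec.size
    out = np.zeros((spec.size, spec.size))
    lm = pentagon_landmark_set(radius=r0, n=spec.n_fold)
    for px, py in lm.points:
        out += np.exp(-(((X - px) ** 2 + (Y - py) ** 2) / sig**2))
    return out


def _decussate_whorl(spec: FixtureSpec) -> np.ndarray:
    X, Y = _grids(spec.size)
    out = np.zeros((spec.size, spec.size))
    r0 = 0.38 * spec.size
    sig_major0 = 0.085 * spec.size
    sig_minor0 = 0.035 * spec.size
    for lev in range(spec.n_levels):
        s = spec.level_scale**lev
        phi0 = math.radians(spec.axis_angle + lev * spec.level_rotation)
        for phi in (phi0, phi0 + np.pi):
            cx_, cy_ = r0 * s * math.cos(phi), r0 * s * math.sin(phi)
            # leaf elongated radially, all lengths scaled by level_scale**lev
            xr = (X - cx_) * math.cos(phi) + (Y - cy_) * math.sin(phi)
            yr = -(X - cx_) * math.sin(phi) + (Y - cy_) * math.cos(phi)
            out += np.exp(-((xr / (sig_major0 * s)) ** 2) - (yr / (sig_minor0 * s)) ** 2)
    return out


def _plane_wave(spec: FixtureSpec) -> np.ndarray:
    X, Y = _grids(spec.size)
    th = math.radians(spec.axis_angle)
    xi = X * math.cos(th) + Y * math.sin(th)
    k = 2 * np.pi * spec.n_fold / spec.size
    return 0.5 * (1.0 + np.cos(k * xi))


def make_fixture(spec: FixtureSpec) -> tuple[IntensityField, list[TransformSpec]]:
    """Render a fixture and the exact symmetry transforms it was built for."""
    if spec.kind == "rosette":
        raw = _rosette(spec)
        truth = [TransformSpec("rotation", angle=360.0 * k / spec.n_fold)
                 for k in range(1, spec.n_fold)]
    elif spec.kind == "bilateral_blob":
        raw = _bilateral_blob(spec)
        truth = [TransformSpec("reflection", angle=spec.axis_angle)]
    elif spec.kind == "pentagon_landmarks":
        raw = _pentagon_field(spec)
        truth = [TransformSpec("rotation", angle=360.0 * k / spec.n_fold)
                 for k in range(1, spec.n_fold)]
    elif spec.kind == "decussate_whorl":
        raw = _decussate_whorl(spec)
        truth = [
            TransformSpec("rotation_scale", angle=spec.level_rotation, scale=spec.level_scale),
            TransformSpec("rotation_scale", angle=2 * spec.level_rotation % 360.0,
                          scale=spec.level_scale**2),
        ]
    elif spec.kind == "plane_wave":
        raw = _plane_wave(spec)
        lam = spec.size / spec.n_fold
        th = math.radians(spec.axis_angle)
        truth = [TransformSpec("translation",
                               shift=(lam * math.cos(th), lam * math.sin(th)),
                               boundary="periodic")]
    else:  # pragma: no cover
        raise ValueError(spec.kind)

    # map to a 0–255-like scale on a positive baseline
    raw = 10.0 + 200.0 * raw / max(raw.max(), 1e-12)
    if spec.noise_amplitude > 0:
        rng = np.random.default_rng(spec.seed)
        dyn = raw.max() - raw.min()
        raw = raw + rng.uniform(-1, 1, raw.shape) * spec.noise_amplitude * dyn
    field = IntensityField(np.maximum(raw, 1.0), provenance="fixture")
    # truth transforms default to the field centre
    truth = [dataclasses.replace(
        t,
        centre=field.centre if t.family in ("rotation", "rotation_scale") else None,
        axis_point=field.centre if t.family == "reflection" else None,
    ) for t in truth]
    return field, truth
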