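"""The transformation-information asymmetry measure.

For a strictly positive intensity field μ and a transformation T, the
measure is the divergence

    TI = (1/|D̃|) ∫_D̃ μ(x) · ln[ μ(x) / Tμ(x) ] dA,

a Kullback–Leibler-style comparison of the image with its transform over
their overlap domain D̃.  TI is zero when T is an exact symmetry of μ on
D̃, and local minima of TI over a transformation family mark approximate
symmetries.  Discretely, the integral is a midpoint-rule pixel sum, so TI
reduces to the mean of μ·ln(μ/Tμ) over the overlap pixels.

TI is covariant under intensity rescaling, TI(cμ) = c·TI(μ): the constant
cancels inside the logarithm.  It is not sign-definite when T changes the
total mass on D̃ (e.g. rescaling transforms).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fields import IntensityField
from .transforms import EmptyOverlapError, OverlapDomain, TransformSpec, apply_transform

__all__ = [
    "TICurve",
    "DifferenceMap",
    "transformation_information",
    "ti_scan",
    "translation_ti_periodic",
    "difference_map",
]


@dataclasses.dataclass
class TICurve:
    """TI evaluated over a 1-D or 2-D grid of transformation parameters.

    ``param_grid`` is a 1-D array for rotation/reflection angle scans or
    reflection-offset scans, a tuple of two 1-D arrays (values along each
    axis) for 2-D scans (shift-x × shift-y, angle × scale).  Entries where
    the overlap was empty hold NaN.
    """

    family: str
    param_grid: np.ndarray | tuple[np.ndarray, np.ndarray]
    ti_values: np.ndarray
    centre_used: tuple[float, float] | None = None
    pixel_size: float = 1.0

    @property
    def ndim(self) -> int:
        return self.ti_values.ndim

    def param_names(self) -> list[str]:
        return {
            "rotation": ["angle_deg"],
            "reflection": ["axis_angle_deg"],
            "translation": ["shift_x", "shift_y"],
            "rotation_scale": ["angle_deg", "scale"],
        }.get(self.family, ["param"])

    def to_frame(self) -> pd.DataFrame:
        names = self.param_names()
        if self.ndim == 1:
            return pd.DataFrame({names[0]: np.asarray(self.param_grid), "ti": self.ti_values})
        g0, g1 = self.param_grid
        a, b = np.meshgrid(g0, g1, indexing="ij")
        return pd.DataFrame({names[0]: a.ravel(), names[1]: b.ravel(), "ti": self.ti_values.ravel()})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        if self.ndim == 1:
            grid = np.asarray(self.param_grid).tolist()
        else:
            grid = [np.asarray(g).tolist() for g in self.param_grid]
        payload = {
            "family": self.family,
            "param_names": self.param_names(),
            "param_grid": grid,
            "ti": np.where(np.isfinite(self.ti_values), self.ti_values, None).tolist(),
            "centre_used": None if self.centre_used is None else list(self.centre_used),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclasses.dataclass
class DifferenceMap:
    """Signed Tμ − μ on the overlap; zero for an exact symmetry."""

    values: np.ndarray
    overlap: OverlapDomain

    def max_abs(self) -> float:
        m = self.overlap.mask.values.astype(bool)
        return float(np.abs(self.values[m]).max())

    def save_png(self, path: str | Path) -> None:
        """Render with a signed colormap (blue transformed-higher, red original-higher)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        lim = max(self.max_abs(), np.finfo(float).tiny)
        fig, ax = plt.subplots(figsize=(4, 4), dpi=150)
        masked = np.ma.masked_where(~self.overlap.mask.values.astype(bool), self.values)
        ax.imshow(masked, cmap="RdBu", vmin=-lim, vmax=lim)
        ax.set_axis_off()
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)


def transformation_information(
    field: IntensityField,
    spec: TransformSpec,
    *,
    normalize: bool = False,
) -> float:
    """TI of a field under one transformation.

    With ``normalize=True`` the mean of μ over D̃ is scaled to 1 before the
    sum, removing the intensity-scale covariance for cross-image
    comparison; the default uses the raw intensities.
    """
    transformed, overlap = apply_transform(field, spec)
    m = overlap.mask.values.astype(bool)
    mu = field.values[m]
    tmu = transformed.values[m]
    if normalize:
        mu = mu / mu.mean()
        tmu = tmu / field.values[m].mean()
    return float(np.mean(mu * np.log(mu / tmu)))


def ti_scan(
    field: IntensityField,
    family: str,
    grid,
    centre: tuple[float, float] | None = None,
    *,
    axis_point: tuple[float, float] | None = None,
) -> TICurve:
    """Evaluate TI over a parameter grid of one transformation family.

    ``grid`` is a 1-D array of angles (degrees) for ``rotation`` and
    ``reflection``, or a pair ``(angles, scales)`` for ``rotation_scale``.
    Reflection axes pass through ``axis_point`` (default: ``centre``, then
    the field centre).  Grid points with empty overlap are NaN.
    """
    centre_used = centre if centre is not None else field.centre

    def _eval(spec: TransformSpec) -> float:
        try:
            return transformation_information(field, spec)
        except EmptyOverlapError:
            return np.nan

    if family == "rotation":
        grid = np.asarray(grid, dtype=float)
        ti = np.array([
            _eval(TransformSpec("rotation", angle=a, centre=centre_used)) for a in grid
        ])
        return TICurve("rotation", grid, ti, centre_used, field.pixel_size)
    if family == "reflection":
        grid = np.asarray(grid, dtype=float)
        point = axis_point if axis_point is not None else centre_used
        ti = np.array([
            _eval(TransformSpec("reflection", angle=a, axis_point=point)) for a in grid
        ])
        return TICurve("reflection", grid, ti, centre_used, field.pixel_size)
    if family == "rotation_scale":
        angles, scales = (np.asarray(g, dtype=float) for g in grid)
        ti = np.empty((angles.size, scales.size))
        for i, a in enumerate(angles):
            for j, s in enumerate(scales):
                ti[i, j] = _eval(
                    TransformSpec("rotation_scale", angle=a, scale=s, centre=centre_used)
                )
        return TICurve("rotation_scale", (angles, scales), ti, centre_used, field.pixel_size)
    raise ValueError(f"ti_scan does not support family {family!r}; use translation_ti_periodic for translations")


def translation_ti_periodic(field: IntensityField, *, method: str = "fft") -> TICurve:
    """TI over all integer-pixel periodic translations.

    On a periodic domain D̃ is the whole grid for every shift, so

        TI(s) = mean(μ·ln μ) − mean_x( μ(x)·ln μ(x − s) ).

    The cross term is a circular cross-correlation of μ with ln μ,
    evaluated by FFT (``method="fft"``) or by an explicit per-shift rolled
    sum (``method="direct"``, the reference semantics).  The returned grid
    is (shift-x, shift-y) in physical units, fftshift-ordered so the zero
    shift sits at the centre.
    """
    mu = field.values
    lmu = np.log(mu)
    h, w = mu.shape
    n = mu.size
    self_term = float(np.mean(mu * lmu))

    # cross[dr, dc] = mean_{r,c} mu[r, c] * lmu[r + dr, c + dc]
    if method == "fft":
        cross = np.fft.ifft2(np.fft.fft2(mu) * np.conj(np.fft.fft2(lmu))).real / n
        # ifft2(F[mu]*conj(F[lmu]))[d] = sum_r mu[r+d] lmu[r] = sum mu[r] lmu[r-d];
        # index [dr, dc] therefore holds lmu displaced by -d — flip to +d
        cross = np.roll(cross[::-1, ::-1], shift=(1, 1), axis=(0, 1))
    elif method == "direct":
        cross = np.empty((h, w))
        for dr in range(h):
            for dc in range(w):
                cross[dr, dc] = np.mean(mu * np.roll(lmu, shift=(-dr, -dc), axis=(0, 1)))
    else:
        raise ValueError(f"unknown method {method!r}")

    ti = self_term - cross  # ti[dr, dc]: Tμ[r, c] = μ[r + dr, c + dc]
    ti[0, 0] = 0.0  # the identity shift, exactly

    # Array offsets to physical shifts (y up): Tμ[r,c] = μ[r + sy, c − sx]
    # so the entry at (dr, dc) is the shift (sx, sy) = (−dc, dr) pixels.
    px = field.pixel_size
    sx_pix = np.fft.fftshift(np.fft.fftfreq(w, d=1.0 / w)).astype(int)
    sy_pix = np.fft.fftshift(np.fft.fftfreq(h, d=1.0 / h)).astype(int)
    ti_xy = ti[np.ix_(sy_pix % h, (-sx_pix) % w)].T
    return TICurve("translation", (sx_pix * px, sy_pix * px), ti_xy, field.centre, px)


def difference_map(field: IntensityField, spec: TransformSpec) -> DifferenceMap:
    """Signed difference Tμ − μ restricted to the overlap domain."""
    transformed, overlap = apply_transform(field, spec)
    diff = np.where(
        overlap.mask.values.astype(bool), transformed.values - field.values, 0.0
    )
    return DifferenceMap(values=diff, overlap=overlap)
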