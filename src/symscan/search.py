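"""Ranked approximate symmetries and automatic centre estimation.

Local minima of a TI curve are the approximate symmetries of the field;
their depth measures deviation from perfect symmetry.  Minima are filtered
by topographic prominence so that pixel noise does not spawn candidates,
and the identity transformation (always an exact symmetry, TI = 0) is
excluded.

Three centre-finding procedures are provided:

* ``rotational_dti`` — for each candidate centre, TI is evaluated at a
  small ring of evenly spaced rotation angles; a well-centred rotationally
  symmetric object makes TI swing strongly with angle, so the Euclidean
  norm of consecutive TI differences around the ring (including the
  wrap-around difference) peaks at the true centre.
* ``reflection_ti`` — the x coordinate minimizes TI for reflections about
  vertical axes, the y coordinate for horizontal axes.
* ``area_balance`` — split lines that equalize foreground area
  left/right and above/below of a binary mask.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.signal import find_peaks

from .fields import BinaryMask, IntensityField, downsample
from .ti import TICurve, ti_scan, transformation_information
from .transforms import EmptyOverlapError, TransformSpec

__all__ = [
    "SymmetryCandidate",
    "CenterEstimate",
    "find_symmetries",
    "estimate_center_rotational",
    "estimate_center_reflection",
    "estimate_center_area",
    "bilateral_axis_search",
]

#: default prominence threshold, as a fraction of the curve's TI range
DEFAULT_MIN_PROMINENCE_FRAC = 0.02


@dataclasses.dataclass
class SymmetryCandidate:
    """One detected approximate symmetry."""

    spec: TransformSpec
    ti_value: float
    prominence: float
    rank: int

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "ti": self.ti_value,
            "prominence": self.prominence,
            "rank": self.rank,
        }


@dataclasses.dataclass
class CenterEstimate:
    """An estimated symmetry centre with its criterion surface."""

    coordinates: tuple[float, float]
    method: str
    score_surface: np.ndarray
    window: tuple[np.ndarray, np.ndarray] | None = None
    found: bool = True
    secondary_minima: list[tuple[float, float]] = dataclasses.field(default_factory=list)


def _is_identity_param(family: str, params: tuple) -> bool:
    if family == "rotation":
        (a,) = params
        return np.isclose(a % 360.0, 0.0) or np.isclose(a % 360.0, 360.0)
    if family == "rotation_scale":
        a, s = params
        return (np.isclose(a % 360.0, 0.0) or np.isclose(a % 360.0, 360.0)) and np.isclose(s, 1.0)
    if family == "translation":
        return np.allclose(params, 0.0)
    return False  # a reflection is never the identity


def _candidates_1d(curve: TICurve, min_prominence: float) -> list[tuple[tuple, float, float]]:
    grid = np.asarray(curve.param_grid, dtype=float)
    ti = curve.ti_values
    finite = np.isfinite(ti)
    if not finite.any():
        raise ValueError("TI curve is undefined everywhere")
    span = grid[-1] - grid[0] if grid.size > 1 else 0.0
    step = np.median(np.diff(grid)) if grid.size > 1 else 1.0
    # angular grids covering a full turn are treated as periodic (0° ≡ 360°)
    periodic = curve.family in ("rotation", "reflection") and np.isclose(span + step, 360.0, atol=step / 2)

    y = np.where(finite, ti, np.nanmax(ti[finite]))
    if periodic:
        ext = np.concatenate([y, y, y])
        peaks, props = find_peaks(-ext, prominence=min_prominence)
        keep = (peaks >= y.size) & (peaks < 2 * y.size)
        idx = peaks[keep] - y.size
        prom = props["prominences"][keep]
    else:
        peaks, props = find_peaks(-y, prominence=min_prominence)
        idx, prom = peaks, props["prominences"]
    out = []
    for i, p in zip(idx, prom):
        if not finite[i]:
            continue
        out.append(((grid[i],), float(ti[i]), float(p)))
    return out


def _minima_persistence(filled: np.ndarray, periodic_axis0: bool) -> dict[tuple[int, int], float]:
    """Topographic prominence of every local minimum by 0-dim persistence.

    Pixels are merged in ascending order (8-connectivity); when a basin
    first touches a deeper basin, its minimum receives prominence equal to
    the merge level minus its depth.  The global minimum's basin gets the
    full relief of the surface.
    """
    h, w = filled.shape
    order = np.argsort(filled, axis=None, kind="stable")
    parent = {}
    basin_min: dict[tuple[int, int], tuple[float, tuple[int, int]]] = {}
    prominence: dict[tuple[int, int], float] = {}

    def find(p):
        root = p
        while parent[root] != root:
            root = parent[root]
        while parent[p] != root:
            parent[p], p = root, parent[p]
        return root

    for flat in order:
        i, j = divmod(int(flat), w)
        level = filled[i, j]
        neigh_roots = set()
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == 0 and dj == 0:
                    continue
                ni, nj = i + di, j + dj
                if periodic_axis0:
                    ni %= h
                if not (0 <= ni < h and 0 <= nj < w):
                    continue
                if (ni, nj) in parent:
                    neigh_roots.add(find((ni, nj)))
        p = (i, j)
        parent[p] = p
        if not neigh_roots:
            basin_min[p] = (level, p)  # a fresh local minimum
            continue
        roots = sorted(neigh_roots, key=lambda r: basin_min[r][0])
        deepest = roots[0]
        for r in roots[1:]:
            val, argmin = basin_min[r]
            prominence[argmin] = float(level - val)
            parent[r] = deepest
        parent[p] = deepest

    top = float(filled.max())
    # surviving basins (never merged away) span the full relief above them
    survivors = {find(p) for p in parent}
    for s in survivors:
        val, argmin = basin_min[s]
        prominence.setdefault(argmin, top - float(val))
    return prominence


def _candidates_2d(curve: TICurve, min_prominence: float) -> list[tuple[tuple, float, float]]:
    g0, g1 = (np.asarray(g, dtype=float) for g in curve.param_grid)
    ti = curve.ti_values
    finite = np.isfinite(ti)
    if not finite.any():
        raise ValueError("TI curve is undefined everywhere")
    filled = np.where(finite, ti, np.nanmax(ti[finite]))
    step0 = np.median(np.diff(g0)) if g0.size > 1 else 1.0
    span0 = (g0[-1] - g0[0]) if g0.size > 1 else 0.0
    periodic0 = curve.family == "rotation_scale" and np.isclose(span0 + step0, 360.0, atol=step0 / 2)
    out = []
    for (i, j), prom in _minima_persistence(filled, periodic0).items():
        if not finite[i, j] or prom < min_prominence:
            continue
        # skip minima on a non-periodic grid border: just a falling edge
        if (not periodic0 and (i == 0 or i == filled.shape[0] - 1)) or j in (0, filled.shape[1] - 1):
            continue
        out.append(((g0[i], g1[j]), float(ti[i, j]), float(prom)))
    return out


def find_symmetries(
    curve: TICurve,
    min_prominence: float | None = None,
) -> list[SymmetryCandidate]:
    """All interior local TI minima with sufficient prominence, ranked by TI.

    ``min_prominence`` defaults to 2% of the curve's TI range.  Identity
    parameters are excluded.  Ties are broken by lower TI, then by smaller
    parameter magnitude.
    """
    finite = np.isfinite(curve.ti_values)
    if not finite.any():
        raise ValueError("TI curve is undefined everywhere")
    if min_prominence is None:
        vals = curve.ti_values[finite]
        min_prominence = DEFAULT_MIN_PROMINENCE_FRAC * float(vals.max() - vals.min())

    if curve.ndim == 1:
        raw = _candidates_1d(curve, min_prominence)
    else:
        raw = _candidates_2d(curve, min_prominence)

    raw = [r for r in raw if not _is_identity_param(curve.family, r[0])]
    raw.sort(key=lambda r: (r[1], float(np.hypot(*r[0])) if len(r[0]) > 1 else abs(r[0][0])))

    out = []
    for rank, (params, ti_val, prom) in enumerate(raw, start=1):
        if curve.family == "rotation":
            spec = TransformSpec("rotation", angle=params[0], centre=curve.centre_used)
        elif curve.family == "reflection":
            spec = TransformSpec("reflection", angle=params[0], axis_point=curve.centre_used)
        elif curve.family == "rotation_scale":
            spec = TransformSpec("rotation_scale", angle=params[0], scale=params[1], centre=curve.centre_used)
        elif curve.family == "translation":
            spec = TransformSpec("translation", shift=(params[0], params[1]), boundary="periodic")
        else:
            raise ValueError(curve.family)
        out.append(SymmetryCandidate(spec=spec, ti_value=ti_val, prominence=prom, rank=rank))
    return out


def _window_grids(window) -> tuple[np.ndarray, np.ndarray]:
    (x0, x1), (y0, y1) = window
    xs = np.arange(int(np.floor(x0)), int(np.ceil(x1)) + 1)
    ys = np.arange(int(np.floor(y0)), int(np.ceil(y1)) + 1)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("degenerate search window")
    return xs, ys


def estimate_center_rotational(
    field: IntensityField,
    window,
    n_angles: int = 12,
    downsample_factor: int = 16,
) -> CenterEstimate:
    """Centre of rotational symmetry via the ‖dTI/dθ‖ criterion.

    ``window`` is ``((x0, x1), (y0, y1))`` in pixel coordinates of the
    *input* field; the field is block-downsampled first (default 16×,
    matching a 12-angle scan) and candidate centres are stepped at the
    downsampled resolution.  Returns coordinates in input-field pixels.
    """
    if n_angles < 3:
        raise ValueError("n_angles must be >= 3")
    ds = downsample(field, downsample_factor)
    f = downsample_factor
    (x0, x1), (y0, y1) = window
    h, w = field.shape
    if not (0 <= x0 <= x1 <= w - 1 and 0 <= y0 <= y1 <= h - 1):
        raise ValueError("window must lie inside the field")
    # map window to downsampled coordinates
    to_ds = lambda c: (c - (f - 1) / 2) / f
    xs, ys = _window_grids(((to_ds(x0), to_ds(x1)), (to_ds(y0), to_ds(y1))))
    hd, wd = ds.shape
    xs = xs[(xs >= 0) & (xs <= wd - 1)]
    ys = ys[(ys >= 0) & (ys <= hd - 1)]
    if xs.size == 0 or ys.size == 0:
        raise ValueError("degenerate search window after downsampling")

    angles = np.arange(n_angles) * 360.0 / n_angles
    score = np.zeros((ys.size, xs.size))
    for iy, cy in enumerate(ys):
        for ix, cx in enumerate(xs):
            ti = np.empty(n_angles)
            for k, a in enumerate(angles):
                try:
                    ti[k] = transformation_information(
                        ds, TransformSpec("rotation", angle=a, centre=(float(cx), float(cy)))
                    )
                except EmptyOverlapError:
                    ti[k] = np.nan
            if np.isnan(ti).any():
                score[iy, ix] = 0.0
                continue
            diffs = np.diff(np.concatenate([ti, ti[:1]]))  # ring incl. wrap-around
            score[iy, ix] = float(np.linalg.norm(diffs))

    if np.allclose(score, 0.0):
        return CenterEstimate((np.nan, np.nan), "rotational_dti", score, (xs, ys), found=False)
    iy, ix = np.unravel_index(np.argmax(score), score.shape)
    # back to input-field pixel coordinates
    cx_full = xs[ix] * f + (f - 1) / 2
    cy_full = ys[iy] * f + (f - 1) / 2
    return CenterEstimate((float(cx_full), float(cy_full)), "rotational_dti", score, (xs, ys))


def _axis_ti_profile(field: IntensityField, positions: np.ndarray, vertical: bool) -> np.ndarray:
    """TI for reflections about vertical (x = p) or horizontal (y = p) axes."""
    out = np.empty(positions.size)
    for i, p in enumerate(positions):
        if vertical:
            spec = TransformSpec("reflection", angle=90.0, axis_point=(float(p), field.centre[1]))
        else:
            spec = TransformSpec("reflection", angle=0.0, axis_point=(field.centre[0], float(p)))
        try:
            out[i] = transformation_information(field, spec)
        except EmptyOverlapError:
            out[i] = np.nan
    return out


def estimate_center_reflection(field: IntensityField, window) -> CenterEstimate:
    """Centre from reflection TI: x from vertical-axis scans, y from horizontal."""
    xs, ys = _window_grids(window)
    h, w = field.shape
    xs = xs[(xs >= 0) & (xs <= w - 1)]
    ys = ys[(ys >= 0) & (ys <= h - 1)]
    if xs.size == 0 or ys.size == 0:
        raise ValueError("degenerate search window")
    tx = _axis_ti_profile(field, xs, vertical=True)
    ty = _axis_ti_profile(field, ys, vertical=False)
    if (np.nanmax(tx) - np.nanmin(tx) < 1e-15) and (np.nanmax(ty) - np.nanmin(ty) < 1e-15):
        surface = ty[:, None] + tx[None, :]
        return CenterEstimate((np.nan, np.nan), "reflection_ti", surface, (xs, ys), found=False)
    bx = xs[np.nanargmin(tx)]
    by = ys[np.nanargmin(ty)]
    # secondary local minima (the best one on each axis besides the global)
    secondary = []
    for grid, prof, best in ((xs, tx, bx), (ys, ty, by)):
        pk, _ = find_peaks(-np.nan_to_num(prof, nan=np.nanmax(prof)))
        for i in pk:
            if grid[i] != best:
                secondary.append((float(grid[i]), float(prof[i])))
    surface = ty[:, None] + tx[None, :]
    return CenterEstimate(
        (float(bx), float(by)), "reflection_ti", surface, (xs, ys),
        secondary_minima=secondary,
    )


def estimate_center_area(mask: BinaryMask) -> CenterEstimate:
    """Split lines equalizing foreground area left/right and above/below.

    Returns the integer pixel position minimizing |area difference| for
    each axis independently (brute force over all split positions).
    """
    v = mask.values.astype(float)
    total = v.sum()
    if total == 0:
        raise ValueError("empty mask")
    h, w = v.shape
    col_sums = v.sum(axis=0)
    row_sums = v.sum(axis=1)

    def best_split(sums: np.ndarray) -> int:
        # split at pixel p: one side covers indices < p, other indices > p
        left = np.concatenate([[0.0], np.cumsum(sums)])[:-1]
        right = sums.sum() - left - sums
        return int(np.argmin(np.abs(left - right)))

    cx = best_split(col_sums)
    row_split = best_split(row_sums)
    cy = (h - 1) - row_split  # report y upward
    score = np.abs(
        np.add.outer(
            np.abs(np.concatenate([[0.0], np.cumsum(row_sums)])[:-1] * 2 + row_sums - total),
            np.abs(np.concatenate([[0.0], np.cumsum(col_sums)])[:-1] * 2 + col_sums - total),
        )
    )
    return CenterEstimate((float(cx), float(cy)), "area_balance", score)


def bilateral_axis_search(
    field: IntensityField,
    centre: tuple[float, float] | None = None,
    angle_range: tuple[float, float] = (-30.0, 30.0),
    step: float = 0.5,
) -> tuple[float, TICurve]:
    """Scan reflection-axis angles through ``centre``; return (argmin, curve)."""
    if step <= 0:
        raise ValueError("step must be positive")
    a0, a1 = angle_range
    if a1 < a0:
        raise ValueError("empty angle range")
    grid = np.arange(a0, a1 + step / 2, step)
    curve = ti_scan(field, "reflection", grid, centre=centre)
    best = float(grid[np.nanargmin(curve.ti_values)])
    return best, curve
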