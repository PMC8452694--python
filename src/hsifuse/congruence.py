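"""Pixel congruency across platforms: binarized-map rigid registration.

Images of the same sample acquired on different instruments share the
sample contour even though their spectra differ.  The workflow exploits
this: collapse each cube to a global intensity map, binarize it, and find
the rigid transform (shift + rotation) of the moving map that minimizes
the sum of squared differences against the reference map with a
Nelder-Mead simplex.  The recovered transform is then applied to every
spectral channel of the moving cube, and the jointly valid area across all
platforms defines the pixels entering the multiset.

Convention used everywhere: coordinates are (row=y, col=x), 0-based, y
increasing downward; a transform rotates the moving image about its centre
by ``theta`` degrees first, then shifts it by ``(dx, dy)`` pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.optimize import minimize
from skimage.filters import threshold_otsu

from .io import HSICube

__all__ = [
    "BinaryMap",
    "RigidTransform",
    "intensity_map",
    "binarize",
    "alignment_ssq",
    "align",
    "apply_transform",
    "common_support",
]


def _norm_angle(theta: float) -> float:
    """Normalize an angle in degrees to (-180, 180]."""
    t = (theta + 180.0) % 360.0 - 180.0
    return 180.0 if t == -180.0 else t


@dataclass
class RigidTransform:
    """Shift-and-rotation parameters mapping a moving image onto a reference.

    dx, dy : shift in pixels (+x rightward, +y downward), real-valued.
    theta  : rotation in degrees about the image centre, counter-clockwise
             positive, applied before the shift.
    """

    dx: float = 0.0
    dy: float = 0.0
    theta: float = 0.0

    def __post_init__(self) -> None:
        self.theta = _norm_angle(float(self.theta))

    def as_array(self) -> np.ndarray:
        return np.array([self.dx, self.dy, self.theta], dtype=float)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"dx": self.dx, "dy": self.dy, "theta_deg": self.theta})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RigidTransform":
        d = json.loads(Path(path).read_text())
        return cls(dx=d["dx"], dy=d["dy"], theta=d["theta_deg"])


@dataclass
class BinaryMap:
    """A 0/1 foreground map on the shared grid convention."""

    values: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("BinaryMap values must be 0 or 1")


def intensity_map(cube: HSICube, absolute: bool | None = None) -> np.ndarray:
    """Global intensity map: per-pixel sum over channels.

    For derivative spectra, which oscillate around zero, absolute values
    are summed so positive and negative lobes do not cancel; for raw
    (non-negative plus noise) data the plain sum is used so that noise
    does not lift the background floor.  ``absolute=None`` decides
    automatically from the negative-signal mass.  Masked pixels map to 0.
    """
    if absolute is None:
        neg = -float(cube.data[cube.data < 0].sum())
        pos = float(cube.data[cube.data > 0].sum())
        absolute = neg > 0.25 * pos
    m = (np.abs(cube.data) if absolute else cube.data).sum(axis=2)
    m[~cube.valid_mask] = 0.0
    return m


def binarize(
    map_: np.ndarray, method: str = "otsu", fraction: float = 0.5, pixel_size: float = 1.0
) -> BinaryMap:
    """Threshold a global intensity map into a 0/1 contour map.

    ``otsu`` picks the threshold by Otsu's criterion; ``otsu-sqrt``
    applies Otsu to square-root-compressed intensities (robust when the
    in-sample dynamic range rivals the sample/background contrast);
    ``fraction`` uses ``fraction * max(map)``.  Pixels >= threshold
    become 1.
    """
    m = np.asarray(map_, dtype=float)
    if method in ("otsu", "otsu-sqrt"):
        if np.ptp(m) == 0:
            raise ValueError(
                "constant intensity map: Otsu undefined, use method='fraction'"
            )
        if method == "otsu-sqrt":
            mm = np.sqrt(np.clip(m, 0.0, None))
            thr = threshold_otsu(mm) ** 2
        else:
            thr = threshold_otsu(m)
    elif method == "fraction":
        thr = fraction * m.max()
    else:
        raise ValueError("method must be 'otsu', 'otsu-sqrt' or 'fraction'")
    return BinaryMap(values=(m >= thr).astype(float), pixel_size=pixel_size)


def _sample_coords(
    shape_ref: tuple[int, int], shape_mov: tuple[int, int], t: RigidTransform
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coordinates in the moving image for every reference-grid pixel.

    Inverse of "rotate about centre by theta, then shift by (dx, dy)".
    Returns (u, v, defined) with u=rows, v=cols in the moving frame.
    """
    ny_r, nx_r = shape_ref
    ny_m, nx_m = shape_mov
    cy, cx = (ny_m - 1) / 2.0, (nx_m - 1) / 2.0
    yy, xx = np.mgrid[0:ny_r, 0:nx_r].astype(float)
    # shift reference-frame centre to the moving-frame centre location
    oy = yy - t.dy - cy
    ox = xx - t.dx - cx
    th = np.deg2rad(t.theta)
    c, s = np.cos(th), np.sin(th)
    u = cy + c * oy + s * ox
    v = cx - s * oy + c * ox
    defined = (u >= 0) & (u <= ny_m - 1) & (v >= 0) & (v <= nx_m - 1)
    return u, v, defined


def _resample(
    img: np.ndarray, u: np.ndarray, v: np.ndarray, order: int
) -> np.ndarray:
    return map_coordinates(
        np.asarray(img, dtype=float), [u, v], order=order, mode="constant", cval=0.0
    )


def alignment_ssq(
    ref: BinaryMap,
    moving: BinaryMap,
    t: RigidTransform,
    interpolation: str = "bilinear",
    min_overlap: float = 0.5,
) -> float:
    """Sum of squared differences between reference and transformed moving map.

    The moving map is resampled (bilinear by default, so the objective is
    piecewise smooth for the simplex) at the rigidly transformed reference
    coordinates; squared differences are taken over the common pixels
    (where both maps are defined) and scaled to the full reference pixel
    count, so shrinking the overlap cannot lower the error by dropping
    terms.  With full overlap this equals the plain sum of squared
    differences.  When less than ``min_overlap`` of the reference
    foreground is covered by the moving map's support, ``inf`` is returned
    to veto degenerate "slide off the image" solutions.
    """
    if abs(ref.pixel_size - moving.pixel_size) > 1e-9:
        raise ValueError("pixel sizes differ; resample before aligning")
    order = {"bilinear": 1, "nearest": 0}[interpolation]
    u, v, defined = _sample_coords(ref.values.shape, moving.values.shape, t)
    n_def = int(defined.sum())
    if n_def == 0:
        return np.inf
    fg = ref.values > 0
    n_fg = fg.sum()
    if n_fg > 0 and (fg & defined).sum() / n_fg < min_overlap:
        return np.inf
    samp = _resample(moving.values, u, v, order)
    diff = (ref.values - samp)[defined]
    return float(ref.values.size * np.sum(diff * diff) / n_def)


def align(
    ref: BinaryMap,
    moving: BinaryMap,
    init: RigidTransform | None = None,
    theta_grid: tuple[float, ...] = (-10.0, -5.0, 0.0, 5.0, 10.0),
    interpolation: str = "bilinear",
    min_overlap: float = 0.5,
    xatol: float = 0.01,
    fatol: float = 1e-4,
    max_iter: int = 500,
) -> RigidTransform:
    """Estimate the rigid transform aligning ``moving`` onto ``ref``.

    Nelder-Mead minimization of :func:`alignment_ssq` over (dx, dy, theta),
    restarted from each angle in ``theta_grid`` (offset from ``init``) since
    the binary-contour objective has local minima; the best result is
    returned and is never worse than the initial guess.
    """
    if init is None:
        init = RigidTransform()

    def cost(p: np.ndarray) -> float:
        return alignment_ssq(
            ref,
            moving,
            RigidTransform(dx=p[0], dy=p[1], theta=p[2]),
            interpolation=interpolation,
            min_overlap=min_overlap,
        )

    best_p = init.as_array()
    best_f = cost(best_p)
    any_finite = np.isfinite(best_f)
    for dtheta in theta_grid:
        p0 = init.as_array() + np.array([0.0, 0.0, dtheta])
        f0 = cost(p0)
        if not np.isfinite(f0):
            continue
        any_finite = True
        res = minimize(
            cost,
            p0,
            method="Nelder-Mead",
            options={
                "xatol": xatol,
                "fatol": fatol,
                "maxiter": max_iter,
                "initial_simplex": p0
                + np.vstack([np.zeros(3), np.diag([2.0, 2.0, 2.0])]),
            },
        )
        if np.isfinite(res.fun) and res.fun < best_f:
            best_f, best_p = res.fun, res.x
    if not any_finite:
        raise RuntimeError(
            "registration failed: no start yields sufficient overlap"
        )
    return RigidTransform(dx=float(best_p[0]), dy=float(best_p[1]), theta=float(best_p[2]))


def apply_transform(
    cube: HSICube,
    t: RigidTransform,
    interpolation: str = "bilinear",
    out_shape: tuple[int, int] | None = None,
) -> HSICube:
    """Resample every channel of a cube with one rigid transform.

    The validity mask is transported with the nearest-neighbour rule and
    pixels falling outside the moving image's support are masked.  An
    explicit ``out_shape`` resamples onto the reference grid size.
    """
    order = {"bilinear": 1, "nearest": 0}[interpolation]
    ny, nx, J = cube.data.shape
    shape_ref = out_shape if out_shape is not None else (ny, nx)
    identity = (
        t.dx == 0.0 and t.dy == 0.0 and t.theta == 0.0 and shape_ref == (ny, nx)
    )
    if identity:
        return cube.copy()
    u, v, defined = _sample_coords(shape_ref, (ny, nx), t)
    data = np.empty(shape_ref + (J,), dtype=float)
    for j in range(J):
        data[:, :, j] = _resample(cube.data[:, :, j], u, v, order)
    mask = _resample(cube.valid_mask.astype(float), u, v, 0) > 0.5
    mask &= defined
    data[~mask] = 0.0
    return cube.copy(data=data, valid_mask=mask)


def common_support(cubes: list[HSICube]) -> np.ndarray:
    """Logical AND of the validity masks of co-registered cubes.

    All cubes must share grid shape and pixel size.  The result is applied
    to every cube before unfolding so all platform blocks of a sample
    share one pixel index.
    """
    if not cubes:
        raise ValueError("no cubes given")
    shape = cubes[0].data.shape[:2]
    pix = cubes[0].pixel_size
    mask = np.ones(shape, dtype=bool)
    for c in cubes:
        if c.data.shape[:2] != shape or abs(c.pixel_size - pix) > 1e-9:
            raise ValueError("cubes are not on a common grid")
        mask &= c.valid_mask
    if not mask.any():
        raise ValueError("no pixel is valid in every cube")
    return mask
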