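"""Modality-specific spectral cleanup and spatial binning/resampling.

The cleanup recipe differs per platform: IR spectra get saturation removal,
spectral cropping and a Savitzky-Golay second derivative; Raman spectra get
asymmetric-least-squares (AsLS) baseline subtraction, cosmic-spike repair
and cropping; fluorescence images get spatial binning to trade resolution
for per-pixel signal.  All steps take and return :class:`~hsifuse.io.HSICube`
objects and never mutate their input.
"""

from __future__ import annotations

from dataclasses import dataclass

from functools import lru_cache

import numpy as np
import scipy.sparse as sp
from scipy.linalg import solveh_banded
from scipy.signal import savgol_filter

from .io import HSICube

__all__ = [
    "PreprocessPlan",
    "mask_saturated",
    "crop_spectral",
    "sg_derivative",
    "asls_baseline",
    "despike",
    "despike_spectrum",
    "bin_pixels",
    "resample_to_grid",
    "apply_plan",
]


@dataclass
class PreprocessPlan:
    """Per-modality cleanup recipe.

    Defaults follow common chemometric practice: SG window 9 / polyorder 3,
    AsLS lam=1e5 / p=0.001 / 10 iterations, spike threshold zmax=8.
    A ``None`` value switches the corresponding step off.
    """

    saturation_value: float | None = None
    spectral_ranges: list[tuple[float, float]] | None = None
    sg_window: int = 9
    sg_polyorder: int = 3
    sg_deriv_order: int = 0  # 0 = no derivative step
    asls_lambda: float = 1e5
    asls_p: float = 0.001
    asls_iters: int = 10
    asls_enabled: bool = False
    spike_zmax: float | None = None
    bin_factor: int = 1
    bin_stat: str = "mean"

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and > sg_polyorder")
        if not 0 < self.asls_p < 1:
            raise ValueError("asls_p must lie in (0, 1)")
        if self.bin_factor < 1:
            raise ValueError("bin_factor must be >= 1")


def mask_saturated(cube: HSICube, saturation_value: float) -> HSICube:
    """Mask every pixel whose spectrum reaches the ceiling in any channel.

    Saturated detector readings carry no quantitative information, so the
    pixel is excluded from all further analysis rather than repaired.
    """
    if not np.isfinite(saturation_value):
        raise ValueError("saturation_value must be finite")
    hot = (cube.data >= saturation_value).any(axis=2)
    return cube.copy(valid_mask=cube.valid_mask & ~hot)


def crop_spectral(cube: HSICube, ranges: list[tuple[float, float]]) -> HSICube:
    """Keep only channels whose axis value falls in any closed range.

    Channel order is preserved; ranges may be given in either direction
    (e.g. ``(3000, 2800)`` on a wavenumber axis).
    """
    if not ranges:
        raise ValueError("ranges must be non-empty")
    lo_ax, hi_ax = cube.axis.min(), cube.axis.max()
    keep = np.zeros(cube.n_channels, dtype=bool)
    for lo, hi in ranges:
        lo, hi = (lo, hi) if lo <= hi else (hi, lo)
        if hi < lo_ax or lo > hi_ax:
            raise ValueError(f"range ({lo}, {hi}) outside axis span ({lo_ax}, {hi_ax})")
        keep |= (cube.axis >= lo) & (cube.axis <= hi)
    if not keep.any():
        raise ValueError("no channels fall inside the requested ranges")
    return cube.copy(data=cube.data[:, :, keep], axis=cube.axis[keep])


def sg_derivative(
    cube: HSICube, window: int = 9, polyorder: int = 3, deriv_order: int = 2
) -> HSICube:
    """Savitzky-Golay derivative of every pixel spectrum.

    The second derivative removes offsets and linear baselines and sharpens
    overlapping bands; the output may be negative.  Channel spacing is taken
    from the spectral axis (assumed uniform).
    """
    if window % 2 == 0 or not (window > polyorder >= deriv_order):
        raise ValueError("need odd window > polyorder >= deriv_order")
    if cube.n_channels < window:
        raise ValueError("fewer channels than SG window")
    delta = float(np.abs(np.median(np.diff(cube.axis)))) if cube.n_channels > 1 else 1.0
    data = savgol_filter(
        cube.data, window, polyorder, deriv=deriv_order, delta=delta, axis=2
    )
    return cube.copy(data=data)


def asls_baseline(
    spectrum: np.ndarray, lam: float = 1e5, p: float = 0.001, iters: int = 10
) -> np.ndarray:
    """Asymmetric-least-squares baseline of one spectrum (Eilers-Boelens).

    Minimizes ``sum_i w_i (y_i - z_i)^2 + lam * sum (DD z)^2`` with the
    asymmetric weights ``w_i = p`` where ``y_i > z_i`` and ``1 - p``
    otherwise, re-estimated ``iters`` times.  With ``p << 0.5`` the
    baseline hugs the spectrum from below, ignoring positive peaks.

    Returns the baseline; subtract it from the spectrum to correct.
    """
    y = np.asarray(spectrum, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("spectrum must be 1-D with at least 3 channels")
    if not np.all(np.isfinite(y)):
        raise ValueError("spectrum contains non-finite values")
    J = y.size
    P = _asls_penalty(J, float(lam))
    w = np.ones(J)
    z = y
    for _ in range(iters):
        ab = P.copy()
        ab[2] += w  # add diag(w) to the banded system (W + lam D'D) z = w y
        z = solveh_banded(ab, w * y, lower=False)
        w = np.where(y > z, p, 1.0 - p)
    return z


@lru_cache(maxsize=8)
def _asls_penalty(J: int, lam: float) -> np.ndarray:
    """Upper banded form of lam * D2' D2 (pentadiagonal, bandwidth 2)."""
    D = sp.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(J - 2, J), format="csc")
    P = (lam * (D.T @ D)).todia()
    ab = np.zeros((3, J))
    ab[0, 2:] = P.diagonal(2)
    ab[1, 1:] = P.diagonal(1)
    ab[2] = P.diagonal(0)
    return ab


def _despike_1d(y: np.ndarray, zmax: float) -> np.ndarray:
    """Repair isolated cosmic spikes in one spectrum.

    Detection uses the modified z-score of the first differences.  A
    cosmic spike of 1-2 channels produces a pair of anomalous differences
    of opposite sign at most two channels apart; the channels between the
    pair are the spike.  An anomalous difference at the spectrum edge with
    no partner marks the edge channel.  Repair: linear interpolation from
    the nearest clean channels (nearest-value at the edges).  Broad
    features never show the tight up-down signature, so they are left
    untouched, and the operation is idempotent.
    """
    J = y.size
    if J < 3:
        return y.copy()
    d = np.diff(y)
    med = np.median(d)
    mad = np.median(np.abs(d - med))
    if mad == 0:
        z = np.zeros_like(d)
        nz = d != med
        z[nz] = np.inf * np.sign(d[nz] - med)
    else:
        z = 0.6745 * (d - med) / mad
    big = np.abs(z) > zmax
    flags = np.zeros(J, dtype=bool)
    # opposite-sign pairs of big differences at distance 1 or 2
    for a in np.nonzero(big)[0]:
        for b in (a + 1, a + 2):
            if b <= J - 2 and big[b] and z[a] * z[b] < 0:
                flags[a + 1 : b + 1] = True
    # lone big difference at either edge -> edge spike
    if big[0] and not flags[1] and (J < 3 or not big[1]):
        flags[0] = True
    if big[J - 2] and not flags[J - 2] and (J < 3 or not big[J - 3]):
        flags[J - 1] = True
    out = y.copy()
    j = 0
    while j < J:
        if not flags[j]:
            j += 1
            continue
        k = j
        while k < J and flags[k]:
            k += 1
        left, right = j - 1, k
        if left < 0 and right >= J:
            pass  # everything flagged; leave untouched
        elif left < 0:
            out[j:k] = y[right]
        elif right >= J:
            out[j:k] = y[left]
        else:
            xs = np.arange(j, k)
            out[j:k] = np.interp(xs, [left, right], [y[left], y[right]])
        j = k
    return out


def despike_spectrum(spectrum: np.ndarray, zmax: float = 8.0) -> np.ndarray:
    """Despike a single 1-D spectrum; see :func:`despike`."""
    return _despike_1d(np.asarray(spectrum, dtype=float), zmax)


def despike(cube: HSICube, zmax: float = 8.0) -> HSICube:
    """Repair cosmic spikes in every pixel spectrum of a cube.

    Only isolated 1-2 channel excursions are replaced (by interpolation of
    the nearest clean channels); all other values are untouched, so a
    spike-free cube passes through bit-identically.
    """
    data = cube.data.copy()
    ny, nx, _ = data.shape
    for iy in range(ny):
        for ix in range(nx):
            if cube.valid_mask[iy, ix]:
                data[iy, ix] = _despike_1d(data[iy, ix], zmax)
    return cube.copy(data=data)


def bin_pixels(cube: HSICube, factor: int, stat: str = "mean") -> HSICube:
    """Average (or sum) non-overlapping b x b pixel tiles channel-wise.

    Only valid pixels contribute; tiles with no valid pixel are masked.
    Trailing partial tiles are dropped so the output grid is exact.  Output
    pixel size is ``factor`` times the input pixel size.
    """
    b = int(factor)
    if b < 1:
        raise ValueError("factor must be >= 1")
    if b == 1:
        return cube.copy()
    ny, nx, J = cube.data.shape
    oy, ox = ny // b, nx // b
    if oy == 0 or ox == 0:
        raise ValueError(f"binning factor {b} larger than image ({ny}x{nx})")
    data = cube.data[: oy * b, : ox * b]
    mask = cube.valid_mask[: oy * b, : ox * b]
    dt = (data * mask[:, :, None]).reshape(oy, b, ox, b, J)
    mt = mask.reshape(oy, b, ox, b)
    sums = dt.sum(axis=(1, 3))
    counts = mt.sum(axis=(1, 3))
    out_mask = counts > 0
    safe = np.maximum(counts, 1)[:, :, None]
    if stat == "mean":
        out = sums / safe
    elif stat == "sum":
        out = sums
    else:
        raise ValueError("stat must be 'mean' or 'sum'")
    out[~out_mask] = 0.0
    return cube.copy(
        data=out,
        valid_mask=out_mask,
        pixel_size=cube.pixel_size * b,
    )


def _overlap_weights(n_in: int, s_in: float, n_out: int, s_out: float) -> sp.csr_matrix:
    """1-D overlap-length matrix W (n_out x n_in) for axis-aligned rebinning."""
    rows, cols, vals = [], [], []
    for i in range(n_out):
        lo, hi = i * s_out, (i + 1) * s_out
        j0 = max(0, int(np.floor(lo / s_in)))
        j1 = min(n_in, int(np.ceil(hi / s_in)))
        for j in range(j0, j1):
            ov = min(hi, (j + 1) * s_in) - max(lo, j * s_in)
            if ov > 1e-12:
                rows.append(i)
                cols.append(j)
                vals.append(ov)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n_out, n_in))


def resample_to_grid(cube: HSICube, target_pixel_size: float) -> HSICube:
    """Area-weighted rebinning onto a coarser grid (e.g. 2 um -> 3 um).

    Each output pixel is the overlap-area-weighted mean of the input pixels
    it covers; the weighting is separable because both grids are axis
    aligned and share the (0, 0) corner.  Masked input pixels carry zero
    weight; output pixels with no valid coverage are masked.  Non-integer
    size ratios are supported; upsampling is not.
    """
    s = cube.pixel_size
    t = float(target_pixel_size)
    if t < s - 1e-12:
        raise ValueError("target pixel size smaller than source (upsampling)")
    if abs(t - s) < 1e-12:
        return cube.copy()
    ny, nx, J = cube.data.shape
    oy = int(np.floor(ny * s / t + 1e-9))
    ox = int(np.floor(nx * s / t + 1e-9))
    if oy == 0 or ox == 0:
        raise ValueError("target pixel larger than the whole image")
    Wy = _overlap_weights(ny, s, oy, t).toarray()
    Wx = _overlap_weights(nx, s, ox, t).toarray()
    m = cube.valid_mask.astype(float)
    dm = cube.data * m[:, :, None]
    # numerator: Wy @ data @ Wx.T per channel; denominator from the mask
    num = np.einsum("ab,bcj,dc->adj", Wy, dm, Wx, optimize=True)
    den = Wy @ m @ Wx.T
    out_mask = den > 1e-12
    out = np.zeros_like(num)
    out[out_mask] = num[out_mask] / den[out_mask][:, None]
    return cube.copy(data=out, valid_mask=out_mask, pixel_size=t)


def apply_plan(cube: HSICube, plan: PreprocessPlan) -> HSICube:
    """Run a full per-modality recipe in the standard order.

    Order: saturation mask -> spectral crop -> despike -> AsLS baseline
    subtraction -> SG derivative -> pixel binning.
    """
    out = cube
    if plan.saturation_value is not None:
        out = mask_saturated(out, plan.saturation_value)
    if plan.spectral_ranges:
        out = crop_spectral(out, plan.spectral_ranges)
    if plan.spike_zmax is not None:
        out = despike(out, plan.spike_zmax)
    if plan.asls_enabled:
        data = out.data.copy()
        ny, nx, _ = data.shape
        for iy in range(ny):
            for ix in range(nx):
                if out.valid_mask[iy, ix]:
                    data[iy, ix] -= asls_baseline(
                        data[iy, ix], plan.asls_lambda, plan.asls_p, plan.asls_iters
                    )
        out = out.copy(data=data)
    if plan.sg_deriv_order > 0:
        out = sg_derivative(out, plan.sg_window, plan.sg_polyorder, plan.sg_deriv_order)
    if plan.bin_factor > 1:
        out = bin_pixels(out, plan.bin_factor, plan.bin_stat)
    return out
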