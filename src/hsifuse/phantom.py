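"""Synthetic co-registered multimodal HSI phantoms with known ground truth.

The generator instantiates the same measurement model the pipeline
assumes — every pixel spectrum is a non-negative mixture of invariant
pure component spectra — and then degrades it with the artifacts each
platform exhibits in practice: a broad fluorescence background and cosmic
spikes for Raman, detector saturation for IR, additive Gaussian (or
Poisson) noise everywhere, plus inter-platform pixel-size mismatch and
rigid misalignment.  Everything is reproducible from one seed and the
full truth (component maps, pure spectra, transforms, spike and
saturation positions) is returned alongside the cubes.

Component maps are rendered on a fine grid and area-downsampled to each
platform's pixel size, mirroring how one physical scene is sampled by
instruments of different resolution.  Per-sample scenes are right-angle
rotations of one rendered scene: spatially distinct images whose
component maps nevertheless share the same Gram matrix, so 2-norm block
balancing preserves exact bilinearity in the clean limit (the master
oracle for the whole pipeline).

The default component palette mimics leaf-tissue constituents: a
chlorophyll-like 682 nm emission, a lignin-like blue-green emission with
Raman bands near 1601/1631 cm^-1, a carotene-like Raman doublet at
1157/1525 cm^-1, and a lipid-like IR pair at 2848/2916 cm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.optimize import linear_sum_assignment

from .congruence import RigidTransform
from .io import HSICube
from .preprocessing import _overlap_weights

__all__ = ["PhantomSpec", "generate_phantom", "match_components", "default_axes"]


def default_axes() -> dict[str, np.ndarray]:
    """Spectral axes of the three emulated platforms.

    Fluorescence emission 420-750 nm in 5 nm steps; Raman shift
    1100-1800 cm^-1 in 4 cm^-1 steps; IR wavenumber over the two
    information-carrying windows 1360-1800 and 2800-3000 cm^-1 in
    8 cm^-1 steps.
    """
    return {
        "fluorescence": np.arange(420.0, 751.0, 5.0),
        "raman": np.arange(1100.0, 1801.0, 4.0),
        "ftir": np.concatenate(
            [np.arange(1368.0, 1801.0, 8.0), np.arange(2800.0, 3001.0, 8.0)]
        ),
    }


# per component, per modality: list of (center, width, amplitude) Gaussian bands
_PALETTE = [
    {  # chlorophyll-like
        "fluorescence": [(682.0, 18.0, 1.0)],
        "raman": [],
        "ftir": [(1660.0, 14.0, 0.5), (2930.0, 22.0, 0.3)],
    },
    {  # lignin-like
        "fluorescence": [(487.0, 24.0, 0.8), (512.0, 26.0, 0.5)],
        "raman": [(1601.0, 9.0, 1.0), (1631.0, 9.0, 0.7)],
        "ftir": [(1730.0, 12.0, 0.4), (1460.0, 16.0, 0.25)],
    },
    {  # carotene-like
        "fluorescence": [],
        "raman": [(1157.0, 8.0, 1.0), (1525.0, 8.0, 0.9)],
        "ftir": [],
    },
    {  # lipid-like
        "fluorescence": [(540.0, 40.0, 0.3)],
        "raman": [],
        "ftir": [(2848.0, 11.0, 1.0), (2916.0, 11.0, 0.9), (1740.0, 12.0, 0.3)],
    },
    {  # matrix: protein/cellulose-like, weakly visible everywhere
        "fluorescence": [(470.0, 55.0, 0.25)],
        "raman": [(1380.0, 25.0, 0.45), (1660.0, 18.0, 0.3)],
        "ftir": [(1655.0, 14.0, 0.6), (1543.0, 14.0, 0.4)],
    },
]

_SHAPES = [
    {"kind": "blob", "center": (0.32, 0.30), "r": 0.18},
    {"kind": "veins"},  # vascular network: ridges at several orientations
    {"kind": "ring", "center": (0.70, 0.68), "r": 0.16, "half_width": 0.035},
    {"kind": "blob", "center": (0.72, 0.25), "r": 0.14},
    {"kind": "matrix", "level": 0.5},
]


@dataclass
class PhantomSpec:
    """Conditions of one simulated multiplatform acquisition.

    Defaults emulate the emulated study: three leaf cross-sections imaged
    at 0.25 um (fluorescence), 2 um (Raman) and 3 um (SR-FTIR) pixels over
    a 60 um scene, with small rigid misalignments between platforms,
    a broad Raman baseline, cosmic spikes, a 2% fraction of saturated IR
    pixels and additive Gaussian noise set by ``snr``.
    """

    n_samples: int = 3
    n_components: int = 4
    scene_um: float = 120.0
    fine_pixel_um: float = 0.25
    pixel_sizes: dict[str, float] = field(
        default_factory=lambda: {"fluorescence": 0.25, "raman": 2.0, "ftir": 3.0}
    )
    axes: dict[str, np.ndarray] = field(default_factory=default_axes)
    map_shapes: list[dict] | None = None  # default: blob / ridge / ring / blob
    spectra: list[dict] | None = None  # default: the leaf-like palette
    transforms: dict[tuple[int, str], RigidTransform] | None = None
    snr: float | None = None  # per-modality noise sd = rms(signal) / snr
    noise_sd: float = 0.0  # absolute additive sd (used when snr is None)
    poisson: bool = False
    poisson_gain: float = 100.0
    raman_baseline: float = 0.0  # broad background amplitude (0 = off)
    spike_rate: float = 0.0  # cosmic spikes per 1000 Raman spectra
    saturation_ceiling: float | None = None  # IR intensity ceiling (None = off)
    saturation_fraction: float = 0.0  # fraction of IR pixels driven hot
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("need at least one component")
        if self.n_samples < 1:
            raise ValueError("need at least one sample")

    @classmethod
    def clean(
        cls,
        n_samples: int = 3,
        n_components: int = 4,
        n_px: int = 20,
        seed: int = 0,
        snr: float | None = None,
    ) -> "PhantomSpec":
        """Congruent-grid preset: all platforms on one 3 um grid, identity
        transforms, no instrument artifacts.  Without noise (``snr=None``)
        the unfolded cubes satisfy D = C S^T exactly."""
        return cls(
            n_samples=n_samples,
            n_components=n_components,
            scene_um=3.0 * n_px,
            fine_pixel_um=3.0,
            pixel_sizes={"fluorescence": 3.0, "raman": 3.0, "ftir": 3.0},
            snr=snr,
            seed=seed,
        )

    @classmethod
    def realistic(cls, seed: int = 0, snr: float = 50.0) -> "PhantomSpec":
        """Full-artifact preset: misalignment, baseline, spikes, saturation.

        Five components: the four localized constituents plus the ground
        tissue matrix, so every platform sees the full tissue contour."""
        return cls(
            n_components=5,
            transforms={
                (s, "fluorescence"): RigidTransform(dx=12.0, dy=-9.0, theta=3.0)
                for s in range(3)
            }
            | {
                (s, "raman"): RigidTransform(dx=2.0, dy=1.5, theta=-3.0)
                for s in range(3)
            },
            snr=snr,
            raman_baseline=0.4,
            spike_rate=3.0,
            saturation_ceiling=4095.0,
            saturation_fraction=0.02,
            seed=seed,
        )


def _tissue_mask(n: int) -> np.ndarray:
    """Leaf-section-like tissue support: a soft-edged, lobed blob.

    The contour is deliberately non-circular (angular radius modulation)
    so that its orientation is identifiable during rigid registration.
    """
    yy, xx = (np.mgrid[0:n, 0:n] + 0.5) / n
    dy = (yy - 0.5) / 0.34
    dx = (xx - 0.5) / 0.44
    r = np.sqrt(dy**2 + dx**2)
    phi = np.arctan2(dy, dx)
    R = (
        1.0
        + 0.12 * np.sin(3.0 * phi + 0.7)
        + 0.08 * np.cos(6.0 * phi)
        + 0.05 * np.sin(9.0 * phi + 1.3)
    )
    return np.clip((R - r) / 0.05, 0.0, 1.0)


def _render_shape(shape: dict, n: int) -> np.ndarray:
    """Render one spatial generator on an n x n unit-square grid."""
    yy, xx = (np.mgrid[0:n, 0:n] + 0.5) / n
    kind = shape["kind"]
    if kind == "blob":
        cy, cx = shape["center"]
        r = shape["r"]
        d2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / r**2
        return np.maximum(0.0, 1.0 - d2)
    if kind == "ring":
        cy, cx = shape["center"]
        r, hw = shape["r"], shape["half_width"]
        d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        return np.maximum(0.0, 1.0 - ((d - r) / hw) ** 2)
    if kind == "ridge":
        pos, hw = shape["pos"], shape["half_width"]
        lo, hi = shape["span"]
        prof = np.maximum(0.0, 1.0 - ((xx - pos) / hw) ** 2)
        prof[(yy < lo) | (yy > hi)] = 0.0
        return prof
    if kind == "veins":
        # a vertical main vein, a horizontal lateral and a short diagonal:
        # structure at several orientations pins down image rotation
        out = np.zeros((n, n))
        for ny0, nx0, dyv, dxv, hw, half_len in [
            (0.5, 0.62, 1.0, 0.0, 0.05, 0.40),
            (0.30, 0.45, 0.0, 1.0, 0.045, 0.30),
            (0.62, 0.40, 0.7071, -0.7071, 0.04, 0.22),
        ]:
            # distance to a segment centred at (ny0, nx0) with direction (dyv, dxv)
            py, px = yy - ny0, xx - nx0
            along = py * dyv + px * dxv
            perp = py * dxv - px * dyv
            prof = np.maximum(0.0, 1.0 - (perp / hw) ** 2)
            prof[np.abs(along) > half_len] = 0.0
            out = np.maximum(out, prof)
        return out
    if kind == "matrix":
        # filled in after the other components are rendered
        return np.zeros((n, n))
    raise ValueError(f"unknown shape kind {kind!r}")


def _gaussian_bands(axis: np.ndarray, bands: list[tuple]) -> np.ndarray:
    s = np.zeros_like(axis, dtype=float)
    for center, width, amp in bands:
        s += amp * np.exp(-0.5 * ((axis - center) / width) ** 2)
    return s


def _component_shapes(spec: PhantomSpec, rng: np.random.Generator) -> list[dict]:
    if spec.map_shapes is not None:
        return spec.map_shapes
    shapes = []
    for k in range(spec.n_components):
        # repeats beyond the palette cycle over the simple (non-matrix) shapes
        base = dict(_SHAPES[k] if k < len(_SHAPES) else _SHAPES[k % 4])
        if k >= len(_SHAPES):  # jitter repeats so maps stay distinct
            if "center" in base:
                base["center"] = tuple(
                    float(np.clip(c + rng.uniform(-0.15, 0.15), 0.15, 0.85))
                    for c in base["center"]
                )
            if "pos" in base:
                base["pos"] = float(np.clip(base["pos"] + rng.uniform(-0.2, 0.2), 0.2, 0.8))
        shapes.append(base)
    return shapes


def _component_spectra(
    spec: PhantomSpec, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Pure spectra per modality, shape (K, J_mod)."""
    modalities = list(spec.pixel_sizes)
    palette = spec.spectra
    if palette is None:
        palette = []
        for k in range(spec.n_components):
            entry = {
                m: list(v) for m, v in _PALETTE[k % len(_PALETTE)].items()
            }
            if k >= len(_PALETTE):  # shift band centres for extra components
                for m, bands in entry.items():
                    ax = spec.axes[m]
                    span = ax.max() - ax.min()
                    entry[m] = [
                        (
                            float(
                                np.clip(
                                    c + rng.uniform(-0.1, 0.1) * span,
                                    ax.min(),
                                    ax.max(),
                                )
                            ),
                            w,
                            a,
                        )
                        for c, w, a in bands
                    ]
            palette.append(entry)
    S = {}
    for m in modalities:
        ax = spec.axes[m]
        S[m] = np.stack(
            [_gaussian_bands(ax, palette[k].get(m, [])) for k in range(spec.n_components)]
        )
    visible = np.zeros(spec.n_components, dtype=bool)
    for m in modalities:
        visible |= S[m].any(axis=1)
    if not visible.all():
        raise ValueError(
            f"component(s) {np.nonzero(~visible)[0].tolist()} have no signal "
            "in any modality"
        )
    return S


def _downsample_maps(maps: np.ndarray, fine: float, target: float) -> np.ndarray:
    """Area-weighted mean of (K, n, n) fine maps onto the target grid."""
    K, ny, nx = maps.shape
    if abs(fine - target) < 1e-12:
        return maps.copy()
    oy = int(np.floor(ny * fine / target + 1e-9))
    ox = int(np.floor(nx * fine / target + 1e-9))
    Wy = _overlap_weights(ny, fine, oy, target).toarray()
    Wx = _overlap_weights(nx, fine, ox, target).toarray()
    Wy /= Wy.sum(axis=1, keepdims=True)
    Wx /= Wx.sum(axis=1, keepdims=True)
    return np.einsum("ab,kbc,dc->kad", Wy, maps, Wx, optimize=True)


def _misalign(cube_data: np.ndarray, t: RigidTransform) -> np.ndarray:
    """Resample channels so that aligning with ``t`` recovers the scene.

    Samples the in-register data at the forward-transformed coordinates;
    out-of-scene areas read as zero background.
    """
    ny, nx, J = cube_data.shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    uu, vv = np.mgrid[0:ny, 0:nx].astype(float)
    oy, ox = uu - cy, vv - cx
    th = np.deg2rad(t.theta)
    c, s = np.cos(th), np.sin(th)
    yy = t.dy + cy + c * oy - s * ox
    xx = t.dx + cx + s * oy + c * ox
    out = np.empty_like(cube_data)
    for j in range(J):
        out[:, :, j] = map_coordinates(
            cube_data[:, :, j], [yy, xx], order=1, mode="constant", cval=0.0
        )
    return out


def generate_phantom(spec: PhantomSpec) -> dict:
    """Generate co-registered multimodal cubes plus full ground truth.

    Returns a dict with

    - ``cubes``: {(sample_id, modality): HSICube}
    - ``truth``: {``S_true`` (per modality K x J), ``maps_ref`` (per
      sample K maps on the reference grid), ``maps_mod`` (per
      sample/modality, pre-misalignment), ``transforms``, ``spikes``
      (injected positions), ``saturated`` (hot-pixel coordinates),
      ``sample_ids``, ``modalities``}.

    In the clean limit (no noise, no artifacts, identity transforms,
    equal pixel sizes) each unfolded cube equals C_true S_true^T exactly.
    """
    rng = np.random.default_rng(spec.seed)
    modalities = list(spec.pixel_sizes)
    K = spec.n_components
    n_fine = int(round(spec.scene_um / spec.fine_pixel_um))
    shapes = _component_shapes(spec, rng)
    base = np.stack([_render_shape(sh, n_fine) for sh in shapes])  # (K, n, n)
    tissue = _tissue_mask(n_fine)
    base *= tissue[None]
    for k, sh in enumerate(shapes):
        if sh["kind"] == "matrix":
            # ground tissue: covers the whole section, attenuated (but not
            # absent) where the localized components dominate
            others = base.sum(axis=0) - base[k]
            base[k] = sh.get("level", 0.5) * tissue * (
                1.0 - 0.5 * np.clip(others / 0.5, 0.0, 1.0)
            )
    # gentle per-component texture so maps are not piecewise-analytic
    for k in range(K):
        tex = gaussian_filter(rng.standard_normal((n_fine, n_fine)), n_fine / 10)
        ptp = np.ptp(tex)
        if ptp > 0:
            tex = 0.85 + 0.3 * (tex - tex.min()) / ptp
        else:  # pragma: no cover - degenerate rng output
            tex = np.ones_like(tex)
        base[k] *= tex

    S_true = _component_spectra(spec, rng)
    ref_modality = max(modalities, key=lambda m: spec.pixel_sizes[m])
    sample_ids = [f"s{i + 1}" for i in range(spec.n_samples)]

    cubes: dict[tuple[str, str], HSICube] = {}
    maps_mod: dict[tuple[str, str], np.ndarray] = {}
    maps_ref: dict[str, np.ndarray] = {}
    spikes: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
    saturated: dict[tuple[str, str], list[tuple[int, int]]] = {}
    transforms: dict[tuple[str, str], RigidTransform] = {}

    for si, sid in enumerate(sample_ids):
        maps_fine = np.rot90(base, k=si % 4, axes=(1, 2))
        maps_ref[sid] = _downsample_maps(
            maps_fine, spec.fine_pixel_um, spec.pixel_sizes[ref_modality]
        )
        for m in modalities:
            t = RigidTransform()
            if spec.transforms is not None:
                t = spec.transforms.get((si, m), RigidTransform())
            transforms[(sid, m)] = t
            mk = _downsample_maps(maps_fine, spec.fine_pixel_um, spec.pixel_sizes[m])
            maps_mod[(sid, m)] = mk
            C = np.moveaxis(mk, 0, 2)  # (ny, nx, K)
            if t.dx or t.dy or t.theta:
                # misaligning abundances and mixing commutes with mixing
                # first (per-pixel linearity); K << J keeps this cheap
                C = _misalign(C, t)
            data = C @ S_true[m]
            ny, nx, J = data.shape
            # noise level is set by the clean signal, before any artifact
            sd = spec.noise_sd
            if spec.snr is not None:
                rms = float(np.sqrt(np.mean(data**2)))
                sd = rms / spec.snr if rms > 0 else 0.0
            if m == "raman" and spec.raman_baseline > 0:
                # tissue autofluorescence: broad, strongest where there is tissue
                shape_b = np.exp(
                    -0.5 * ((spec.axes[m] - 1350.0) / 320.0) ** 2
                ) + 0.3
                tot = data.sum(axis=2)
                rel = tot / max(tot.max(), 1e-12)
                amp = spec.raman_baseline * rel * (0.6 + 0.4 * rng.random((ny, nx)))
                data = data + amp[:, :, None] * shape_b[None, None, :]
            sp: list[tuple[int, int, int]] = []
            if m == "raman" and spec.spike_rate > 0:
                n_spiked = rng.binomial(ny * nx, spec.spike_rate / 1000.0)
                flat = rng.choice(ny * nx, size=n_spiked, replace=False)
                ref_level = max(float(np.percentile(data, 99)), 1e-6)
                for f in flat:
                    iy, ix = divmod(int(f), nx)
                    ch = int(rng.integers(1, J - 1))
                    data[iy, ix, ch] += rng.uniform(20.0, 100.0) * ref_level
                    sp.append((iy, ix, ch))
            spikes[(sid, m)] = sp
            hot: list[tuple[int, int]] = []
            if (
                m == "ftir"
                and spec.saturation_ceiling is not None
                and spec.saturation_fraction > 0
            ):
                n_hot = max(1, int(round(spec.saturation_fraction * ny * nx)))
                # saturation happens where the sample is opaque, i.e. on
                # signal-carrying pixels, not in the empty background
                per_pix = data.max(axis=2).ravel()
                candidates = np.nonzero(per_pix > 0.1 * per_pix.max())[0]
                n_hot = min(n_hot, candidates.size)
                flat = rng.choice(candidates, size=n_hot, replace=False)
                ceil = spec.saturation_ceiling
                for f in flat:
                    iy, ix = divmod(int(f), nx)
                    boosted = data[iy, ix] * (10.0 * ceil / max(data[iy, ix].max(), 1e-9))
                    data[iy, ix] = np.minimum(boosted, ceil)
                    hot.append((iy, ix))
            saturated[(sid, m)] = hot
            if spec.poisson:
                data = rng.poisson(
                    np.maximum(data, 0.0) * spec.poisson_gain
                ) / spec.poisson_gain
            if sd > 0:
                data = data + rng.normal(0.0, sd, size=data.shape)
            unit = "nm" if m == "fluorescence" else "cm-1"
            cubes[(sid, m)] = HSICube(
                data=data,
                axis=spec.axes[m].copy(),
                pixel_size=spec.pixel_sizes[m],
                modality=m,
                sample_id=sid,
                axis_unit=unit,
            )

    return {
        "cubes": cubes,
        "truth": {
            "S_true": S_true,
            "maps_ref": maps_ref,
            "maps_mod": maps_mod,
            "transforms": transforms,
            "spikes": spikes,
            "saturated": saturated,
            "sample_ids": sample_ids,
            "modalities": modalities,
            "ref_modality": ref_modality,
        },
    }


def balanced_truth_spectra(truth: dict, multiset) -> np.ndarray:
    """Concatenate the true spectra on the balanced multiset's scale.

    Block balancing divides each (sample, platform) block by its 2-norm,
    so spectra recovered from a balanced multiset carry a per-platform
    scale of 1/weight.  For a like-for-like comparison the true spectra
    must be scaled the same way (the per-sample weights of one platform
    agree up to the small misalignment residuals; their mean is used).
    """
    parts = []
    for m in multiset.modalities:
        w = float(
            np.mean([multiset.weights[(s, m)] for s in multiset.samples])
        )
        parts.append(truth["S_true"][m] / w)
    return np.concatenate(parts, axis=1)


def match_components(
    S_est: np.ndarray, S_true: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Optimal assignment of estimated to true components by |correlation|.

    Returns ``(perm, corr)`` where estimated component ``i`` matches true
    component ``perm[i]`` with Pearson correlation magnitude ``corr[i]``.
    The assignment maximizes the total |correlation| (Hungarian method);
    correlation is scale invariant, so rescaled estimates match the same
    permutation.
    """
    S_est = np.atleast_2d(np.asarray(S_est, dtype=float))
    S_true = np.atleast_2d(np.asarray(S_true, dtype=float))
    if S_est.shape[0] != S_true.shape[0]:
        raise ValueError("component counts differ")
    K = S_est.shape[0]
    corr = np.zeros((K, K))
    for i in range(K):
        for j in range(K):
            a, b = S_est[i], S_true[j]
            sa, sb = a.std(), b.std()
            if sa == 0 or sb == 0:
                corr[i, j] = 0.0
            else:
                corr[i, j] = abs(float(np.corrcoef(a, b)[0, 1]))
    rows, cols = linear_sum_assignment(-corr)
    perm = np.empty(K, dtype=int)
    perm[rows] = cols
    return perm, corr[np.arange(K), perm]
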