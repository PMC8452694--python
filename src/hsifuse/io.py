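"""Cube container, file I/O and unfold/refold between cube and matrix form.

A hyperspectral image (HSI) is held as an :class:`HSICube`: a
``(ny, nx, J)`` intensity array plus its spectral axis, pixel size and a
per-pixel validity mask.  Unmixing operates on the unfolded matrix form
(:class:`UnfoldedBlock`), where each row is the spectrum of one valid
pixel; :func:`unfold` / :func:`refold` convert between the two.

Three on-disk dialects are supported: ENVI (text ``.hdr`` + band-sequential
binary), a multi-page TIFF stack with a JSON metadata sidecar, and an HDF5
container.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import tifffile

MODALITIES = ("fluorescence", "raman", "ftir")

__all__ = [
    "HSICube",
    "UnfoldedBlock",
    "load_cube",
    "save_cube",
    "unfold",
    "refold",
    "MODALITIES",
]


class MetadataError(ValueError):
    """Required metadata (spectral axis, pixel size ...) is missing."""


class FormatError(ValueError):
    """On-disk payload is inconsistent with its header."""


@dataclass
class HSICube:
    """One sample imaged by one platform.

    Parameters
    ----------
    data : ndarray, shape (ny, nx, J)
        Pixel spectra. May be negative (e.g. derivative IR spectra).
    axis : ndarray, shape (J,)
        Spectral axis, strictly monotonic. Units: nm for fluorescence
        emission, cm^-1 for Raman shift and IR wavenumber.
    pixel_size : float
        Edge length of the (square) pixels in micrometres.
    modality : str
        One of ``fluorescence``, ``raman``, ``ftir``.
    sample_id : str
        Sample label; blocks of the same sample share it.
    valid_mask : ndarray of bool, shape (ny, nx), optional
        False marks excluded pixels (e.g. saturated). Defaults to all-true.
    axis_unit : str
        Label for the spectral axis ("nm", "cm-1").
    """

    data: np.ndarray
    axis: np.ndarray
    pixel_size: float
    modality: str
    sample_id: str = "sample"
    valid_mask: np.ndarray | None = None
    axis_unit: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D (ny, nx, J), got {self.data.shape}")
        ny, nx, J = self.data.shape
        if self.axis.shape != (J,):
            raise ValueError(
                f"axis length {self.axis.size} != channel count {J}"
            )
        d = np.diff(self.axis)
        if J > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("spectral axis must be strictly monotonic")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if self.valid_mask is None:
            self.valid_mask = np.ones((ny, nx), dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != (ny, nx):
                raise ValueError("valid_mask shape does not match data")
        if not np.all(np.isfinite(self.data[self.valid_mask])):
            raise ValueError("non-finite intensities on valid pixels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    def copy(self, **changes) -> "HSICube":
        base = dict(
            data=self.data.copy(),
            axis=self.axis.copy(),
            pixel_size=self.pixel_size,
            modality=self.modality,
            sample_id=self.sample_id,
            valid_mask=self.valid_mask.copy(),
            axis_unit=self.axis_unit,
        )
        base.update(changes)
        return HSICube(**base)


@dataclass
class UnfoldedBlock:
    """Matrix form D (I x J) of the valid pixels of one cube.

    Row i holds the spectrum of pixel ``pixel_index[i]``; rows are in
    row-major (y outer, x inner) order.  ``weight_applied`` records the
    balancing divisor (1.0 until balanced).
    """

    D: np.ndarray
    pixel_index: np.ndarray  # (I, 2) int array of (y, x)
    modality: str
    sample_id: str
    axis: np.ndarray
    shape: tuple[int, int]  # (ny, nx) of the source grid
    weight_applied: float = 1.0

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        self.pixel_index = np.asarray(self.pixel_index, dtype=int)
        if self.D.ndim != 2:
            raise ValueError("D must be 2-D")
        if self.pixel_index.shape != (self.D.shape[0], 2):
            raise ValueError("pixel_index must be (I, 2)")

    @property
    def n_pixels(self) -> int:
        return self.D.shape[0]

    @property
    def n_channels(self) -> int:
        return self.D.shape[1]


def unfold(cube: HSICube) -> UnfoldedBlock:
    """Unfold a cube into its I x J matrix of valid-pixel spectra.

    Masked pixels are dropped (not zero-filled). Raises ``ValueError`` if
    every pixel is masked.
    """
    ys, xs = np.nonzero(cube.valid_mask)  # row-major order by construction
    if ys.size == 0:
        raise ValueError("all pixels are masked; nothing to unfold")
    D = cube.data[ys, xs, :]
    idx = np.stack([ys, xs], axis=1)
    return UnfoldedBlock(
        D=D,
        pixel_index=idx,
        modality=cube.modality,
        sample_id=cube.sample_id,
        axis=cube.axis.copy(),
        shape=cube.data.shape[:2],
    )


def refold(
    values: np.ndarray,
    pixel_index: np.ndarray,
    shape: tuple[int, int],
    fill: float = np.nan,
) -> np.ndarray:
    """Refold a per-pixel vector back onto the (ny, nx) grid.

    Pixels absent from ``pixel_index`` receive ``fill``.
    """
    values = np.asarray(values, dtype=float)
    pixel_index = np.asarray(pixel_index, dtype=int)
    if values.shape[0] != pixel_index.shape[0]:
        raise ValueError("values and pixel_index lengths differ")
    ny, nx = shape
    if pixel_index.size and (
        pixel_index.min() < 0
        or pixel_index[:, 0].max() >= ny
        or pixel_index[:, 1].max() >= nx
    ):
        raise IndexError("pixel_index out of bounds for shape")
    out = np.full((ny, nx), fill, dtype=float)
    out[pixel_index[:, 0], pixel_index[:, 1]] = values
    return out


# ---------------------------------------------------------------------------
# On-disk formats
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 4: np.float32, 5: np.float64, 12: np.uint16}
_ENVI_CODES = {np.dtype(np.float64): 5, np.dtype(np.float32): 4}


def save_cube(cube: HSICube, path: str | Path, format: str = "hdf5") -> None:
    """Write a cube to disk in one of the supported dialects.

    ``hdf5`` is bit-faithful; ``tiff_stack`` stores one page per channel
    plus a JSON sidecar; ``envi`` writes a text header and band-sequential
    float64 binary.
    """
    path = Path(path)
    if format == "hdf5":
        _save_hdf5(cube, path)
    elif format == "tiff_stack":
        _save_tiff(cube, path)
    elif format == "envi":
        _save_envi(cube, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def load_cube(path: str | Path, format: str = "hdf5") -> HSICube:
    """Read a cube written by :func:`save_cube`."""
    path = Path(path)
    if not path.exists() and format != "envi":
        raise FileNotFoundError(path)
    if format == "hdf5":
        return _load_hdf5(path)
    if format == "tiff_stack":
        return _load_tiff(path)
    if format == "envi":
        return _load_envi(path)
    raise ValueError(f"unknown format {format!r}")


def _save_hdf5(cube: HSICube, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=cube.data)
        f.create_dataset("axis", data=cube.axis)
        f.create_dataset("mask", data=cube.valid_mask)
        f.attrs["pixel_size_um"] = cube.pixel_size
        f.attrs["modality"] = cube.modality
        f.attrs["sample_id"] = cube.sample_id
        f.attrs["axis_unit"] = cube.axis_unit


def _load_hdf5(path: Path) -> HSICube:
    with h5py.File(path, "r") as f:
        if "axis" not in f:
            raise MetadataError(f"{path}: no spectral axis stored")
        data = f["data"][()]
        axis = f["axis"][()]
        mask = f["mask"][()].astype(bool) if "mask" in f else None
        if data.shape[2] != axis.shape[0]:
            raise FormatError(
                f"{path}: {data.shape[2]} bands but axis of length {axis.shape[0]}"
            )
        return HSICube(
            data=data,
            axis=axis,
            pixel_size=float(f.attrs["pixel_size_um"]),
            modality=str(f.attrs["modality"]),
            sample_id=str(f.attrs["sample_id"]),
            valid_mask=mask,
            axis_unit=str(f.attrs.get("axis_unit", "")),
        )


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _save_tiff(cube: HSICube, path: Path) -> None:
    # one page per spectral channel, float32
    pages = np.moveaxis(cube.data.astype(np.float32), 2, 0)
    tifffile.imwrite(path, pages)
    meta = {
        "axis": cube.axis.tolist(),
        "axis_unit": cube.axis_unit,
        "pixel_size_um": cube.pixel_size,
        "modality": cube.modality,
        "sample_id": cube.sample_id,
    }
    if not cube.valid_mask.all():
        meta["valid_mask"] = cube.valid_mask.astype(int).tolist()
    _sidecar(path).write_text(json.dumps(meta))


def _load_tiff(path: Path) -> HSICube:
    side = _sidecar(path)
    if not side.exists():
        raise MetadataError(f"{path}: sidecar {side.name} with spectral axis missing")
    meta = json.loads(side.read_text())
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    data = np.moveaxis(pages, 0, 2)
    axis = np.asarray(meta["axis"], dtype=float)
    if data.shape[2] != axis.size:
        raise FormatError(
            f"{path}: {data.shape[2]} pages but axis of length {axis.size}"
        )
    mask = meta.get("valid_mask")
    return HSICube(
        data=data,
        axis=axis,
        pixel_size=float(meta["pixel_size_um"]),
        modality=meta["modality"],
        sample_id=meta.get("sample_id", "sample"),
        valid_mask=None if mask is None else np.asarray(mask, dtype=bool),
        axis_unit=meta.get("axis_unit", ""),
    )


def _envi_paths(path: Path) -> tuple[Path, Path]:
    if path.suffix == ".hdr":
        return path, path.with_suffix(".img")
    return path.with_suffix(path.suffix + ".hdr") if path.suffix else Path(
        str(path) + ".hdr"
    ), path


def _save_envi(cube: HSICube, path: Path) -> None:
    hdr, img = _envi_paths(path)
    ny, nx, J = cube.data.shape
    lines = [
        "ENVI",
        f"samples = {nx}",
        f"lines = {ny}",
        f"bands = {J}",
        "header offset = 0",
        "file type = ENVI Standard",
        "data type = 5",
        "interleave = bsq",
        "byte order = 0",
        "wavelength units = " + (cube.axis_unit or "Unknown"),
        "wavelength = {" + ", ".join(f"{v:.6f}" for v in cube.axis) + "}",
        f"pixel size = {{{cube.pixel_size:.6f}, {cube.pixel_size:.6f}}}",
        f"modality = {cube.modality}",
        f"sample id = {cube.sample_id}",
    ]
    hdr.write_text("\n".join(lines) + "\n")
    # band-sequential: (J, ny, nx)
    np.ascontiguousarray(np.moveaxis(cube.data.astype(np.float64), 2, 0)).tofile(img)


def _parse_envi_header(hdr: Path) -> dict:
    text = hdr.read_text()
    # join brace-delimited multi-line values
    fields: dict[str, str] = {}
    buf = ""
    key = None
    for raw in text.splitlines():
        line = raw.strip()
        if key is not None:
            buf += " " + line
            if "}" in line:
                fields[key] = buf
                key = None
            continue
        if "=" not in line:
            continue
        k, v = line.split("=", 1)
        k, v = k.strip().lower(), v.strip()
        if v.startswith("{") and "}" not in v:
            key, buf = k, v
        else:
            fields[k] = v
    return fields


def _load_envi(path: Path) -> HSICube:
    hdr, img = _envi_paths(path)
    if not hdr.exists():
        raise FileNotFoundError(hdr)
    if not img.exists():
        raise FileNotFoundError(img)
    fields = _parse_envi_header(hdr)
    try:
        nx = int(fields["samples"])
        ny = int(fields["lines"])
        J = int(fields["bands"])
        code = int(fields.get("data type", 5))
    except KeyError as exc:  # pragma: no cover - malformed header
        raise MetadataError(f"{hdr}: missing header field {exc}") from exc
    if "wavelength" not in fields:
        raise MetadataError(f"{hdr}: no wavelength (spectral axis) entry")
    axis = np.array(
        [float(t) for t in fields["wavelength"].strip("{} ").split(",") if t.strip()]
    )
    if axis.size != J:
        raise FormatError(f"{hdr}: bands = {J} but {axis.size} wavelengths")
    dtype = _ENVI_DTYPES.get(code)
    if dtype is None:
        raise FormatError(f"{hdr}: unsupported ENVI data type {code}")
    raw = np.fromfile(img, dtype=dtype)
    if raw.size != ny * nx * J:
        raise FormatError(
            f"{img}: payload holds {raw.size} values, header implies {ny * nx * J}"
        )
    data = np.moveaxis(raw.reshape(J, ny, nx), 0, 2)
    pix = 1.0
    if "pixel size" in fields:
        pix = float(fields["pixel size"].strip("{} ").split(",")[0])
    return HSICube(
        data=data,
        axis=axis,
        pixel_size=pix,
        modality=fields.get("modality", "unknown"),
        sample_id=fields.get("sample id", "sample"),
        axis_unit=fields.get("wavelength units", ""),
    )
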