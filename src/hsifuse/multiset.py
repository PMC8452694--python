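"""Row- and column-wise augmented multiset assembly with block balancing.

A fused data set stacks the unfolded blocks of several samples (rows) and
several platforms (columns) into one matrix M: blocks of the same sample
sit side by side (their pixels are congruent, so rows match), blocks of
the same platform sit one under the other (their spectral axes match).
Before assembly each block is divided by its 2-norm so no platform
dominates the joint factorization merely through signal scale or channel
count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .io import UnfoldedBlock

__all__ = ["Multiset", "block_norm", "balance", "assemble"]


def block_norm(block: UnfoldedBlock, kind: str = "frobenius") -> float:
    """2-norm of an unfolded block.

    ``frobenius`` (default, the chemometric block-scaling convention) is
    the square root of the sum of squared entries; ``spectral`` is the
    largest singular value.
    """
    if block.D.size == 0:
        raise ValueError("empty block has no norm")
    if kind == "frobenius":
        n = float(np.linalg.norm(block.D, "fro"))
    elif kind == "spectral":
        n = float(np.linalg.norm(block.D, 2))
    else:
        raise ValueError("kind must be 'frobenius' or 'spectral'")
    if n == 0.0:
        raise ValueError("all-zero block cannot be balanced")
    return n


def balance(blocks: list[UnfoldedBlock], kind: str = "frobenius") -> list[UnfoldedBlock]:
    """Divide each block by its own 2-norm; the divisor is recorded.

    Balancing is scale invariant: pre-scaling a block leaves its balanced
    version unchanged.  Multiplying a balanced block by its
    ``weight_applied`` restores the original exactly.
    """
    out = []
    for b in blocks:
        w = block_norm(b, kind)
        out.append(
            UnfoldedBlock(
                D=b.D / w,
                pixel_index=b.pixel_index.copy(),
                modality=b.modality,
                sample_id=b.sample_id,
                axis=b.axis.copy(),
                shape=b.shape,
                weight_applied=w * b.weight_applied,
            )
        )
    return out


@dataclass
class Multiset:
    """Augmented matrix of sample x platform blocks with full bookkeeping.

    ``row_blocks`` maps sample_id -> (start, stop) row range; ``col_blocks``
    maps modality -> (start, stop) column range; ``weights`` holds the
    balancing divisor per (sample, modality) cell.
    """

    M: np.ndarray
    row_blocks: dict[str, tuple[int, int]]
    col_blocks: dict[str, tuple[int, int]]
    weights: dict[tuple[str, str], float]
    pixel_index: dict[str, np.ndarray]
    shapes: dict[str, tuple[int, int]]
    axes: dict[str, np.ndarray]

    @property
    def samples(self) -> list[str]:
        return list(self.row_blocks)

    @property
    def modalities(self) -> list[str]:
        return list(self.col_blocks)

    @property
    def n_blocks(self) -> int:
        return len(self.row_blocks) * len(self.col_blocks)

    def get_block(self, sample_id: str, modality: str) -> np.ndarray:
        r0, r1 = self.row_blocks[sample_id]
        c0, c1 = self.col_blocks[modality]
        return self.M[r0:r1, c0:c1]

    def row_slice(self, sample_id: str) -> slice:
        r0, r1 = self.row_blocks[sample_id]
        return slice(r0, r1)

    def col_slice(self, modality: str) -> slice:
        c0, c1 = self.col_blocks[modality]
        return slice(c0, c1)

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("M", data=self.M)
            for sid, (r0, r1) in self.row_blocks.items():
                g = f.require_group(f"rows/{sid}")
                g.attrs["range"] = (r0, r1)
                g.attrs["shape"] = self.shapes[sid]
                g.create_dataset("pixel_index", data=self.pixel_index[sid])
            for mod, (c0, c1) in self.col_blocks.items():
                g = f.require_group(f"cols/{mod}")
                g.attrs["range"] = (c0, c1)
                g.create_dataset("axis", data=self.axes[mod])
            wg = f.require_group("weights")
            for (sid, mod), w in self.weights.items():
                wg.attrs[f"{sid}::{mod}"] = w

    @classmethod
    def load(cls, path: str | Path) -> "Multiset":
        with h5py.File(path, "r") as f:
            M = f["M"][()]
            row_blocks, shapes, pixel_index = {}, {}, {}
            for sid in f["rows"]:
                g = f[f"rows/{sid}"]
                row_blocks[sid] = tuple(int(v) for v in g.attrs["range"])
                shapes[sid] = tuple(int(v) for v in g.attrs["shape"])
                pixel_index[sid] = g["pixel_index"][()]
            col_blocks, axes = {}, {}
            for mod in f["cols"]:
                g = f[f"cols/{mod}"]
                col_blocks[mod] = tuple(int(v) for v in g.attrs["range"])
                axes[mod] = g["axis"][()]
            weights = {}
            for key, w in f["weights"].attrs.items():
                sid, mod = key.split("::")
                weights[(sid, mod)] = float(w)
        # restore insertion order by range start
        row_blocks = dict(sorted(row_blocks.items(), key=lambda kv: kv[1][0]))
        col_blocks = dict(sorted(col_blocks.items(), key=lambda kv: kv[1][0]))
        return cls(M, row_blocks, col_blocks, weights, pixel_index, shapes, axes)


def assemble(blocks: dict[tuple[str, str], UnfoldedBlock]) -> Multiset:
    """Assemble (sample, modality) blocks into the augmented matrix.

    Sample order and modality order follow first appearance in the input
    mapping.  Within a sample all platform blocks must share the identical
    pixel index (congruency); within a modality all sample blocks must
    share the spectral axis.
    """
    if not blocks:
        raise ValueError("no blocks to assemble")
    samples: list[str] = []
    modalities: list[str] = []
    for sid, mod in blocks:
        if sid not in samples:
            samples.append(sid)
        if mod not in modalities:
            modalities.append(mod)
    for sid in samples:
        for mod in modalities:
            if (sid, mod) not in blocks:
                raise ValueError(f"missing block for sample {sid!r}, modality {mod!r}")

    pixel_index: dict[str, np.ndarray] = {}
    shapes: dict[str, tuple[int, int]] = {}
    for sid in samples:
        ref = blocks[(sid, modalities[0])]
        for mod in modalities[1:]:
            b = blocks[(sid, mod)]
            if b.pixel_index.shape != ref.pixel_index.shape or not np.array_equal(
                b.pixel_index, ref.pixel_index
            ):
                raise ValueError(
                    f"pixel congruency violated in sample {sid!r}: "
                    f"{mod!r} block does not share the reference pixel index"
                )
        pixel_index[sid] = ref.pixel_index.copy()
        shapes[sid] = tuple(ref.shape)

    axes: dict[str, np.ndarray] = {}
    for mod in modalities:
        ref = blocks[(samples[0], mod)]
        for sid in samples[1:]:
            b = blocks[(sid, mod)]
            if b.axis.shape != ref.axis.shape or not np.allclose(b.axis, ref.axis):
                raise ValueError(
                    f"axis mismatch in modality {mod!r}: sample {sid!r} differs"
                )
        axes[mod] = ref.axis.copy()

    row_blocks: dict[str, tuple[int, int]] = {}
    r = 0
    for sid in samples:
        n = blocks[(sid, modalities[0])].n_pixels
        row_blocks[sid] = (r, r + n)
        r += n
    col_blocks: dict[str, tuple[int, int]] = {}
    c = 0
    for mod in modalities:
        n = blocks[(samples[0], mod)].n_channels
        col_blocks[mod] = (c, c + n)
        c += n

    M = np.zeros((r, c))
    weights: dict[tuple[str, str], float] = {}
    for sid in samples:
        r0, r1 = row_blocks[sid]
        for mod in modalities:
            c0, c1 = col_blocks[mod]
            b = blocks[(sid, mod)]
            M[r0:r1, c0:c1] = b.D
            weights[(sid, mod)] = b.weight_applied
    return Multiset(
        M=M,
        row_blocks=row_blocks,
        col_blocks=col_blocks,
        weights=weights,
        pixel_index=pixel_index,
        shapes=shapes,
        axes=axes,
    )
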