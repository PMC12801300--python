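"""Memory-lean grid containers.

Wide regions of the ray-traced volume are pure solvent and never touched, so
dense per-voxel arrays waste most of their footprint.  Two containers exploit
that sparsity while staying behaviorally identical to dense arrays:

* :class:`StatusMap` - a bilevel in/out/boundary/cavity grid.  The first level
  is a uniform coarse grid at one quarter of the target resolution; a coarse
  cell holds nothing until a voxel inside it is written, at which point a
  4x4x4 fine block is allocated.  Statuses pack two bits each into 32-bit
  words (64 voxels = four words per block).
* :class:`BitBuffer` - a flat boolean buffer packing 32 booleans per 32-bit
  word.

Index arithmetic is all power-of-two (``>> 2``/``& 3`` for blocks,
``>> 5``/``& 31`` for bits).  Grid dimensions need not be multiples of four:
edge blocks are full 4x4x4 blocks whose out-of-range lanes are simply unused.
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np

__all__ = ["Status", "StatusMap", "BitBuffer", "BilevelIntGrid", "VertexIndexMap"]


class Status(IntEnum):
    OUTSIDE = 0
    INSIDE = 1
    BOUNDARY = 2
    CAVITY = 3


_BLOCK_WORDS = 4  # 64 voxels * 2 bits / 32


class StatusMap:
    """Bilevel status grid over ``dims`` fine voxels (node counts)."""

    def __init__(self, dims: tuple[int, int, int]):
        nx, ny, nz = (int(d) for d in dims)
        if min(nx, ny, nz) < 1:
            raise ValueError("StatusMap dims must be positive")
        self.dims = (nx, ny, nz)
        self._blocks: dict[tuple[int, int, int], np.ndarray] = {}

    # -- scalar access -----------------------------------------------------
    def _check(self, i: int, j: int, k: int) -> None:
        nx, ny, nz = self.dims
        if not (0 <= i < nx and 0 <= j < ny and 0 <= k < nz):
            raise IndexError(f"voxel index ({i},{j},{k}) outside dims {self.dims}")

    def get(self, i: int, j: int, k: int) -> Status:
        self._check(i, j, k)
        block = self._blocks.get((i >> 2, j >> 2, k >> 2))
        if block is None:
            return Status.OUTSIDE
        idx = ((i & 3) << 4) | ((j & 3) << 2) | (k & 3)
        word = int(block[idx >> 4])
        return Status((word >> ((idx & 15) << 1)) & 3)

    def set(self, i: int, j: int, k: int, value: Status) -> None:
        self._check(i, j, k)
        key = (i >> 2, j >> 2, k >> 2)
        block = self._blocks.get(key)
        if block is None:
            block = np.zeros(_BLOCK_WORDS, dtype=np.uint32)
            self._blocks[key] = block
        idx = ((i & 3) << 4) | ((j & 3) << 2) | (k & 3)
        shift = np.uint32((idx & 15) << 1)
        w = idx >> 4
        block[w] = (block[w] & ~(np.uint32(3) << shift)) | (np.uint32(int(value) & 3) << shift)

    @property
    def allocated_blocks(self) -> int:
        return len(self._blocks)

    # -- bulk conversion ---------------------------------------------------
    def to_dense(self) -> np.ndarray:
        """Dense uint8 array of :class:`Status` values, elementwise equal to
        ``get``."""
        nx, ny, nz = self.dims
        dense = np.zeros((nx, ny, nz), dtype=np.uint8)
        shifts = (np.arange(16, dtype=np.uint32) << 1)
        for (bi, bj, bk), block in self._blocks.items():
            # Unpack the four words into a 4x4x4 cube of 2-bit lanes.
            vals = ((block[:, None] >> shifts[None, :]) & 3).astype(np.uint8).reshape(4, 4, 4)
            i0, j0, k0 = bi << 2, bj << 2, bk << 2
            di = min(4, nx - i0)
            dj = min(4, ny - j0)
            dk = min(4, nz - k0)
            dense[i0 : i0 + di, j0 : j0 + dj, k0 : k0 + dk] = vals[:di, :dj, :dk]
        return dense

    @classmethod
    def from_dense(cls, dense: np.ndarray) -> "StatusMap":
        """Pack a dense status array; only blocks containing a non-outside
        voxel are allocated."""
        dense = np.asarray(dense, dtype=np.uint8)
        m = cls(dense.shape)
        nx, ny, nz = dense.shape
        px, py, pz = (-nx) % 4, (-ny) % 4, (-nz) % 4
        padded = np.pad(dense, ((0, px), (0, py), (0, pz)))
        cx, cy, cz = padded.shape[0] // 4, padded.shape[1] // 4, padded.shape[2] // 4
        cubes = padded.reshape(cx, 4, cy, 4, cz, 4).transpose(0, 2, 4, 1, 3, 5)
        occupied = np.argwhere(cubes.reshape(cx, cy, cz, 64).any(axis=-1))
        shifts = (np.arange(16, dtype=np.uint32) << 1)
        for bi, bj, bk in occupied:
            lanes = cubes[bi, bj, bk].reshape(4, 16).astype(np.uint32)
            words = np.bitwise_or.reduce(lanes << shifts[None, :], axis=1).astype(np.uint32)
            m._blocks[(int(bi), int(bj), int(bk))] = words
        return m


class BitBuffer:
    """Packed boolean buffer: 32 booleans per unsigned 32-bit word."""

    def __init__(self, length: int):
        if length < 0:
            raise ValueError("length must be non-negative")
        self.length = int(length)
        self.words = np.zeros((self.length + 31) >> 5, dtype=np.uint32)

    def _check(self, i: int) -> None:
        if not 0 <= i < self.length:
            raise IndexError(f"bit index {i} outside length {self.length}")

    def get(self, i: int) -> bool:
        self._check(i)
        return bool((self.words[i >> 5] >> np.uint32(i & 31)) & 1)

    def set(self, i: int, value: bool = True) -> None:
        self._check(i)
        w, b = i >> 5, np.uint32(i & 31)
        if value:
            self.words[w] |= np.uint32(1) << b
        else:
            self.words[w] &= ~(np.uint32(1) << b)

    def to_array(self) -> np.ndarray:
        bits = (self.words[:, None] >> np.arange(32, dtype=np.uint32)[None, :]) & 1
        return bits.reshape(-1)[: self.length].astype(bool)

    def any(self) -> bool:
        return bool(self.words.any())

    def count(self) -> int:
        return int(self.to_array().sum())


class BilevelIntGrid:
    """Bilevel grid of int32 payloads (default -1), same 4x4x4 block scheme as
    :class:`StatusMap`.  Used to index mesh vertices by grid edge."""

    def __init__(self, dims: tuple[int, int, int]):
        nx, ny, nz = (int(d) for d in dims)
        self.dims = (nx, ny, nz)
        self._blocks: dict[tuple[int, int, int], np.ndarray] = {}

    def get(self, i: int, j: int, k: int) -> int:
        block = self._blocks.get((i >> 2, j >> 2, k >> 2))
        if block is None:
            return -1
        return int(block[((i & 3) << 4) | ((j & 3) << 2) | (k & 3)])

    def set(self, i: int, j: int, k: int, value: int) -> None:
        key = (i >> 2, j >> 2, k >> 2)
        block = self._blocks.get(key)
        if block is None:
            block = np.full(64, -1, dtype=np.int32)
            self._blocks[key] = block
        block[((i & 3) << 4) | ((j & 3) << 2) | (k & 3)] = value


class VertexIndexMap:
    """Joint vertex/normal index over grid edges.

    One bilevel grid per edge direction maps the edge (keyed by its lower
    node) to the mesh vertex index; the vertex's normal lives in the mesh
    arrays at the same index, so a single structure serves both.  An edge is
    written at most once per build.
    """

    def __init__(self, dims: tuple[int, int, int]):
        self.grids = tuple(BilevelIntGrid(dims) for _ in range(3))

    def get(self, direction: int, i: int, j: int, k: int) -> int:
        return self.grids[direction].get(i, j, k)

    def put(self, direction: int, i: int, j: int, k: int, index: int) -> None:
        if self.grids[direction].get(i, j, k) != -1:
            raise ValueError("grid edge written twice in one build")
        self.grids[direction].set(i, j, k, index)
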