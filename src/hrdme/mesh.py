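"""Nested stack of Cartesian cubic meshes on a cube.

Level 0 is the coarsest mesh: a single voxel covering the whole domain.
Each refinement halves the voxel width, so level ``l`` is a ``2**l`` per
axis grid with ``(2**l)**3`` voxels, and every voxel is fully contained in
exactly one voxel of the next coarser level (its *parent*) and tiles into
the 8 voxels of the next finer level (its *children*).  Parent/child maps
therefore reduce to integer index arithmetic and nothing is stored.

Diffusion on a fixed level is a jump process between face-adjacent voxels
with per-face rate ``D / h**2``.  Boundaries are reflective: absent faces
are simply removed from the neighbor list, which reduces the total jump
rate of boundary voxels and preserves the uniform stationary distribution
on the closed domain (the well-mixed limit).  Indexing is 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

__all__ = ["VoxelRef", "MeshHierarchy"]

#: Face-neighbor offsets in 3D.
_FACES = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))


@dataclass(frozen=True, order=True)
class VoxelRef:
    """A voxel identified by its mesh level and integer grid indices."""

    level: int
    ijk: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ValueError(f"level must be nonnegative, got {self.level}")
        n = 1 << self.level
        if len(self.ijk) != 3 or any(not (0 <= c < n) for c in self.ijk):
            raise ValueError(f"indices {self.ijk} out of bounds for level {self.level}")


class MeshHierarchy:
    """``n_levels`` nested cubic grids on a cube of the given volume."""

    def __init__(self, n_levels: int, volume: float = 1.0) -> None:
        if n_levels < 1:
            raise ValueError(f"need at least one level, got {n_levels}")
        if volume <= 0:
            raise ValueError(f"volume must be positive, got {volume}")
        self.n_levels = int(n_levels)
        self.volume = float(volume)
        self.side = float(volume) ** (1.0 / 3.0)
        #: per-level voxel width h_l = side / 2**l
        self.widths = self.side / (1 << np.arange(self.n_levels, dtype=np.int64))

    # -- index arithmetic ------------------------------------------------

    def grid_size(self, level: int) -> int:
        """Voxels per axis at ``level`` (= 2**level)."""
        self._check_level(level)
        return 1 << level

    def n_voxels(self, level: int) -> int:
        self._check_level(level)
        return (1 << level) ** 3

    def parent(self, v: VoxelRef) -> VoxelRef:
        """The containing voxel one level coarser."""
        if v.level == 0:
            raise ValueError("the root voxel has no parent")
        return VoxelRef(v.level - 1, tuple(c >> 1 for c in v.ijk))

    def children(self, v: VoxelRef) -> list[VoxelRef]:
        """The 8 voxels one level finer whose union tiles ``v``."""
        if v.level >= self.n_levels - 1:
            raise ValueError(f"level {v.level} is the finest level; no children")
        i, j, k = (c << 1 for c in v.ijk)
        return [
            VoxelRef(v.level + 1, (i + di, j + dj, k + dk))
            for di in (0, 1)
            for dj in (0, 1)
            for dk in (0, 1)
        ]

    def ancestor_at(self, v: VoxelRef, level: int) -> VoxelRef:
        """The containing voxel at the (coarser or equal) target ``level``."""
        self._check_level(level)
        if level > v.level:
            raise ValueError(f"level {level} is finer than the voxel's level {v.level}")
        shift = v.level - level
        return VoxelRef(level, tuple(c >> shift for c in v.ijk))

    def descendants(self, v: VoxelRef, level: int) -> Iterator[VoxelRef]:
        """All voxels at the (finer or equal) ``level`` contained in ``v``."""
        self._check_level(level)
        if level < v.level:
            raise ValueError(f"level {level} is coarser than the voxel's level {v.level}")
        shift = level - v.level
        base = tuple(c << shift for c in v.ijk)
        n = 1 << shift
        for di in range(n):
            for dj in range(n):
                for dk in range(n):
                    yield VoxelRef(level, (base[0] + di, base[1] + dj, base[2] + dk))

    def neighbors(self, v: VoxelRef) -> list[VoxelRef]:
        """Face-adjacent voxels on the same level (reflective boundary).

        An interior voxel has 6 neighbors, a face voxel 5, an edge voxel 4,
        a corner 3; the level-0 root has none.
        """
        self._check_level(v.level)
        n = 1 << v.level
        out = []
        i, j, k = v.ijk
        for di, dj, dk in _FACES:
            a, b, c = i + di, j + dj, k + dk
            if 0 <= a < n and 0 <= b < n and 0 <= c < n:
                out.append(VoxelRef(v.level, (a, b, c)))
        return out

    # -- diffusion rates -------------------------------------------------

    def face_rate(self, D: float, level: int) -> float:
        """Jump rate across one face at ``level``: D / h_l**2."""
        self._check_level(level)
        if level == 0:
            return 0.0
        return D / float(self.widths[level]) ** 2

    def jump_rate(self, D: float, v: VoxelRef) -> float:
        """Total diffusion firing rate for a molecule in voxel ``v``.

        ``(number of existing neighbors) * D / h**2``; the jump target is
        then chosen uniformly among the existing neighbors.
        """
        return len(self.neighbors(v)) * self.face_rate(D, v.level)

    def voxel_center(self, v: VoxelRef) -> np.ndarray:
        h = float(self.widths[v.level])
        return (np.asarray(v.ijk, dtype=float) + 0.5) * h

    # -- reporting -------------------------------------------------------

    def summary(self, species: dict[str, float] | None = None) -> str:
        """Plain-text per-level report: voxel counts, widths and, when a
        ``{name: D}`` map is given, per-species interior jump rates."""
        lines = [f"mesh hierarchy: {self.n_levels} levels on a cube of volume "
                 f"{self.volume:g} (side {self.side:g})"]
        header = f"{'level':>5} {'grid':>8} {'voxels':>10} {'width':>12}"
        if species:
            header += "".join(f" {f'6D/h^2 [{n}]':>16}" for n in species)
        lines.append(header)
        for l in range(self.n_levels):
            row = (f"{l:>5} {self.grid_size(l):>7}^3 {self.n_voxels(l):>10} "
                   f"{self.widths[l]:>12.6g}")
            if species:
                row += "".join(f" {6.0 * self.face_rate(D, l):>16.6g}"
                               for D in species.values())
            lines.append(row)
        return "\n".join(lines)

    def _check_level(self, level: int) -> None:
        if not 0 <= level < self.n_levels:
            raise ValueError(f"level {level} outside [0, {self.n_levels})")

    def __repr__(self) -> str:  # pragma: no cover
        return f"MeshHierarchy(n_levels={self.n_levels}, volume={self.volume})"
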