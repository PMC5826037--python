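"""Overlapping-cube grids for local refinement, and the grid-size heuristic.

Local clustering runs inside overlapping cubes of edge ``g`` whose origins
step by ``stride`` along each axis (default ``ceil(g / 2)``, i.e. 50%
overlap).  The last cube on each axis is moved so it ends exactly at the
volume boundary; cubes never extend outside the volume, every voxel is
covered at least once, and at the default stride by at most 2 cubes per axis
(8 overall).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .errors import ParameterError

__all__ = ["GridSpec", "build_grid", "suggest_grid_size"]


@dataclass
class GridSpec:
    """Cube origins (list of (z, y, x) int tuples), edge and stride."""

    origins: list
    edge: tuple[int, int, int]  #: per-axis cube edge (clamped to the extent)
    stride: int
    shape: tuple[int, int, int]

    def __len__(self) -> int:
        return len(self.origins)

    def slices(self, origin) -> tuple[slice, slice, slice]:
        return tuple(slice(o, o + e) for o, e in zip(origin, self.edge))

    def coverage_count(self) -> np.ndarray:
        """How many cubes cover each voxel."""
        count = np.zeros(self.shape, dtype=np.int32)
        for origin in self.origins:
            count[self.slices(origin)] += 1
        return count


def _axis_origins(extent: int, g: int, stride: int) -> list[int]:
    if extent <= g:
        return [0]
    last = extent - g
    origins = list(range(0, last + 1, stride))
    if origins[-1] != last:
        prev = origins[-2] if len(origins) > 1 else 0
        if len(origins) > 1 and last - prev <= g:
            origins[-1] = last  # keep <= 2 cubes/axis at default stride
        else:
            origins.append(last)  # appending always preserves coverage
    return origins


def build_grid(shape, g: int, stride: int | None = None) -> GridSpec:
    """Enumerate cube origins for a volume of the given shape.

    ``g`` may exceed an axis extent, in which case the cube is clamped to
    that extent (a single cube spans the axis).
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or min(shape) < 1:
        raise ParameterError(f"shape must be 3 positive extents, got {shape}")
    if g < 3:
        raise ParameterError(f"grid size must be >= 3, got {g}")
    if stride is None:
        stride = -(-g // 2)
    if not 1 <= stride <= g:
        raise ParameterError(f"stride must be in [1, {g}], got {stride}")
    edge = tuple(min(g, s) for s in shape)
    per_axis = [_axis_origins(s, e, stride) for s, e in zip(shape, edge)]
    origins = [tuple(o) for o in product(*per_axis)]
    return GridSpec(origins=origins, edge=edge, stride=stride, shape=shape)


def suggest_grid_size(structure_width: float, voxel_size_um: float | None = None,
                      margin: int = 2) -> int:
    """Recommended grid size for a structure of known width.

    The grid should be slightly larger than the largest dimension of the
    phase of interest, so the local clustering does not hunt for sub-classes
    inside it: ``round(width_in_voxels) + margin``, floored at 3.

    ``structure_width`` is in micrometres when ``voxel_size_um`` is given,
    otherwise already in voxels.  Example: a 40 um wire at 7.86 um voxels is
    ~5 voxels wide, giving a grid size of 7 with the default margin of 2.
    """
    if not structure_width > 0:
        raise ParameterError("structure width must be > 0")
    if margin < 1:
        raise ParameterError("margin must be >= 1")
    width_vox = structure_width
    if voxel_size_um is not None:
        if not voxel_size_um > 0:
            raise ParameterError("voxel_size_um must be > 0")
        width_vox = structure_width / voxel_size_um
    return max(3, int(np.rint(width_vox)) + int(margin))
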