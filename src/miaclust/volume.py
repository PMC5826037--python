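"""In-memory containers for grayscale, label and membership volumes.

All volumes are indexed ``(z, y, x)`` throughout the package and carry an
isometric voxel edge length in micrometres.  Intensities are non-negative and
bounded by the declared bit depth (8- or 16-bit unsigned convention, the two
ranges micro-CT reconstructions are exported in).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

__all__ = ["Volume", "LabelVolume", "MembershipField"]


def _check_3d(arr: np.ndarray, name: str) -> None:
    if arr.ndim != 3:
        raise ParameterError(f"{name} must be 3-dimensional, got ndim={arr.ndim}")
    if min(arr.shape) < 1:
        raise ParameterError(f"{name} has an empty axis: shape={arr.shape}")


@dataclass
class Volume:
    """A 3D grayscale scan (or phantom) with voxel-size metadata.

    Parameters
    ----------
    data
        3D array of non-negative finite intensities, indexed ``(z, y, x)``.
    voxel_size_um
        Isometric voxel edge length in micrometres; must be positive.
    bit_depth
        8 or 16; declares the intensity range ``[0, 2**bit_depth - 1]``.
    """

    data: np.ndarray
    voxel_size_um: float
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        _check_3d(self.data, "Volume.data")
        if self.bit_depth not in (8, 16):
            raise ParameterError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if not float(self.voxel_size_um) > 0:
            raise ParameterError(f"voxel_size_um must be > 0, got {self.voxel_size_um}")
        self.voxel_size_um = float(self.voxel_size_um)
        if np.issubdtype(self.data.dtype, np.floating):
            if not np.isfinite(self.data).all():
                raise ParameterError("Volume intensities must be finite")
        lo = self.data.min()
        hi = self.data.max()
        if lo < 0:
            raise ParameterError(f"Volume intensities must be >= 0, min={lo}")
        if hi > 2**self.bit_depth - 1:
            raise ParameterError(
                f"Volume intensities exceed {self.bit_depth}-bit range (max={hi})"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def max_value(self) -> int:
        """Largest representable intensity at the declared bit depth."""
        return 2**self.bit_depth - 1

    def with_data(self, data: np.ndarray) -> "Volume":
        """Same metadata, new voxel data."""
        return Volume(data, self.voxel_size_um, self.bit_depth)


@dataclass
class LabelVolume:
    """Per-voxel integer class labels.

    Label ``0`` is reserved for background / masked / sub-threshold voxels;
    labels ``1..n_classes`` are material classes ordered by ascending class
    center intensity (so ``n_classes`` is always the brightest class).
    """

    labels: np.ndarray
    n_classes: int
    voxel_size_um: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        _check_3d(self.labels, "LabelVolume.labels")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ParameterError("labels must be an integer array")
        if self.n_classes < 1:
            raise ParameterError(f"n_classes must be >= 1, got {self.n_classes}")
        if not float(self.voxel_size_um) > 0:
            raise ParameterError("voxel_size_um must be > 0")
        self.voxel_size_um = float(self.voxel_size_um)
        lo, hi = int(self.labels.min()), int(self.labels.max())
        if lo < 0 or hi > self.n_classes:
            raise ParameterError(
                f"labels must lie in 0..{self.n_classes}, got range [{lo}, {hi}]"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


@dataclass
class MembershipField:
    """Per-voxel fuzzy class-membership probabilities.

    ``memberships`` has shape ``(n_classes, nz, ny, nx)``; for in-mask voxels
    the class vector sums to one, outside the mask it is identically zero.
    Class axis order follows ascending class-center intensity.
    """

    memberships: np.ndarray
    mask: np.ndarray
    voxel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.memberships = np.asarray(self.memberships)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.memberships.ndim != 4:
            raise ParameterError("memberships must have shape (C, nz, ny, nx)")
        _check_3d(self.mask, "MembershipField.mask")
        if self.memberships.shape[1:] != self.mask.shape:
            raise ParameterError("memberships and mask shapes disagree")
        self.voxel_size_um = float(self.voxel_size_um)

    @property
    def n_classes(self) -> int:
        return self.memberships.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    def validate(self, atol: float = 1e-6) -> None:
        """Assert the probabilistic invariants (cheap checks are done at
        construction; this one touches every voxel)."""
        u = self.memberships
        if u.min() < -atol or u.max() > 1 + atol:
            raise ParameterError("memberships outside [0, 1]")
        sums = u.sum(axis=0)
        if self.mask.any() and np.abs(sums[self.mask] - 1.0).max() > atol:
            raise ParameterError("in-mask membership vectors must sum to 1")
        if (~self.mask).any() and np.abs(sums[~self.mask]).max() > atol:
            raise ParameterError("out-of-mask memberships must be 0")
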