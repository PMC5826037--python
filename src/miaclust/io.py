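"""Reading and writing volumes as NIfTI-1 or multi-page TIFF.

Arrays are stored ``(z, y, x)`` in memory.  NIfTI files keep the conventional
``(x, y, z)`` on-disk order, so axes are transposed on the way in and out;
TIFF stacks are written one page per z-slice.  Intensities are never rescaled.

Voxel size comes from the file header (NIfTI ``pixdim``; for TIFF the
ImageJ-style ``spacing`` plus resolution tags this module itself writes).  An
explicit ``voxel_size_um`` override always wins, with a warning logged when it
contradicts the header.  Unit conventions of third-party micro-CT exports vary,
which is exactly why the override exists.
"""

from __future__ import annotations

import logging
import os
from fractions import Fraction

import nibabel as nib
import numpy as np
import tifffile

from .errors import AnisotropyError, FormatError, ParameterError
from .volume import LabelVolume, MembershipField, Volume

__all__ = ["read_volume", "write_volume"]

log = logging.getLogger(__name__)

#: relative tolerance on voxel-spacing isometry
_ISO_RTOL = 1e-3


def _infer_format(path: str, format: str) -> str:
    if format != "auto":
        return format
    name = str(path).lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".tif", ".tiff")):
        return "tiff"
    raise FormatError(f"cannot infer volume format from file name: {path}")


def _check_isometric(spacings, path) -> float:
    s = np.asarray(spacings, dtype=float)
    if not (s > 0).all():
        raise FormatError(f"non-positive voxel spacing in header of {path}")
    if (s.max() - s.min()) / s.max() > _ISO_RTOL:
        raise AnisotropyError(
            f"anisotropic voxel spacing {tuple(s)} in {path}; the clustering "
            "and thickness modules assume isometric voxels"
        )
    return float(s.mean())


def _squeeze_to_3d(data: np.ndarray, path) -> np.ndarray:
    # common exporter quirk: trailing singleton (time / channel) dimension
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(
            f"{path}: expected a 3D volume, got {data.ndim} non-singleton "
            "dimension(s)"
        )
    return data


def _resolve_voxel_size(header_vs, override, path) -> float:
    if override is not None:
        if not override > 0:
            raise ParameterError("voxel_size_um override must be > 0")
        if header_vs is not None and abs(header_vs - override) > 1e-6 * override:
            log.warning(
                "voxel size override %g um differs from header value %g in %s",
                override, header_vs, path,
            )
        return float(override)
    if header_vs is None:
        raise FormatError(
            f"{path}: no voxel size in header; pass voxel_size_um explicitly"
        )
    return float(header_vs)


def read_volume(path, format: str = "auto", voxel_size_um: float | None = None) -> Volume:
    """Read a 3D grayscale volume.

    Parameters
    ----------
    path
        ``.nii`` / ``.nii.gz`` or ``.tif`` / ``.tiff`` file.
    format
        ``"nifti"``, ``"tiff"`` or ``"auto"`` (by extension).
    voxel_size_um
        Optional override of the header voxel size (see module docstring).
    """
    fmt = _infer_format(path, format)
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    if fmt == "nifti":
        return _read_nifti(path, voxel_size_um)
    return _read_tiff(path, voxel_size_um)


def _read_nifti(path, override) -> Volume:
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = _squeeze_to_3d(data, path)
    zooms = img.header.get_zooms()[:3]
    header_vs = _check_isometric(zooms, path)
    vs = _resolve_voxel_size(header_vs, override, path)
    data = np.transpose(data, (2, 1, 0))  # (x,y,z) on disk -> (z,y,x)
    return Volume(data, voxel_size_um=vs, bit_depth=_bit_depth_of(data))


def _read_tiff(path, override) -> Volume:
    try:
        with tifffile.TiffFile(str(path)) as tif:
            data = tif.asarray()
            header_vs = _tiff_voxel_size(tif)
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot read TIFF file {path}: {exc}") from exc
    data = _squeeze_to_3d(data, path)
    vs = _resolve_voxel_size(header_vs, override, path)
    return Volume(data, voxel_size_um=vs, bit_depth=_bit_depth_of(data))


def _tiff_voxel_size(tif: "tifffile.TiffFile"):
    meta = tif.imagej_metadata or {}
    spacing = meta.get("spacing")  # z-step, in the writer's unit (um here)
    page = tif.pages[0]
    xres = page.tags.get("XResolution")
    yres = page.tags.get("YResolution")
    if spacing is None or xres is None or yres is None:
        return None
    sx = float(Fraction(*xres.value))  # pixels per unit
    sy = float(Fraction(*yres.value))
    if sx <= 0 or sy <= 0:
        return None
    return _check_isometric((float(spacing), 1.0 / sy, 1.0 / sx), "TIFF header")


def _bit_depth_of(data: np.ndarray) -> int:
    if data.dtype == np.uint8:
        return 8
    return 16


def write_volume(volume, path, format: str = "auto") -> None:
    """Write a :class:`Volume`, :class:`LabelVolume` or a single membership
    channel to ``path``.

    Labels are stored as unsigned integers, membership channels as 32-bit
    floats in ``[0, 1]``; a round trip through :func:`read_volume` reproduces
    the data exactly (floats to ~1e-7) and the voxel size to 1e-6 relative.
    """
    fmt = _infer_format(path, format)
    if isinstance(volume, LabelVolume):
        dtype = np.uint8 if volume.n_classes <= 255 else np.uint16
        data = volume.labels.astype(dtype)
        vs = volume.voxel_size_um
    elif isinstance(volume, MembershipField):
        raise ParameterError(
            "write one membership channel at a time: write_volume accepts a "
            "Volume whose data is mf.memberships[c]"
        )
    elif isinstance(volume, Volume):
        data = volume.data
        if np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float32)
        vs = volume.voxel_size_um
    else:
        raise ParameterError(f"unsupported object for write_volume: {type(volume)}")

    parent = os.path.dirname(os.path.abspath(str(path)))
    if not os.path.isdir(parent) or not os.access(parent, os.W_OK):
        raise FormatError(f"cannot write to directory {parent}")

    if fmt == "nifti":
        affine = np.diag([vs, vs, vs, 1.0])
        img = nib.Nifti1Image(np.transpose(data, (2, 1, 0)), affine)
        img.header.set_zooms((vs, vs, vs))
        nib.save(img, str(path))
    else:
        tifffile.imwrite(
            str(path),
            data,
            imagej=True,
            resolution=(1.0 / vs, 1.0 / vs),
            metadata={"spacing": vs, "unit": "um", "axes": "ZYX"},
        )
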