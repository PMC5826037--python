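"""Seeded ground-truth phantoms for validating segmentation and thickness.

Three geometries:

``plate_coil``
    A helical band (a coiled flat ribbon, like a machined wire of
    rectangular cross-section wound into a spring) of known uniform
    thickness, in air.  The thin dimension lies along the coil axis (z),
    tilted only by the small pitch angle, and the band height is widened by
    ``1 / cos`` of that angle so the thickness *normal to the band* equals
    ``thickness_vox`` exactly, everywhere away from the free rims.  Keeping
    the thin dimension close to the grid axis mirrors how such reference
    objects are scanned and measured in practice: sphere-fitting thickness
    on a voxel grid resolves an axis-aligned plate exactly, while a plate
    rotating through oblique orientations carries an irreducible
    digitization bias of a few percent at this thickness.
``trabecular_lattice``
    A connected rod lattice (rods of the stated thickness along all three
    axes) that approximates trabecular struts.
``fossil_like``
    The lattice (bone phase) embedded in an ellipsoidal matrix that is
    *brighter* than bone, with crack slits at background level — the classic
    fossil pathology where invasive sediment out-attenuates the bone.

Artifacts are applied in a fixed order: geometry -> multiplicative
center-bright radial ramp (``1 + a * (1 - r / r_max)`` on non-background
voxels, emulating the inverse-beam-hardening gradient of dense specimens)
-> bright inclusions -> additive Gaussian noise -> clip to bit depth.
A single ``numpy.random.default_rng(seed)`` stream drives inclusions and
noise, so an identical spec yields a bit-identical volume.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import GeometryError, ParameterError
from .segmenter import binarize
from .volume import LabelVolume, Volume

__all__ = ["PhantomSpec", "PhantomTruth", "make_phantom", "phantom_report"]

_KINDS = ("plate_coil", "trabecular_lattice", "fossil_like")


@dataclass
class PhantomSpec:
    """Geometry, intensity levels, artifact strengths and the RNG seed.

    Intensity levels are in the declared bit-depth range.  ``thickness_vox``
    is the known structure thickness (band width / rod diameter) in voxels.
    Geometry knobs with ``None`` defaults are derived from the thickness:
    coil pitch ``3 t``, coil inner radius ``4 t``, lattice spacing ``3 t``.
    """

    kind: str
    shape: tuple[int, int, int]
    thickness_vox: float = 5.0
    foreground_level: float = 30000.0
    background_level: float = 0.0
    matrix_level: float | None = None
    gradient_amplitude: float = 0.0
    noise_sd: float = 0.0
    inclusion_density: float = 0.0
    seed: int = 0
    bit_depth: int = 16
    voxel_size_um: float = 1.0
    coil_pitch: float | None = None
    coil_inner_radius: float | None = None
    lattice_spacing: float | None = None
    edge_margin: int = 5

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ParameterError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or min(self.shape) < 1:
            raise ParameterError(f"shape must be 3 positive extents: {self.shape}")
        if self.thickness_vox < 2:
            raise ParameterError("thickness_vox must be >= 2")
        maxval = 2**self.bit_depth - 1
        levels = [self.foreground_level, self.background_level]
        if self.kind == "fossil_like":
            if self.matrix_level is None:
                raise ParameterError("fossil_like requires matrix_level")
            if not self.matrix_level > self.foreground_level:
                raise ParameterError(
                    "fossil_like matrix must be brighter than bone "
                    f"({self.matrix_level} <= {self.foreground_level})"
                )
            levels.append(self.matrix_level)
        for lv in levels:
            if not 0 <= lv <= maxval:
                raise ParameterError(
                    f"level {lv} outside {self.bit_depth}-bit range"
                )
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if not 0 <= self.inclusion_density < 1:
            raise ParameterError("inclusion_density must be in [0, 1)")

    @property
    def pitch(self) -> float:
        return self.coil_pitch or 3.0 * self.thickness_vox

    @property
    def inner_radius(self) -> float:
        return self.coil_inner_radius or 4.0 * self.thickness_vox

    @property
    def spacing(self) -> float:
        return self.lattice_spacing or 3.0 * self.thickness_vox


@dataclass
class PhantomTruth:
    """A generated volume with its ground truth."""

    volume: Volume
    true_mask: np.ndarray        #: the structure (wire band / bone phase)
    true_labels: LabelVolume     #: all phases, ascending by clean intensity
    inclusion_mask: np.ndarray   #: voxels overwritten by bright specks
    spec: PhantomSpec


def _coil_mask(spec: PhantomSpec) -> np.ndarray:
    nz, ny, nx = spec.shape
    t, pitch, r0 = spec.thickness_vox, spec.pitch, spec.inner_radius
    if pitch <= t + 1:
        raise GeometryError("coil pitch must exceed the band thickness")
    m = spec.edge_margin
    r_end = min(ny, nx) / 2.0 - m
    if r_end <= r0 + t:
        raise GeometryError(
            f"shape {spec.shape} too small for a coil of thickness {t}"
        )
    if nz - 2 * m < pitch:
        raise GeometryError("z extent too small for one coil winding")
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    z = np.arange(nz)[:, None, None]
    y, x = np.meshgrid(np.arange(ny) - cy, np.arange(nx) - cx, indexing="ij")
    rho = np.hypot(y, x)[None]
    phi = np.mod(np.arctan2(x, y), 2 * np.pi)[None]

    # helicoid winding k: band occupies z in [h, h + t_z) with base height
    # h = m + pitch * (phi/2pi + k); the band height t_z = t / cos(pitch
    # angle) makes the thickness *normal* to the band exactly t
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = pitch / (2 * np.pi * np.maximum(rho, 1e-9))
    t_z = t / np.cos(np.arctan(slope))
    a = z - m - pitch * phi / (2 * np.pi)
    k = np.floor(a / pitch)
    w = a - k * pitch  # z-offset above the winding base, in [0, pitch)
    h = z - w
    in_band = (w < t_z) & (k >= 0)
    # only complete windings: never cut a band by the volume faces
    in_band &= (h >= m - 1e-9) & (h + t_z <= nz - 1 - m + 1e-9)
    in_band &= (rho >= r0) & (rho <= r_end)
    return in_band


def _lattice_mask(spec: PhantomSpec, region: np.ndarray | None = None) -> np.ndarray:
    nz, ny, nx = spec.shape
    t = spec.thickness_vox
    s = spec.spacing
    if s <= t:
        raise GeometryError("lattice spacing must exceed the rod thickness")
    z, y, x = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                          indexing="ij", sparse=True)
    inz = np.mod(z, s) < t
    iny = np.mod(y, s) < t
    inx = np.mod(x, s) < t
    mask = (iny & inx) | (inz & inx) | (inz & iny)  # rods along z, y, x
    if region is not None:
        mask = mask & region
    return mask


def _ellipsoid(shape, scale: float) -> np.ndarray:
    nz, ny, nx = shape
    z, y, x = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                          indexing="ij", sparse=True)
    cz, cy, cx = (nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0
    az, ay, ax_ = scale * nz / 2.0, scale * ny / 2.0, scale * nx / 2.0
    return (((z - cz) / az) ** 2 + ((y - cy) / ay) ** 2
            + ((x - cx) / ax_) ** 2) <= 1.0


def _crack_slits(spec: PhantomSpec, rng: np.random.Generator,
                 region: np.ndarray) -> np.ndarray:
    """A few planar slits (2 voxels wide) through the specimen."""
    nz, ny, nx = spec.shape
    z, y, x = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                          indexing="ij", sparse=False)
    slits = np.zeros(spec.shape, dtype=bool)
    center = np.array([(nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0])
    for _ in range(3):
        normal = rng.normal(size=3)
        normal /= np.linalg.norm(normal)
        offset = rng.uniform(-0.25, 0.25) * min(spec.shape)
        d = ((z - center[0]) * normal[0] + (y - center[1]) * normal[1]
             + (x - center[2]) * normal[2]) - offset
        slits |= np.abs(d) <= 1.0
    return slits & region


def make_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Generate the phantom volume and its ground truth for ``spec``."""
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    clean = np.full(shape, float(spec.background_level))

    if spec.kind == "plate_coil":
        structure = _coil_mask(spec)
        clean[structure] = spec.foreground_level
        labels = np.where(structure, 2, 1).astype(np.int32)
        n_classes = 2
        specimen = structure  # gradient acts on the structure only
    elif spec.kind == "trabecular_lattice":
        structure = _lattice_mask(spec)
        clean[structure] = spec.foreground_level
        labels = np.where(structure, 2, 1).astype(np.int32)
        n_classes = 2
        specimen = structure
    else:  # fossil_like
        outer = _ellipsoid(shape, 0.9)
        bone_region = _ellipsoid(shape, 0.8)
        structure = _lattice_mask(spec, region=bone_region)
        cracks = _crack_slits(spec, rng, outer)
        matrix = outer & ~structure
        structure = structure & ~cracks
        matrix = matrix & ~cracks
        clean[matrix] = spec.matrix_level
        clean[structure] = spec.foreground_level
        labels = np.ones(shape, dtype=np.int32)
        labels[structure] = 2
        labels[matrix] = 3
        n_classes = 3
        specimen = structure | matrix
    if not structure.any():
        raise GeometryError("phantom geometry produced an empty structure")

    # artifact order is fixed: gradient -> inclusions -> noise -> clip
    if spec.gradient_amplitude:
        nz, ny, nx = shape
        z, y, x = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                              indexing="ij", sparse=True)
        cz, cy, cx = (nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0
        r = np.sqrt((z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2)
        # the artifact spans the scanned object, not the padding air around
        # it: normalize by the specimen's own radial extent
        r_max = float((r * specimen).max())
        ramp = 1.0 + spec.gradient_amplitude * np.maximum(1.0 - r / r_max, 0.0)
        clean = np.where(specimen, clean * ramp, clean)

    maxval = 2**spec.bit_depth - 1
    inclusions = np.zeros(shape, dtype=bool)
    if spec.inclusion_density:
        inclusions = (rng.random(shape) < spec.inclusion_density) & specimen
        clean[inclusions] = 0.95 * maxval

    noisy = clean
    if spec.noise_sd:
        noisy = clean + rng.normal(0.0, spec.noise_sd, size=shape)
    data = np.clip(np.rint(noisy), 0, maxval)
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    volume = Volume(data.astype(dtype), spec.voxel_size_um, spec.bit_depth)
    return PhantomTruth(
        volume=volume,
        true_mask=structure,
        true_labels=LabelVolume(labels, n_classes, spec.voxel_size_um),
        inclusion_mask=inclusions,
        spec=replace(spec),
    )


def phantom_report(truth: PhantomTruth, labels: LabelVolume, class_id) -> dict:
    """Voxelwise accuracy of one segmented class against the ground truth.

    Sensitivity, specificity and Dice of ``binarize(labels, class_id)``
    versus ``truth.true_mask``, restricted to non-inclusion voxels (an
    inclusion speck genuinely is not bone, so neither prediction can be
    scored there).
    """
    if labels.shape != truth.true_mask.shape:
        raise ParameterError("label volume shape does not match the phantom")
    pred = binarize(labels, class_id)
    valid = ~truth.inclusion_mask
    truem = truth.true_mask[valid]
    predm = pred[valid]
    tp = int(np.sum(truem & predm))
    fn = int(np.sum(truem & ~predm))
    fp = int(np.sum(~truem & predm))
    tn = int(np.sum(~truem & ~predm))
    sensitivity = tp / (tp + fn) if tp + fn else float("nan")
    specificity = tn / (tn + fp) if tn + fp else float("nan")
    dice = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan")
    return {"sensitivity": sensitivity, "specificity": specificity,
            "dice": dice, "tp": tp, "fp": fp, "fn": fn, "tn": tn}
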