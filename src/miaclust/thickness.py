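"""3D local thickness by maximal-sphere fitting, and parameter sweeps.

Local thickness at a point is the diameter of the largest sphere that
contains the point and lies entirely inside the structure (the
Hildebrand–Rüegsegger definition, what BoneJ's "Thickness" computes for
trabecular morphometry).  The implementation follows the classic three-step
recipe:

1. Euclidean distance transform of the mask.  The inscribed-sphere radius at
   a foreground voxel is taken as ``EDT - 0.5``: the structure boundary runs
   half a voxel beyond the outermost foreground voxel centers, so an n-voxel
   slab measures n, not n + 1.  The volume border counts as background.
2. Distance-ridge reduction: a sphere wholly contained in a neighbor's
   sphere (``r(q) >= r(p) + |p - q|``) is redundant and discarded.
3. Sphere painting: every surviving sphere writes its diameter into the
   voxels it covers; each voxel keeps the maximum.

By default candidate sphere centers are voxel centers, which makes the
result exactly reproducible by exhaustive enumeration.  The optional
``subvoxel_refine`` mode additionally fits the medial apex of the distance
field between voxel centers (a tent fit along 13 lattice directions with
Lipschitz-envelope capping) and paints from the fitted centers; this
reduces the known underestimation of oblique and even-width plates at the
cost of heuristic center placement on junction-heavy structures.

Summary statistics are computed over every foreground voxel (not per medial
sphere), in voxels and in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import EmptyStructureError, ParameterError
from .segmenter import (SegmentationConfig, binarize, segment)
from .preprocess import PreprocessParams
from .volume import Volume

__all__ = ["ThicknessResult", "local_thickness", "thickness_sweep"]


@dataclass
class ThicknessResult:
    """Per-voxel local thickness and its summary statistics."""

    thickness_map: np.ndarray  #: voxels; 0 outside the structure
    voxel_size_um: float
    mean_vox: float
    sd_vox: float
    n_foreground: int

    @property
    def mean_um(self) -> float:
        return self.mean_vox * self.voxel_size_um

    @property
    def sd_um(self) -> float:
        return self.sd_vox * self.voxel_size_um


def _signed_distance(mask: np.ndarray) -> np.ndarray:
    """EDT - 0.5 inside the structure, -(EDT - 0.5) outside."""
    padded = np.pad(mask, 1, mode="constant", constant_values=False)
    inside = ndimage.distance_transform_edt(padded)[1:-1, 1:-1, 1:-1]
    outside = ndimage.distance_transform_edt(~mask)
    return np.where(mask, inside - 0.5, 0.5 - outside)


def _refine_radii(d: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Tent-fit sub-voxel medial refinement of the inscribed radii.

    Sampling sphere centers only at voxel centers underestimates oblique or
    even-width plates by up to a voxel, because the true medial surface runs
    between voxel centers.  Along a line through the medial surface the
    distance field is a tent; the three-point fit
    ``A = d(p) + (d(p+e) - d(p-e)) / 2`` reconstructs the tent apex exactly,
    for any slope, whenever the apex lies within one step of ``p`` — the
    apex is the radius of an inscribed sphere centered near ``p``.  Per
    voxel only the best-aligned direction's fit is kept (deepest concavity
    per unit length ~ cosine of the angle to the surface normal); taking a
    max over all 13 noisy candidates instead would bias the radii upward.

    Returns ``(radii, offsets)``; ``offsets`` has shape ``(3,) + shape`` and
    holds each refined sphere's estimated sub-voxel center displacement from
    its voxel (zero where the plain radius stands).
    """
    refined = np.where(mask, d, 0.0)
    best_score = np.zeros_like(d)
    best_cand = np.zeros_like(d)
    best_off = np.zeros((3,) + d.shape)
    directions = [(1, 0, 0), (0, 1, 0), (0, 0, 1),
                  (1, 1, 0), (1, 0, 1), (0, 1, 1),
                  (1, -1, 0), (1, 0, -1), (0, 1, -1),
                  (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1)]
    for off in directions:
        length = float(np.sqrt(sum(c * c for c in off)))
        lo = [2 * max(0, c, -c) for c in off]
        hi = [s - l for s, l in zip(d.shape, lo)]
        if any(h <= l for l, h in zip(lo, hi)):
            continue
        core = tuple(slice(l, h) for l, h in zip(lo, hi))

        def view(k):
            return d[tuple(slice(l + k * c, h + k * c)
                           for l, h, c in zip(lo, hi, off))]

        dp, du, dl, du2, dl2 = view(0), view(1), view(-1), view(2), view(-2)
        a = dp - 0.5 * (du + dl)   # g * (L - |s|) for a true tent
        b = 0.5 * (du - dl)        # g * s (signed apex position)
        cand = dp + b
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.where(a + np.abs(b) > 0,
                         length * b / (a + np.abs(b)), 0.0)
        # d is 1-Lipschitz along the line, so the apex at position s cannot
        # exceed any sample plus its distance; an exact tent satisfies all
        # five bounds with slack, junction artifacts get clamped
        for dk, k in ((dp, 0.0), (du, 1.0), (dl, -1.0), (du2, 2.0), (dl2, -2.0)):
            np.minimum(cand, dk + np.abs(k * length - s), out=cand)
        score = a / length
        better = (score > best_score[core] + 1e-12) & mask[core]
        np.copyto(best_score[core], score, where=better)
        np.copyto(best_cand[core], cand, where=better)
        frac = s / length
        for axis, c in enumerate(off):
            np.copyto(best_off[(axis,) + core], frac * c, where=better)
    # Lipschitz envelope: d at the fitted center m cannot exceed
    # d(v) + |v - m| for any neighboring voxel v; this clamps spurious
    # apexes at junctions that look tent-like along one line but are
    # contradicted by an off-line boundary.  A true plate apex satisfies
    # every bound with slack (slope <= 1), so plates are unaffected.
    core = tuple(slice(1, s - 1) for s in d.shape)
    cap = np.full(d.shape, np.inf)
    for u in product((-1, 0, 1), repeat=3):
        shifted = d[tuple(slice(1 + c, s - 1 + c)
                          for c, s in zip(u, d.shape))]
        dist2 = np.zeros(shifted.shape)
        for axis, c in enumerate(u):
            dist2 += (c - best_off[(axis,) + core]) ** 2
        np.minimum(cap[core], shifted + np.sqrt(dist2), out=cap[core])
    np.minimum(best_cand, cap, out=best_cand)

    use = (best_score > 1e-12) & (best_cand > refined)
    offsets = np.where(use[None], best_off, 0.0)
    np.maximum(refined, np.where(use, best_cand, 0.0), out=refined)
    return refined, offsets


def _distance_ridge(radii: np.ndarray, offsets: np.ndarray,
                    mask: np.ndarray) -> np.ndarray:
    """Keep only sphere centers not contained in a neighbor's sphere
    (``r(q) >= r(p) + |m_p - m_q|`` with sub-voxel centers discards ``p``)."""
    keep = mask.copy()
    for off in product((-1, 0, 1), repeat=3):
        if not any(off):
            continue
        src = tuple(slice(max(c, 0), radii.shape[i] + min(c, 0))
                    for i, c in enumerate(off))
        dst = tuple(slice(max(-c, 0), radii.shape[i] + min(-c, 0))
                    for i, c in enumerate(off))
        dist2 = np.zeros(radii[dst].shape)
        for axis, c in enumerate(off):
            dist2 += (c + offsets[(axis,) + src] - offsets[(axis,) + dst]) ** 2
        contained = radii[src] >= radii[dst] + np.sqrt(dist2) - 1e-9
        contained &= mask[src] & mask[dst] & (radii[src] > radii[dst])
        keep[dst] &= ~contained
    return keep


def _ball_offsets(radius: float, delta) -> np.ndarray:
    """Integer displacements o with |o - delta| <= radius."""
    r = int(np.floor(radius + float(np.max(np.abs(delta))) + 1e-9))
    ax = np.arange(-r, r + 1)
    dz, dy, dx = np.meshgrid(ax, ax, ax, indexing="ij")
    inside = ((dz - delta[0]) ** 2 + (dy - delta[1]) ** 2
              + (dx - delta[2]) ** 2) <= radius**2 + 1e-9
    return np.stack([dz[inside], dy[inside], dx[inside]], axis=1)


def local_thickness(mask: np.ndarray, voxel_size_um: float = 1.0,
                    subvoxel_refine: bool = False) -> ThicknessResult:
    """Sphere-fitting local thickness of a binary structure.

    Raises :class:`EmptyStructureError` on an empty mask.  The thickness map
    is in voxel units; multiply by ``voxel_size_um`` (done for the summary
    fields) for physical units.  With ``subvoxel_refine`` the medial sphere
    centers and radii are additionally fitted between voxel centers (see the
    module docstring); the default voxel-centered measurement is exactly the
    result of exhaustive sphere enumeration.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ParameterError("mask must be 3-dimensional")
    if not voxel_size_um > 0:
        raise ParameterError("voxel_size_um must be > 0")
    if not mask.any():
        raise EmptyStructureError("cannot measure thickness of an empty mask")

    d = _signed_distance(mask)
    if subvoxel_refine:
        radii, offsets = _refine_radii(d, mask)
    else:
        radii = np.where(mask, d, 0.0)
        offsets = np.zeros((3,) + mask.shape)
    ridge = _distance_ridge(radii, offsets, mask)

    thickness = np.zeros(mask.shape, dtype=np.float64)
    flat = thickness.ravel()
    strides = np.array([mask.shape[1] * mask.shape[2], mask.shape[2], 1])
    centers = np.argwhere(ridge)
    center_r = radii[ridge]
    center_off = offsets[:, ridge].T
    shape = np.array(mask.shape)
    # group spheres by (radius, sub-voxel center) for vectorized painting;
    # radii quantized to 1/64 voxel, center offsets to the quarter grid
    keys = np.column_stack([np.round(center_r * 64) / 64,
                            np.round(center_off * 4) / 4])
    uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
    for gi in range(len(uniq)):
        r, delta = uniq[gi, 0], uniq[gi, 1:]
        pts = centers[inverse == gi]
        offs = _ball_offsets(r, delta)
        coords = pts[:, None, :] + offs[None, :, :]
        # spheres around sub-voxel centers can poke past the volume
        # border; clip (clipped indices land on ~mask and are zeroed below)
        np.clip(coords, 0, shape - 1, out=coords)
        idx = (coords @ strides).ravel()
        np.maximum.at(flat, idx, 2.0 * r)
    thickness[~mask] = 0.0

    vals = thickness[mask]
    return ThicknessResult(
        thickness_map=thickness,
        voxel_size_um=float(voxel_size_um),
        mean_vox=float(vals.mean()),
        sd_vox=float(vals.std()),
        n_foreground=int(mask.sum()),
    )


def thickness_sweep(volume: Volume, pp: PreprocessParams | None,
                    cfg_base: SegmentationConfig, parameter: str, values,
                    class_id="brightest") -> pd.DataFrame:
    """Re-segment at each parameter value and measure the class thickness.

    ``parameter`` is ``"prob_threshold"`` or ``"grid_size"``; each value
    triggers one full segmentation plus a local-thickness measurement of the
    binarized ``class_id``.  Returns a tidy table with one row per value
    (columns: parameter, value, mean_vox, sd_vox, mean_um, sd_um).
    """
    if parameter not in ("prob_threshold", "grid_size"):
        raise ParameterError(
            f"parameter must be 'prob_threshold' or 'grid_size', got {parameter!r}"
        )
    rows = []
    for value in values:
        kwargs = {
            "n_classes": cfg_base.n_classes,
            "grid_size": cfg_base.grid_size,
            "class_presence_threshold": cfg_base.class_presence_threshold,
            "prob_threshold": cfg_base.prob_threshold,
            "fuzziness_m": cfg_base.fuzziness_m,
            "tol": cfg_base.tol,
            "max_iter": cfg_base.max_iter,
            "overlap_stride": cfg_base.overlap_stride,
        }
        kwargs[parameter] = value
        if parameter == "grid_size":
            kwargs["overlap_stride"] = None  # stride re-derived from g
        cfg = SegmentationConfig(**kwargs)
        result = segment(volume, pp, cfg)
        sel = binarize(result.labels, class_id)
        if sel.any():
            th = local_thickness(sel, volume.voxel_size_um)
            rows.append((parameter, value, th.mean_vox, th.sd_vox,
                         th.mean_um, th.sd_um))
        else:
            rows.append((parameter, value, 0.0, 0.0, 0.0, 0.0))
    return pd.DataFrame(
        rows, columns=["parameter", "value", "mean_vox", "sd_vox",
                       "mean_um", "sd_um"]
    )
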