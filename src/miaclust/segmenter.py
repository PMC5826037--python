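"""Locally adaptive fuzzy c-means segmentation of 3D grayscale volumes.

The pipeline segments a micro-CT volume into ``C`` intensity classes while
tolerating the smooth intensity inhomogeneities (e.g. a center-bright
artifact) that defeat global thresholds:

1.  optional median filter and background threshold (``preprocess``);
2.  deterministic 1D K-means on the in-mask intensities seeds ``C`` class
    centers;
3.  global fuzzy c-means turns these into per-voxel membership vectors;
4.  the volume is tiled with overlapping cubes (``grid``); inside each cube
    c-means is re-run, warm-started from the global memberships, after
    dropping classes that hold less than a minimum fraction (default 2%) of
    the cube's membership mass;
5.  cube-level memberships are merged by unweighted averaging over the cubes
    covering each voxel and renormalized;
6.  each voxel takes the class of its highest membership, optionally subject
    to a probability threshold (51-100%); sub-threshold and background voxels
    get label 0, classes are labeled 1..C by ascending center intensity.

The estimator follows the scikit-learn clusterer protocol (``fit``,
``fit_predict``, trailing-underscore fitted attributes); the module-level
functions are thin wrappers for script use.  Everything is deterministic:
identical input and parameters give bit-identical labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .errors import DegenerateInputError, ParameterError
from .fcm import fcm, kmeans_init, _membership_matrix
from .grid import GridSpec, build_grid
from .preprocess import PreprocessParams, background_mask, median_filter
from .volume import LabelVolume, MembershipField, Volume

__all__ = [
    "SegmentationConfig",
    "SegmentationResult",
    "MIAClusterSegmenter",
    "admissible_prob_thresholds",
    "normalize_prob_threshold",
    "local_refine",
    "assign_labels",
    "binarize",
    "segment",
]


def admissible_prob_thresholds() -> tuple[float, ...]:
    """The 50 active probability-threshold values, 51%..100%.

    50% is additionally accepted as an alias for "no threshold" (a membership
    maximum over a vector summing to one can only tie 0.5, never fall below
    it for two classes, and the pipeline treats it as a no-op).
    """
    return tuple(t / 100.0 for t in range(51, 101))


def normalize_prob_threshold(prob_threshold):
    """Validate and canonicalise a probability threshold.

    Accepts ``None``, a fraction in {0.50, 0.51, ..., 1.00} or the same as
    integer percent (50..100).  Returns a float fraction, with 0.50 mapped to
    ``None`` (threshold off).
    """
    if prob_threshold is None:
        return None
    t = float(prob_threshold)
    if t > 1.5:  # integer-percent spelling
        t = t / 100.0
    pct = round(t * 100)
    if abs(t * 100 - pct) > 1e-9 or not 50 <= pct <= 100:
        raise ParameterError(
            f"probability threshold must be one of 50%..100% in integer "
            f"percent steps, got {prob_threshold!r}"
        )
    return None if pct == 50 else pct / 100.0


@dataclass
class SegmentationConfig:
    """User-facing parameters of the segmentation.

    ``grid_size`` should be slightly larger than the widest dimension of the
    phase of interest (see :func:`miaclust.grid.suggest_grid_size`).
    ``overlap_stride`` defaults to ``ceil(grid_size / 2)`` (50% overlap).
    """

    n_classes: int
    grid_size: int
    class_presence_threshold: float = 0.02
    prob_threshold: float | None = None
    fuzziness_m: float = 2.0
    tol: float = 1e-5
    max_iter: int = 100
    overlap_stride: int | None = None
    emit_global: bool = False

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ParameterError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.grid_size < 3:
            raise ParameterError(f"grid_size must be >= 3, got {self.grid_size}")
        if not 0 < self.class_presence_threshold < 1:
            raise ParameterError("class_presence_threshold must be in (0, 1)")
        self.prob_threshold = normalize_prob_threshold(self.prob_threshold)
        if not self.fuzziness_m > 1:
            raise ParameterError("fuzziness_m must be > 1")
        if not self.tol > 0:
            raise ParameterError("tol must be > 0")
        if self.max_iter < 1:
            raise ParameterError("max_iter must be >= 1")
        if self.overlap_stride is not None and not (
            1 <= self.overlap_stride <= self.grid_size
        ):
            raise ParameterError(
                f"overlap_stride must be in [1, {self.grid_size}]"
            )

    @property
    def stride(self) -> int:
        return self.overlap_stride or ceil(self.grid_size / 2)


@dataclass
class SegmentationResult:
    """Everything a segmentation run produces."""

    labels: LabelVolume
    local_memberships: MembershipField
    centers: np.ndarray
    config: SegmentationConfig
    preprocess: PreprocessParams
    iteration_log: dict = field(default_factory=dict)
    global_memberships: MembershipField | None = None
    global_labels: LabelVolume | None = None


def _global_membership_field(data, mask, centers, m) -> np.ndarray:
    """Evaluate the converged membership formula on every in-mask voxel.

    The membership of a voxel depends only on its intensity, so the field is
    computed once per distinct value and broadcast back.
    """
    C = len(centers)
    out = np.zeros((C,) + data.shape, dtype=np.float64)
    values, inverse = np.unique(data[mask], return_inverse=True)
    u = _membership_matrix(values.astype(np.float64), np.asarray(centers), m)
    full = u[inverse]  # (n_mask, C)
    for c in range(C):
        out[c][mask] = full[:, c]
    return out


def local_refine(volume: Volume, mask, global_mf, global_centers,
                 cfg: SegmentationConfig, grid: GridSpec | None = None,
                 stats: dict | None = None) -> np.ndarray:
    """Re-run fuzzy c-means inside overlapping cubes and merge the results.

    Per cube: classes whose global membership mass is below
    ``class_presence_threshold`` times the cube's in-mask voxel count are
    dropped; the survivors are refined by c-means warm-started from the
    (renormalized) global memberships.  A single surviving class gets
    membership 1; an intensity-constant cube keeps its global memberships
    unchanged (there is nothing to refine).  Each voxel's merged vector is
    the unweighted mean over all cubes covering it, renormalized to sum 1.

    Returns the merged ``(C, nz, ny, nx)`` membership array.
    """
    data = volume.data
    mask = np.asarray(mask, dtype=bool)
    global_centers = np.asarray(global_centers, dtype=np.float64)
    C = len(global_centers)
    if global_mf.shape != (C,) + data.shape:
        raise ParameterError("global membership field shape mismatch")
    if grid is None:
        grid = build_grid(data.shape, cfg.grid_size, cfg.stride)

    acc = np.zeros((C,) + data.shape, dtype=np.float64)
    count = np.zeros(data.shape, dtype=np.int16)
    n_refined = n_single = n_constant = n_empty = 0
    local_iters = 0

    for origin in grid.origins:
        sl = grid.slices(origin)
        msk = mask[sl]
        n = int(msk.sum())
        if n == 0:
            n_empty += 1
            continue
        gsub = global_mf[(slice(None),) + sl][:, msk]  # (C, n)
        presence = gsub.sum(axis=1)
        keep = presence >= cfg.class_presence_threshold * n
        local = np.zeros((C, n), dtype=np.float64)
        n_keep = int(keep.sum())
        xs = data[sl][msk].astype(np.float64)
        if n_keep == 1:
            local[keep] = 1.0
            n_single += 1
        elif xs.max() == xs.min():
            # degenerate cube: a constant intensity cannot be refined
            local = gsub
            n_constant += 1
        else:
            u0 = gsub[keep].T.copy()
            u0 /= u0.sum(axis=1, keepdims=True)
            res = fcm(
                xs,
                centers_init=global_centers[keep],
                m=cfg.fuzziness_m,
                tol=cfg.tol,
                max_iter=cfg.max_iter,
                membership_init=u0,
            )
            local[keep] = res.memberships.T
            local_iters += res.n_iter
            n_refined += 1
        sub = acc[(slice(None),) + sl]
        sub[:, msk] += local
        count[sl][msk] += 1

    merged = np.zeros_like(acc)
    covered = count > 0
    for c in range(C):
        merged[c][covered] = acc[c][covered] / count[covered]
    total = merged.sum(axis=0)
    ok = covered & (total > 0)
    for c in range(C):
        merged[c][ok] /= total[ok]
    if stats is not None:
        stats.update(
            n_cubes=len(grid),
            n_cubes_refined=n_refined,
            n_cubes_single_class=n_single,
            n_cubes_constant=n_constant,
            n_cubes_empty=n_empty,
            local_fcm_iterations_total=local_iters,
        )
    return merged


def assign_labels(mf: MembershipField, prob_threshold=None) -> LabelVolume:
    """Hard labels from memberships: per in-mask voxel the argmax class
    (1-based, ascending center order; ties to the lowest index), or 0 when
    a probability threshold is set and the maximum does not meet or exceed
    it.  Out-of-mask voxels are 0."""
    t = normalize_prob_threshold(prob_threshold)
    u = mf.memberships
    best = np.argmax(u, axis=0)  # first maximum = lowest class index
    labels = np.where(mf.mask, best.astype(np.int32) + 1, 0)
    if t is not None:
        umax = np.take_along_axis(u, best[None], axis=0)[0]
        labels[mf.mask & (umax < t - 1e-12)] = 0
    return LabelVolume(labels.astype(np.int32), n_classes=mf.n_classes,
                       voxel_size_um=mf.voxel_size_um)


def binarize(labels: LabelVolume, class_id) -> np.ndarray:
    """Boolean mask of one class.

    ``class_id`` is a 1-based class index or one of ``"brightest"`` /
    ``"second-brightest"`` resolved against ascending center order (the
    fossil bone phase is typically the second-brightest of three classes,
    below the invasive matrix).
    """
    C = labels.n_classes
    if class_id == "brightest":
        cid = C
    elif class_id == "second-brightest":
        if C < 2:
            raise ParameterError("'second-brightest' needs at least 2 classes")
        cid = C - 1
    else:
        cid = int(class_id)
        if not 1 <= cid <= C:
            raise ParameterError(f"class_id must be in 1..{C}, got {class_id}")
    return labels.labels == cid


class MIAClusterSegmenter(ClusterMixin, BaseEstimator):
    """K-means-initialized global + local fuzzy c-means voxel clusterer.

    Parameters
    ----------
    n_classes : int, default 3
        Number of intensity classes (>= 2), e.g. background / bone / matrix.
    grid_size : int, default 20
        Edge of the overlapping refinement cubes, in voxels; choose it
        slightly larger than the widest dimension of the phase of interest.
    class_presence_threshold : float, default 0.02
        Minimum fraction of a cube's membership mass a class needs to take
        part in that cube's local clustering.
    prob_threshold : float or int or None, default None
        Optional cutoff on the winning membership (51-100%, fraction or
        integer percent; 50 = off); sub-threshold voxels are labeled 0.
    fuzziness : float, default 2.0
        Fuzzy c-means exponent ``m`` (> 1).
    tol : float, default 1e-5
        c-means convergence threshold (largest center move relative to the
        intensity range).
    max_iter : int, default 100
        c-means iteration cap per stage.
    stride : int or None, default None
        Cube origin step; ``None`` means ``ceil(grid_size / 2)``.
    median_kernel : int, default 0
        Odd cubic median-filter kernel applied first; 0 skips it.
    background_threshold : float or None, default None
        Intensity below which voxels are excluded from clustering (label 0).
    emit_global : bool, default False
        Also keep the global-only memberships/labels for comparison.
    voxel_size_um : float, default 1.0
        Used when ``fit`` receives a plain array instead of a Volume.

    Attributes
    ----------
    centers_ : ndarray of shape (n_classes,)
        Converged global class centers, ascending.
    memberships_ : MembershipField
        Merged local membership field.
    labels_ : ndarray
        Per-voxel labels (0 = background/sub-threshold, 1..C ascending).
    label_volume_ : LabelVolume
    global_memberships_, global_label_volume_
        Only set when ``emit_global`` is true.
    mask_ : ndarray of bool
        In-analysis mask after background thresholding.
    n_iter_ : dict
        Per-stage iteration counts and cube statistics.
    objective_ : list of float
        Global c-means objective per iteration (non-increasing).
    """

    def __init__(self, n_classes: int = 3, grid_size: int = 20,
                 class_presence_threshold: float = 0.02, prob_threshold=None,
                 fuzziness: float = 2.0, tol: float = 1e-5, max_iter: int = 100,
                 stride: int | None = None, median_kernel: int = 0,
                 background_threshold: float | None = None,
                 emit_global: bool = False, voxel_size_um: float = 1.0):
        self.n_classes = n_classes
        self.grid_size = grid_size
        self.class_presence_threshold = class_presence_threshold
        self.prob_threshold = prob_threshold
        self.fuzziness = fuzziness
        self.tol = tol
        self.max_iter = max_iter
        self.stride = stride
        self.median_kernel = median_kernel
        self.background_threshold = background_threshold
        self.emit_global = emit_global
        self.voxel_size_um = voxel_size_um

    # -- scikit-learn plumbing -------------------------------------------
    def _config(self) -> SegmentationConfig:
        return SegmentationConfig(
            n_classes=self.n_classes,
            grid_size=self.grid_size,
            class_presence_threshold=self.class_presence_threshold,
            prob_threshold=self.prob_threshold,
            fuzziness_m=self.fuzziness,
            tol=self.tol,
            max_iter=self.max_iter,
            overlap_stride=self.stride,
            emit_global=self.emit_global,
        )

    def _as_volume(self, X) -> Volume:
        if isinstance(X, Volume):
            return X
        X = np.asarray(X)
        bit = 8 if (X.dtype == np.uint8) else 16
        return Volume(X, voxel_size_um=self.voxel_size_um, bit_depth=bit)

    # -- fitting ----------------------------------------------------------
    def fit(self, X, y=None):
        """Segment the volume ``X`` (a :class:`Volume` or 3D array)."""
        cfg = self._config()
        pp = PreprocessParams(self.median_kernel, self.background_threshold)
        volume = self._as_volume(X)

        if pp.median_kernel:
            volume = median_filter(volume, pp.median_kernel)
        if pp.background_threshold is not None:
            mask = background_mask(volume, pp.background_threshold)
        else:
            mask = np.ones(volume.shape, dtype=bool)
        if not mask.any():
            raise DegenerateInputError(
                "background threshold removed every voxel"
            )
        data = volume.data
        in_mask = data[mask].astype(np.float64)

        values, counts = np.unique(in_mask, return_counts=True)
        if values.size < cfg.n_classes:
            raise DegenerateInputError(
                f"only {values.size} distinct in-mask intensity value(s) for "
                f"{cfg.n_classes} classes"
            )

        centers0 = kmeans_init(values, cfg.n_classes, weights=counts)
        global_res = fcm(values, centers0, m=cfg.fuzziness_m, tol=cfg.tol,
                         max_iter=cfg.max_iter, weights=counts)
        centers = global_res.centers
        global_field = _global_membership_field(data, mask, centers,
                                                cfg.fuzziness_m)

        stats: dict = {}
        merged = local_refine(volume, mask, global_field, centers, cfg,
                              stats=stats)

        vs = volume.voxel_size_um
        self.centers_ = centers
        self.mask_ = mask
        self.objective_ = global_res.objective
        self.memberships_ = MembershipField(merged, mask, vs)
        self.label_volume_ = assign_labels(self.memberships_,
                                           cfg.prob_threshold)
        self.labels_ = self.label_volume_.labels
        self.n_iter_ = {"global_fcm_iterations": global_res.n_iter, **stats}
        if cfg.emit_global:
            self.global_memberships_ = MembershipField(global_field, mask, vs)
            self.global_label_volume_ = assign_labels(self.global_memberships_,
                                                      cfg.prob_threshold)
        else:
            self.global_memberships_ = None
            self.global_label_volume_ = None
        self.processed_volume_ = volume
        return self

    def predict(self, X=None):
        """Labels of the fitted volume (the clusterer does not generalise to
        unseen volumes; re-fit instead)."""
        if not hasattr(self, "labels_"):
            raise ParameterError("call fit before predict")
        return self.labels_


def segment(volume: Volume, pp: PreprocessParams | None,
            cfg: SegmentationConfig) -> SegmentationResult:
    """Run the full pipeline and bundle the outputs (functional façade over
    :class:`MIAClusterSegmenter`)."""
    pp = pp or PreprocessParams()
    est = MIAClusterSegmenter(
        n_classes=cfg.n_classes,
        grid_size=cfg.grid_size,
        class_presence_threshold=cfg.class_presence_threshold,
        prob_threshold=cfg.prob_threshold,
        fuzziness=cfg.fuzziness_m,
        tol=cfg.tol,
        max_iter=cfg.max_iter,
        stride=cfg.overlap_stride,
        median_kernel=pp.median_kernel,
        background_threshold=pp.background_threshold,
        emit_global=cfg.emit_global,
        voxel_size_um=volume.voxel_size_um,
    ).fit(volume)
    return SegmentationResult(
        labels=est.label_volume_,
        local_memberships=est.memberships_,
        centers=est.centers_,
        config=cfg,
        preprocess=pp,
        iteration_log=est.n_iter_,
        global_memberships=est.global_memberships_,
        global_labels=est.global_label_volume_,
    )
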