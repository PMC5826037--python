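# miaclust

Locally adaptive fuzzy c-means segmentation of micro-CT (μCT) volumes of
bone and fossil material, with sphere-fitting 3D thickness measurement and
synthetic ground-truth phantoms for validation.

## The problem

Quantifying trabecular architecture from μCT scans requires segmenting the
bone phase from air, desiccated tissue or mineralized sediment. Global
methods (thresholds, global clustering) fail on real scans for two reasons:
smooth intensity inhomogeneity — e.g. a center-bright artifact in dense
fossils — moves the same material across any single intensity boundary, and
invasive matrix can out-attenuate the bone itself, so the phase of interest
is not the brightest one. `miaclust` addresses both with a two-stage,
data-led clustering that needs only two input parameters: the number of
classes and a grid size read off the specimen itself.

## The algorithm

For voxel intensities `x_k` and `C` class centers `v_c`, fuzzy c-means
minimizes

    J(U, v) = Σ_{c,k} u_{ck}^m (x_k − v_c)²,   Σ_c u_{ck} = 1,  m > 1,

by alternating the closed-form updates

    u_{ck} = [ Σ_j ( |x_k − v_c| / |x_k − v_j| )^{2/(m−1)} ]^{−1},
    v_c    = Σ_k u_{ck}^m x_k / Σ_k u_{ck}^m.

The pipeline:

1. optional median filter and background threshold (background voxels are
   excluded from clustering and labeled 0);
2. deterministic 1D K-means (quantile-seeded Lloyd) initializes the `C`
   centers from the in-mask intensity histogram;
3. global fuzzy c-means produces per-voxel membership vectors;
4. the volume is tiled with overlapping cubes of edge `g` (stride
   `⌈g/2⌉`); in each cube, classes holding less than 2% (configurable) of
   the cube's membership mass are dropped and c-means is re-run on the
   survivors, warm-started from the global solution — this is what adapts
   the segmentation to local intensity level;
5. cube memberships are averaged over the cubes covering each voxel and
   renormalized;
6. voxels take the class of their maximum membership (classes `1..C` by
   ascending center intensity), optionally subject to a probability
   threshold from the 50-value menu 51–100% (voxels below it get label 0).

The grid size should be slightly larger than the widest dimension of the
phase of interest: `suggest_grid_size(width, voxel_size)` implements
`round(width/voxel_size) + 2`, e.g. a 40 μm wire at 7.86 μm voxels → 7.

Validation instruments included: Hildebrand–Rüegsegger local thickness (the
diameter of the largest inscribed sphere covering each voxel, computed via
distance transform, distance ridge and sphere painting) and deterministic
phantom generators (`plate_coil`, a coiled ribbon of known thickness;
`trabecular_lattice`; `fossil_like` with bright matrix, cracks, a
center-bright gradient, bright inclusions and noise).

## Worked example

```python
import miaclust as mc

spec = mc.PhantomSpec(kind="plate_coil", shape=(64, 256, 256),
                      thickness_vox=5, foreground_level=30000,
                      background_level=0, gradient_amplitude=0.10,
                      noise_sd=1500, seed=42, voxel_size_um=7.86)
truth = mc.make_phantom(spec)

cfg = mc.SegmentationConfig(n_classes=2, grid_size=7)
result = mc.segment(truth.volume, None, cfg)
wire = mc.binarize(result.labels, "brightest")
th = mc.local_thickness(wire, truth.volume.voxel_size_um)
print(f"mean = {th.mean_vox:.4f} voxels ({th.mean_um:.3f} um), "
      f"sd = {th.sd_vox:.4f} voxels")
print(f"relative error vs 5 voxels: {abs(th.mean_vox - 5)/5:.3%}")
```

prints

```
mean = 4.9508 voxels (38.913 um), sd = 0.3740 voxels
relative error vs 5 voxels: 0.983%
```

i.e. the segmentation recovers the known 5-voxel (39.3 μm) band thickness
to within 1%, despite the 10% intensity gradient and heavy noise. The same
estimator is available scikit-learn style:

```python
est = mc.MIAClusterSegmenter(n_classes=2, grid_size=7, voxel_size_um=7.86)
labels = est.fit_predict(truth.volume.data)   # est.centers_, est.memberships_
```

and from the shell:

```
miaclust phantom --kind plate_coil --shape 64,256,256 --thickness 5 \
    --noise-sd 1500 --gradient-amplitude 0.1 --seed 42 \
    --voxel-size 7.86 --out wire.nii
miaclust segment wire.nii labels.nii --classes 2 --grid-size 7
miaclust binarize labels.nii wire_mask.nii --class brightest
miaclust thickness wire_mask.nii
```

Every command writes a `*.manifest.txt` next to its output with the fully
resolved configuration and input/output digests; re-running with the same
inputs is bit-identical.

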