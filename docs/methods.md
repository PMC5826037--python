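# Methods

## Segmentation model

The segmenter clusters voxels by intensity only (one feature), first
globally and then inside overlapping cubes, so that the class boundary can
follow smooth intensity inhomogeneity across the volume while remaining a
plain intensity clustering within any neighborhood. The model and defaults:

* **K-means initialization.** Lloyd's algorithm on the in-mask intensity
  histogram, seeded deterministically at the `(i+0.5)/C` quantiles of the
  data (falling back to quantiles of the distinct values under heavy ties),
  iterated to assignment stability (cap 300). There is no RNG anywhere in
  the pipeline: identical input and parameters give bit-identical labels.
  Like all Lloyd variants this finds a local WCSS optimum; with a dominant
  background peak two seeds can land in that peak, which is why background
  thresholding (below) precedes clustering of specimen-in-air scans. On
  balanced well-separated mixtures it attains the dynamic-programming
  global optimum (verified in the test suite against an exact O(Cn²) DP).
* **Fuzzy c-means.** Standard alternating updates of the fuzzified WCSS
  objective. Fuzziness `m = 2.0` (the universal default; exposed).
  Convergence when the largest center move per iteration, relative to the
  intensity range of the input, drops below `tol = 1e-5` (cap 100
  iterations). Both stages run on the value histogram (unique intensities
  with counts), which is exact for 1D features and makes the global stage
  cost independent of volume size for 16-bit data. A point coinciding with
  one or more centers splits its unit membership equally among them. Two
  centers approaching within 1e-9 of the intensity range raise an error
  naming the classes rather than silently merging.
* **Local refinement.** Cubes of edge `g` at stride `⌈g/2⌉` (50% overlap,
  ≤ 8 cubes per voxel; both configurable), with the last cube on each axis
  moved to end exactly at the volume boundary. Per cube, class `c` is
  dropped when its global membership mass is below
  `class_presence_threshold × (in-mask voxels in the cube)`; the default
  threshold is 2%. The in-mask count (not the full cube volume) is the
  denominator so the rule is insensitive to how much masked background a
  cube contains. Survivors are refined by c-means warm-started from the
  renormalized global memberships; one survivor gets membership 1; an
  intensity-constant cube keeps its global memberships (nothing to refine,
  and refining would collapse centers). Dropped classes contribute zero
  membership from that cube.
* **Merging.** A voxel's merged vector is the unweighted arithmetic mean
  over all cubes covering it, renormalized to sum 1. Distance-weighted
  merging was considered and rejected as an extra knob with no observable
  benefit on the phantoms.
* **Labeling.** Argmax with ties to the lowest class index; classes are
  numbered `1..C` by ascending converged center (so "second-brightest" is
  well defined, e.g. fossil bone below invasive matrix). Label 0 is
  reserved for background-masked and sub-threshold voxels whether or not a
  probability threshold is used. The threshold menu is the 50 integer
  percents 51–100; the comparison is inclusive ("meet or exceed"); 50% is
  accepted as an explicit alias for "no threshold" (for two classes the
  maximum of a probability vector can never fall below one half, and the
  alias is kept uniform for any C).

### Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `n_classes` | — | number of material phases (≥ 2), e.g. air/bone/matrix |
| `grid_size` | — | refinement cube edge, voxels; slightly larger than the widest dimension of the phase of interest (`suggest_grid_size`: `round(width_vox) + 2`, floor 3) |
| `class_presence_threshold` | 0.02 | minimum fraction of a cube's membership mass a class needs locally |
| `prob_threshold` | off | 51–100% cutoff on the winning membership; sub-threshold voxels → 0 |
| `fuzziness` | 2.0 | c-means exponent; larger = softer boundaries |
| `stride` | `⌈g/2⌉` | cube origin step (1 → maximal overlap, `g` → tiling) |

A grid size smaller than the structure makes the local stage hunt for
sub-classes inside it (thinning the phase); much larger values converge on
the global segmentation — the whole-volume cube reproduces the global
result exactly, which the tests assert to 1e-6 at tight tolerance.

## Local thickness

Local thickness at a voxel is the diameter of the largest sphere containing
it that lies entirely inside the structure (Hildebrand–Rüegsegger, the
definition behind BoneJ's Thickness). Implementation: Euclidean distance
transform → distance-ridge reduction (a sphere contained in a neighbor's
sphere is dropped) → sphere painting (each surviving sphere writes its
diameter into the voxels it covers; voxels keep the maximum). Mean and SD
are taken over all foreground voxels, in voxels and μm.

Numerical conventions, chosen so a digitized slab of n voxels measures n:
the inscribed radius is `EDT − 0.5` (the continuous boundary runs half a
voxel beyond the outermost foreground voxel centers) and the volume border
counts as background. Painting groups spheres by radius quantized to 1/64
voxel. The default measurement places sphere centers at voxel centers,
which makes it exactly reproducible by exhaustive enumeration (the test
suite does so on random masks). Known biases of this voxel-centered
estimator: even-width aligned plates read one voxel thin (their medial
plane lies between voxels) and oblique plates read up to ~20% thin at
5-voxel scale; an optional `subvoxel_refine` mode fits the medial apex of
the distance field between voxel centers (a tent fit along 13 lattice
directions, clamped by a Lipschitz envelope, painted from the fitted
centers) and removes the even-width error and part of the oblique bias, at
the cost of heuristic center placement on junction-heavy structures. Exact
numeric parity with any particular BoneJ version is not claimed — the
definition, not the binary, is the contract.

## Phantoms

The generators produce ground truth for every structural claim, with a
fixed artifact order (geometry → gradient → inclusions → noise → clip to
bit depth) and one `default_rng(seed)` stream, so a spec is bit-reproducible.

* `plate_coil` emulates a machined reference object: a flat ribbon of
  rectangular cross-section wound into a helix, in air. The thin dimension
  lies along the coil axis and the band height is widened by `1/cos(pitch
  angle)` so the thickness *normal to the band* equals the requested value
  exactly; rims are never cut by the volume faces. The thin dimension is
  kept near-axis-aligned deliberately: that is how such reference objects
  are scanned and measured in practice, and it keeps the known thickness
  within reach of any sphere-fitting instrument — a plate sweeping all
  oblique orientations carries an irreducible digitization bias of several
  percent at 5-voxel thickness, which would measure the estimator, not the
  segmentation. Defaults: pitch `3t`, inner radius `4t`, edge margin 5.
* `trabecular_lattice`: connected rods of the stated thickness along all
  three axes at spacing `3t` — a strut-like stand-in, not anatomically
  realistic microarchitecture.
* `fossil_like`: the lattice (bone level) inside an ellipsoidal matrix
  *brighter* than bone, with planar background-level crack slits, bright
  inclusion specks, and a multiplicative center-bright ramp
  `1 + a(1 − r/r_max)` applied to specimen voxels, `r_max` the specimen's
  own radial extent (the artifact spans the scanned object, not the air
  around it). This reproduces the failure mode that motivates the local
  stage: with `a × bone level` exceeding the bone/matrix gap, a global
  clustering reassigns central bone to the matrix class (Dice drops to
  ~0.57 in the acceptance experiment) while the local refinement holds
  (~0.90).

What the phantoms do *not* emulate: partial-volume mixing at boundaries
(levels are piecewise constant before noise), detector blur, ring/streak
artifacts, or real trabecular topology. Passing the phantom suite therefore
demonstrates correctness of the algorithmic chain under controlled
pathologies, not segmentation accuracy on any particular real scan.

## Validation experiments (test suite)

* Wire recovery: 64×256×256 plate-coil phantom (5-voxel thickness, 10%
  gradient, noise σ=1500), segmented with `C=2, g=7`; mean thickness of the
  brighter class within 1% and within one voxel of truth. The same run at
  32×128×128 drives the threshold-monotonicity sweep (50–95% in 5% steps):
  the sets of assigned voxels are exactly nested, and mean thickness is
  non-increasing up to a 1e-3-voxel numerical ripple (removing thin
  boundary voxels can raise the surviving set's mean microscopically).
* Oracle suites: 1D K-means vs exact DP on 100 mixture instances;
  thickness vs exhaustive sphere enumeration on 50 random 12³ masks
  (1-voxel tolerance); the c-means membership update vs direct evaluation
  of the formula.
* Fixed point, determinism, permutation safety, membership normalization,
  and the preprocess/grid/IO contracts, as unit and property tests.

Problem sizes in the suite are chosen so the whole run completes in a few
minutes on one CPU; all conclusions above are scale-free properties.

## Known limitations

* Intensity-only features: textures or multi-channel data are out of scope.
* Lloyd K-means initialization inherits local optima under extreme class
  imbalance; threshold the background away first (the fossil recipe:
  median kernel 3, threshold 10000).
* The voxel-centered thickness default under-reads oblique thin plates
  (see above); `subvoxel_refine` mitigates but is heuristic at junctions.
* Matrix–air interface rings are segmented as matrix/bone-like shells, as
  with any intensity method; removing them (e.g. by connected components)
  is left to post-processing.
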