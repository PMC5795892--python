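# Methods

`visceraseg` segments the internal organs of eviscerated poultry in
registered RGB-D images: every pixel receives one of four labels —
miscellaneous tissue, heart, liver or lung — plus background and an
ignore code.  The pipeline is classical rather than end-to-end: a
supervoxel oversegmentation reduces the image to a few hundred regions,
a random forest assigns each region a class-probability vector from
pooled features, and a pairwise conditional random field (CRF) over the
region adjacency graph refines the labeling using learned class-pair
potentials.  This design suits very small datasets of organic,
texture-poor objects, where deep end-to-end models have too little data
to train.

## Data model

Inputs are 8-bit RGB + 16-bit depth PNG pairs (depth in millimetres,
0 = missing) with pinhole intrinsics; depth is converted to metres on
load.  Ground truth uses one label code per pixel.  Following the
annotation convention of production-line viscera datasets, a 2-pixel
ignore band separates adjacent organ classes — label assignment at organ
borders is genuinely ambiguous — and pixels without a depth measurement
are likewise ignored.  Ignore and background pixels are excluded from
both training and evaluation.

The band is measured in Chebyshev (8-connected) distance and applied
symmetrically: a pixel of class A within 2 px of a pixel of a different
organ class becomes ignore.  Borders against background do not create a
band.  This operation is idempotent and monotone in the width.

## Synthetic scenes

The package ships a generator that emulates the statistical structure of
such a dataset so the full pipeline is trainable and testable without
any data download:

- 151 viscera "sets" × 4 views = 604 images by default; views of one
  set share organ geometry under a small in-plane translation plus a
  depth-dependent parallax shift.  Splits are always by set id, so the
  same viscera never straddles training and test.
- The foreground occupies a vertically elongated region (~73% × 23% of
  the frame, i.e. ~350×150 px at 480×640) built from thresholded
  smoothed noise — deformable bodies without straight lines or sharp
  edges.
- Class pixel shares target the skew 70% miscellaneous / 20% liver /
  5% heart / 5% lung.  Because the measured shares exclude the ignore
  band, and at small working resolutions the 2-px band removes a third
  of the foreground (depleting small classes), the generator
  fixed-point-iterates the organ pixel targets against the measured
  post-band shares on frozen per-class score fields.  Measured mean
  miscellaneous share at 120×160: ~70% ± 2 (50 scenes).
- Layout priors place heart and lungs near the top and the liver
  centrally; organ shapes come from per-class smoothed-noise score
  fields thresholded at share-matching quantiles.
- Two deliberate difficulty features mirror real viscera: heart and
  miscellaneous tissue overlap in color (fat covers much of the heart),
  while organs protrude toward the camera by class-specific amounts
  (heart 32 mm, lung 22 mm, liver 12 mm), so depth carries class signal
  that color does not.  2D-vs-3D comparisons on this generator are
  therefore constructed to favor 3D when the pipeline uses depth
  correctly.
- Missing-depth holes are Bernoulli at 2% per pixel; color and depth
  carry Gaussian pixel noise plus smooth within-organ variation and a
  per-view lighting factor.

What the generator does **not** emulate: anatomical organ shapes,
specular highlights, real sensor noise statistics (RealSense
quantization, edge shadows), registration error, and occlusion by the
hanger.  Passing tests demonstrate the pipeline's mechanics and internal
consistency, not field performance on real poultry lines.

## Oversegmentation

A VCCS-style seeded clustering, run either on the point cloud (3D mode)
or the pixel grid (2D mode).  Seeds are placed on an even grid of pitch
`rseed` (grid nodes with no data point within `rseed/2` are discarded;
each seed starts at the data point nearest its node).  Alternating
assign/update iterations minimize

    D = sqrt( w_c · D_c²  +  w_s · D_s² / (3·rseed)²  +  w_g · D_g² )

with D_c the Euclidean LAB distance, D_s the spatial distance (metres in
3D, pixels in 2D) and D_g = 1 − |n_i · n_k| the normal-alignment
dissimilarity (0 in 2D mode or when w_g = 0).  Assignment is restricted
to a hard radius of 3·rseed; ties go to the lowest cluster id.  The
geometric channel uses the surface normal alone rather than a full
33-bin FPFH histogram; the weight interface is unchanged and FPFH is an
extension point.

Two practical choices matter:

- **Weight scale.**  LAB distances are tens of units, so their squares
  dominate any O(1) term.  Defaults are w_c = 0.004, w_s = 1.0 (and
  w_g = 0.5 in 3D): at a typical organ-boundary contrast (ΔLAB ≈ 16)
  the color term matches the spatial term at full radius.  Weights are
  fully configurable; setting w_c higher trades compactness for
  boundary adherence.
- **Contiguity.**  Per-pixel noise lets isolated pixels hop to a
  similar-colored cluster elsewhere in the search window.  As is
  standard for SLIC-family methods, a post-pass keeps each cluster's
  largest 8-connected component and hands orphans to the nearest
  retained pixel's cluster; in 3D the hand-off must also respect the
  3·rseed radius (otherwise a pixel across a depth discontinuity could
  join a spatially distant cluster) and violators keep their clustered
  id.  Per-cluster statistics are recomputed afterwards.

Adjacency: 8-connected pixel contact (2D) or co-occupancy/26-adjacency
of `rvoxel` voxels (3D).  The alternation is monitored: the summed
squared dissimilarity is non-increasing over iterations (exact when
w_g = 0; the normal-mean update is heuristic otherwise).

Default pitches: 12 mm (3D) / 15 px (2D) at 480×640; the desk-scale
configuration uses 20 mm / 6 px at 120×160, chosen to keep roughly
100–150 regions per frame.

## Feature maps and pooling

Per-pixel maps: L*, a*, b* (D65, sRGB), depth, per-axis surface-normal
components (k-NN plane fits, k = 12, smallest principal axis, sign
flipped toward the camera), and optionally one activation map per filter
of every convolutional layer of a VGG-16-shaped network, bilinearly
resized to input resolution (the hypercolumn idea; 4224 maps for
VGG-16).  Two providers implement the CNN contract: the real VGG-16
with ImageNet weights (optional extra `vgg`; activations taken after
each ReLU, input shorter side resized to 224 — both configurable) and a
deterministic seeded random-convolution bank with the identical
layer/filter layout, which is the default and keeps the repository
buildable offline.  Providers only change feature values, never shapes
or orderings; activation maps are pooled one at a time, so the ~5 GB
full-resolution stack is never materialized.

Features are mean-pooled over each superpixel's member pixels.

| mode   | unary (dim)                          | edge (dim)                          |
|--------|--------------------------------------|-------------------------------------|
| 2D     | LAB 3 + centroid (r,c)/(H,W) — 5     | |ΔLAB| 3 + |Δcentroid| 2 — 5        |
| 3D     | LAB 3 + centroid xyz (m) — 6         | |ΔLAB| 3 + |Δxyz| 3 + |Δnormal| 3 — 9 |
| 3D+CNN | 3D + mean activations — 6 + #maps    | as 3D — 9                           |

Edge features are componentwise absolute differences: symmetric in the
endpoints, non-negative, zero iff the pooled statistics coincide.  An
optional constant bias column (off by default, so dimensionalities match
the table) gives the CRF feature-independent Potts-style terms.

## Random-forest unaries

Superpixels inherit the majority ground-truth class over their
non-ignore members (ties → lower class code; regions with no labeled
member are excluded from training).  The forest is trained with
per-class weights — by default the inverse class frequency of the
training superpixels — to counter the 70/20/5/5 skew.  The tree count
can be selected by out-of-bag-error convergence on a doubling grid
(tolerance 0.002), and remaining hyperparameters by a cross-validated
grid search whose folds are grouped by viscera set, so views of one set
never straddle folds.  The desk-scale configuration fixes 100 trees and
skips the grid search; at that problem size the forest is insensitive to
the grid and the saved time goes to the CRF stage.  Probabilities are
reported in class order (misc, heart, liver, lung) and are the CRF's
node features.

## CRF

The energy of a labeling y over superpixels s and adjacency edges (a,b)
is

    E(y) = − Σ_s W_u[y_s]·Q_s  −  Σ_(a,b) W_p[y_a, y_b]·F_ab

with Q the RF probability vectors, F the edge features, and W_p a
symmetric K×K table of weight vectors — the model learns *class-pair*
relationships, not just smoothness.  MAP inference: exhaustive
enumeration (≤ 12 nodes), damped loopy max-product (damping 0.5, 50
iterations) polished by ICM — and never worse than plain ICM, which has
no optimality guarantee on loopy graphs either, so the better of the two
is returned — or ICM alone.  All are deterministic with ties resolved to
the lowest class code, and satisfy E(exact) ≤ E(maxprod) ≤ E(icm).

Learning is a margin-rescaled structured SVM with n-slack cutting
planes: per round, loss-augmented MAP per instance, violated constraints
accumulate, and the QP (solved with SLSQP; exact for this convex
program) is re-solved; the objective is non-decreasing in the constraint
set.  Four choices shape its behavior, all adopted after the plain
formulation measurably degraded the forest at small training sizes:

1. **Origin-preserving standardization.**  Features are scaled to unit
   variance but not centred: a zero edge feature means "identical
   superpixels", and centring would make the average edge contribute
   zero potential for every label pair, erasing baseline class-pair
   affinity.
2. **Full-graph training with imputed labels.**  Training instances keep
   every superpixel (ignore-band regions get their unary-argmax label
   and zero loss weight), so training graphs are structurally identical
   to what test-time inference sees.
3. **Symmetric, pixel-weighted class-balanced loss.**  Mislabeling a
   node of true class g as k costs (w_g + w_k)/2 times the node's pixel
   count, with w the inverse class frequency (pixel-level).  Weighting
   by the true class alone makes wrongly *claiming* a rare class nearly
   free, and the learned model over-expands rare classes into
   miscellaneous tissue.
4. **An RF-anchored ridge prior.**  The QP regularizes toward "identity
   unary weights, zero pairwise" (strength `unary_prior`, default 4;
   the pairwise block carries a further ×2 shrinkage).  In the heavily
   regularized limit the CRF reproduces the forest's argmax exactly;
   with the default C = 3×10⁻³ it departs only where training margins
   demand it, flipping mainly low-confidence superpixels — the regime
   where neighborhood context genuinely adds information.  At the API
   level the prior defaults to zero, preserving the classic C → 0 ⇒
   w → 0 behavior.

Under these defaults, desk-scale experiments (below) show the CRF
improving the class-average Jaccard over the forest alone in 9 of 10
seeded runs (mean +2.9 points) while never increasing the number of
connected label components.

## Evaluation

Scoring is pixel-level after projecting superpixel labels back to
pixels; ground-truth background and ignore pixels are excluded.  Per
class, J = tp/(tp+fp+fn)·100; the headline number is the unweighted mean
over the four classes, so the skew cannot hide failures on small organs.
Confusion counts are pooled over all test images before computing
Jaccard (pixel-level aggregation); classes absent from the pooled ground
truth are flagged and excluded from the average rather than scored 0/0.
Row-normalized confusion matrices account for the imbalance.

The achievable segmentation accuracy (ASA) relabels each superpixel with
the ground-truth class of largest intersection and reports the resulting
pixel accuracy — the upper bound the oversegmentation imposes (1 =
perfect boundary adherence).  Pixel accuracy ≤ ASA holds exactly by
construction.  The per-class Jaccard of that same best-case relabeling
is reported as the "achievable" Jaccard; note it is a best-case
*accuracy* labeling, not a per-class optimum, so a pipeline can exceed
it by a hair on a near-saturated class — comparisons use a
0.1-percentage-point tolerance.

## Experiment protocol and problem sizes

`run_experiment` splits sets 91/30/30 by default (RF-train / CRF-train /
test; the CRF trains on RF probabilities predicted out-of-training, a
leakage point many re-implementations get wrong), runs all stages, and
reports RF-only and RF+CRF metrics plus the ASA bound.  All randomness
descends from one seed; equal configurations produce byte-identical
metrics.

`desk_config` is the package's reference configuration for laptop-scale
experiments and for the test suite: 30 sets (20/5/5) at 120×160, a
0.45 m working-volume depth clip (the viscera hang at ~0.35 m, the
background plane at ~0.55 m), 100 trees, 20-mm/6-px seed pitches.  One
full 3D experiment takes ~20 s on one core.  Real-time throughput is a
non-goal.

## Known limitations

- Loopy max-product carries no optimality guarantee; the ICM fallback
  bounds it from above but inference on cyclic graphs remains
  approximate.
- The SSVM working set is not pruned; very long cutting-plane runs grow
  the QP (capped at 30 rounds by default).
- The 3D mode estimates normals before the working-volume clip is
  applied to clustering, so normals at the clip boundary use neighbors
  on one side only.
- The random-convolution provider shares only the *layout* of VGG-16;
  its features are untrained projections and should not be expected to
  match ImageNet-trained activations in discriminative power.
- Synthetic-data conclusions transfer to real viscera only to the
  extent the generator's assumptions (see above) hold.
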