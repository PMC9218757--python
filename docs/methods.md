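# Methods

This note documents the models, parameters and design choices behind
`rgbdfruit`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, what the synthetic benchmark does and does not
represent, and where the approach is known to break.

## Center location from the depth gradient field

A spherical fruit surface seen by a range camera is a convex bowl in the
depth map D (range in mm, smaller = nearer, 0 = sensor hole). Its
gradient ∇D = (u, v) points radially outward from the projected fruit
center. Rotating each vector 90° screen-clockwise, (u, v) → (−v, u) under
the image convention (x right, y down), converts the diverging field into
a vortex circulating around the center.

Two identities anchor the implementation:

* The curl of the rotated gradient equals the divergence of the original
  gradient — the depth Laplacian. With identical finite-difference
  stencils this identity is exact to rounding, and the test suite asserts
  it at 1e−6. It is a discretization check, not the detection signal.
* For a *unit-speed* vortex the curl grows like 1/r toward the center.
  This is what makes center detection work: the raw Laplacian of a fruit
  bowl is dominated by the depth step at the silhouette (a rim ring, not
  a center peak), whereas the direction-only field concentrates its
  circulation at the center regardless of the step size.

The detection branch therefore conditions the rotated field before taking
the curl: each vector is rescaled to magnitude |g|/(|g| + g₀) with
`gradient_floor` g₀ = 0.5 mm/px, which approaches unit speed for genuine
object gradients but damps the weak, incoherent gradients of sensor noise
and gentle background relief (whose direction-only vortices would
otherwise score as well as fruit). Vectors stronger than
`gradient_ceiling` = 3 mm/px are zeroed entirely: they occur only at
depth discontinuities (fruit silhouettes, branch edges), and their
spurious circulation is what displaces centers in occluded scenes.

The conditioned curl is integrated at two scales, σ and 2σ
(`omega_smoothing_sigma` = 8 px), each response multiplied by its σ so
fruit of different pixel radius score comparably (standard scale-space
normalization for a 1/r response). Centers are positive local maxima of
the combined response above `vorticity_threshold` = 0.3 of the global
maximum, separated by at least `center_min_distance` = 20 px. A band of
2σ along the image border is excluded: one-sided stencils and smoothing
boundary conditions make the response there untrustworthy.

Depth is pre-smoothed with a masked Gaussian (`smoothing_sigma` = 4 px)
in which invalid pixels carry zero weight and the result is renormalized;
the same operation inpaints holes for the detection branch, so scattered
sensor dropouts (a few percent of pixels) neither punch gaps into the
field nor bias local means. Iso-depth contour extraction
(marching squares at `contour_interval` spacing) is provided for
inspection only; nothing downstream consumes it.

## Superpixels and features

The RGB frame is converted to CIE L\*a\*b\* (D65) and partitioned by SLIC:
seeds on a regular grid of step S = round(√(N/k)), each seed moved to the
lowest-L\*-gradient pixel of its 3×3 neighbourhood, then localized
k-means over Dis = sqrt(dc² + (ds/S)²·m²) within 2S×2S windows, with
centers updated to block means until no center moves 0.5 px or 10
iterations pass. Disconnected fragments below S²/16 px merge into an
adjacent block so the partition is usable downstream. Defaults
k = 150 and m = 10: at 512×424 this gives ~38 px blocks, small enough to
follow fruit boundaries that matter at the fitting stage, large enough
that block feature means are stable (~1400 px per block) and that the
density statistics of the clustering stage are meaningful.

Each block contributes the feature point (mean R−B, mean G−B) computed
from the raw RGB channels. The blue channel carries little
fruit/foliage contrast, so these two differences discount illumination
while preserving the small colour offset of green fruit against leaves;
the features are kept in raw intensity units (range −255…255) and the
KDE bandwidth absorbs the scale.

## Density-peak clustering with KDE density

For n blocks with pairwise Euclidean distances d_ij:

* local density by Gaussian KDE,
  ρᵢ = 1/(nh) Σⱼ K((xᵢ−xⱼ)/h, (yᵢ−yⱼ)/h),
  K(x,y) = exp(−(x²+y²)/2σ²)/(2πσ²), self term included. h and σ are
  redundant scales; h is fixed at 1 and only σ exposed. The classic
  hard-cutoff count ρᵢ = #{j≠i : d_ij ≤ d_c} is retained for comparison
  but is not the default — the KDE removes the manually chosen d_c.
* separation δᵢ = min distance to a denser point (for the global maximum,
  the max distance to any point), with exact density ties broken by index
  so the whole stage is deterministic.
* centers by double sorting: among the `n_density_top` = 60 densest
  blocks, the `n_delta_top` = 4 with the largest δ.
* one-pass chain assignment: visiting points by decreasing ρ, each
  non-center inherits the label of its nearest denser neighbour. No
  iteration, no random initialization.
* coverage pruning: clusters ranked by member pixel count; the top
  `n_keep_clusters` = 4 survive, members of pruned clusters reattach
  along their chains (or to the nearest kept point in feature space).

The bandwidth default is fixed at σ = 2.0 intensity units rather than
Silverman's rule: Silverman assumes a unimodal cloud and, on the strongly
multi-modal block clouds these scenes produce, over-smooths until the
fruit mode dissolves into the canopy slope. σ = 2 is of the order of the
within-mode block spacing at k = 150. (`cluster_blocks` still applies
Silverman when no bandwidth is given, for exploratory use on other data.)

The selection counts deserve a note, because they are the stage's real
degrees of freedom. `n_delta_top` is what bounds the number of clusters,
and it should be of the order of the number of feature modes actually
present — here four: fruit, sunlit foliage, shaded foliage, branches.
Substantially larger values plant redundant centers inside each mode and
fragment it; the fragments then lose the coverage ranking and the fruit
is pruned into the background. `n_density_top` is only a gate that keeps
delta-outliers of negligible density from becoming centers, and it should
be loose (here 60 of ~150 blocks ≈ the densest 40%) so that every genuine
mode peak passes it; the δ sort does the discriminating.
`n_keep_clusters` must cover all real modes (4), otherwise the smallest
genuine mode — usually the fruit — is pruned. With these counts the
stage is self-healing: an occasional extra center inside a mode captures
only a small shard, and pruning reattaches shards along the density
chains.

## Fusion and radius fitting

Per-block cluster labels are painted onto pixels and split into
8-connected components. Each detected center claims the component under
its pixel; components larger than `max_region_fraction` = 0.45 of the
frame (background canopy) or smaller than `min_region_px` = 150 px drop
their centers. Several centers in one component flag all of them as
overlapping.

The boundary profile marches 360 rays from the center and records where
each ray first leaves the component. For an isolated fruit the radius is
the profile maximum — occlusions bite wedges out of the region, but the
unoccluded directions still reach the full rim. For overlapping fruit the
profile is smoothed circularly over ±10°, plateau-aware local maxima are
extracted, and the radius is the smallest of them: rays through the
partner fruit reach its far rim (a large maximum), while the own rim
produces the small one. A constant profile (no local structure) falls
back to the max rule. Fitted circles below `min_radius_px` = 10 px are
discarded as stray centers near a region edge.

Evaluation declares a detection correct when its center lies inside the
true circle and the circle IoU is ≥ 0.5, matched greedily one-to-one by
IoU within each scene (matching never crosses scene boundaries);
recognition rate is matched truths over all truths, reported overall and
per category, along with mean center error (px) and mean relative radius
error over the matched pairs.

## Synthetic scenes

The generator renders what the algorithm actually consumes, not
photorealism:

* orthographic depth at 2 mm/px: fruit pixels get the sphere-surface
  range z_c − s·√(r² − d²) (convex bowl, minimum at the center), the
  nearer surface wins where fruit overlap, occluders lie between fruit
  and camera; background is a plane plus low-frequency ripple
  (25 mm, ~40 px correlation) so the background field is irregular;
  Gaussian sensor noise (5 mm) and uniformly scattered zero-valued holes
  (5%) finish the frame.
* colour: the fruit, foliage and branch means differ by at most 15
  intensity units per channel — the near-colour condition that defeats
  colour-only segmentation. Fruit gets mild limb darkening (shade floor
  0.88) and 4% multiplicative skin mottle; the canopy brightness field is
  bimodal (sunlit faces vs deep interior shadow, via a sigmoid of a
  smooth field) with independent smooth hue (±8 on G) and redness (±3 on
  R) variation per leaf patch; branches are drawn as rotated
  rectangles/ellipses.
* geometry: close-range frames, fruit radius 22–27% of the frame's short
  side (95–115 px at 512×424, i.e. fruit covering ~13–19% of the frame,
  an overlapping pair up to ~30%), matching harvesting imagery where the
  target fruit dominates the view. This scale is not incidental: the
  segmentation stage identifies the fruit as one of the scene's dominant
  feature modes by pixel coverage, which presumes close-range framing.
  On wide framings where fruit covers a few percent of the image the
  coverage ranking cannot distinguish the fruit mode from canopy
  sub-structure, and segmentation degrades — a genuine applicability
  limit of the method, not of the simulator.
* ground truth: center, radius and a category per fruit — overlapping if
  fruit discs intersect (dominant), occluded if an occluder crosses the
  disc, else single — recomputable from geometry alone. Benchmarks draw
  categories per scene as (0.55, 0.17, 0.28) and are fully determined by
  one seed.

What passing on these scenes does not show: robustness to real Kinect
noise spectra (flying pixels, correlated edge dropout), specular
highlights, wind-blurred RGB/depth misregistration, or fruit colours that
drift with ripeness. The generator's foliage is statistically textured
but not leaf-structured, so SLIC boundaries are easier than on real
canopies.

## Numerical and procedural details

* All stages are deterministic given the configuration; the only RNG in
  the package is the scene generator, fully driven by explicit seeds.
* Exact density ties break by point index (lower = denser); equidistant
  nearest-denser neighbours resolve to the denser, then lower-indexed
  candidate; coverage ties break by lower cluster id.
* Degenerate inputs: an all-invalid depth map raises; a vorticity map
  with no positive response returns an empty center set (not an error);
  a scene with no detected fruit yields zero detections and exit code 0.
* Problem sizes in the shipped tests and the acceptance script — 50
  single-fruit scenes for center recovery, 30 mixed scenes for
  segmentation and end-to-end rates, 20 random fields for the curl
  identity, 50 random instances for the brute-force oracle checks — were
  chosen so the whole suite replays a representative benchmark in a few
  minutes on one CPU.

## Known limitations

* Branch-occluded fruit: branch edges perturb the conditioned field, so
  occluded centers localize to ~4–10 px rather than ~1 px; with the max
  radius rule this still recognizes the fruit but inflates the radius.
  When a branch bisects the fruit region, the profile may reach only the
  nearer sub-region, under- or over-shooting the radius; no repair is
  attempted.
* Background vorticity dimples (ripple minima) above the relative
  threshold produce false centers. Most die at the region-plausibility
  gate, but some survive as false circles in canopy components of
  plausible size; the evaluation metric (recognition = recall at
  IoU ≥ 0.5) is insensitive to them, and no precision-oriented
  suppression is built in.
* The cluster-count machinery assumes the scene decomposes into a handful
  of colour modes with the fruit among the dominant ones by coverage;
  wide framings or heavily mixed canopies violate this (see above).
* Radius precision is bounded by superpixel granularity (~38 px blocks at
  the defaults); expect mean relative radius errors of 5–10%, not
  sub-pixel circles.
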