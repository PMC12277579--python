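# Methods

## Problem and model

Input images show cereal grains scattered loosely on white paper: grains may
be isolated or touching in small clusters, and individual kernels carry
chips, dents and bumps. The package counts grains per image and labels each
boundary pixel with the grain it belongs to. The shape model is the ellipse:
a wheat kernel's outline is close to elliptical (axis ratio roughly 1.6–2.4),
which is what licenses both the corner-based split of compound contours and
the least-squares elliptical regrouping of their arcs. Bean-shaped or
strongly non-elliptical seeds are outside the model.

## Pipeline

### Preprocessing

- **Bilinear 2× downsampling.** Non-overlapping 2×2 windows are replaced by
  their bilinear midpoint, which reduces to the per-channel mean of the four
  pixels; values are rounded half-up for platform determinism. A 3968×2976
  capture becomes 1984×1488, the working resolution at which all later
  stages (and the default CRF radius) operate. `downsample_factor = 1`
  skips the stage for inputs already at working resolution — the synthetic
  generator's default canvas is 1984×1488, so evaluation runs use factor 1.
- **Gaussian filter.** 5×5 kernel; sigma derived from the kernel size
  (0.3·((k−1)/2 − 1) + 0.8) unless set. Both unstated in the source method;
  these are the common denoising defaults.
- **HSV conversion, channel choice.** Grains on white paper separate most
  reliably in saturation (paper is near-achromatic regardless of shading),
  so Otsu runs on the saturation channel by default with the *high* class as
  foreground; `value` or `luma` channels (foreground low) are available.
  All HSV channels are scaled to 0–255.
- **Mean-shift smoothing.** Flat-kernel joint spatial/color mean shift
  (spatial half-width 10 px, color radius 20, ≤ 5 iterations, convergence at
  0.5 intensity units). The reference parameterization is unpublished;
  these are typical values for flattening paper texture and intra-grain
  gradients. Implemented as a numba kernel; flat regions converge in one
  iteration so the cost is near one window pass per pixel.
- **Otsu threshold.** Exhaustive 256-bin between-class-variance maximum.
  On an empty histogram valley the maximum is a plateau; the plateau
  midpoint is returned so the threshold sits centrally between modes.
  Constant images raise (no threshold exists).
- **Dust removal.** Components under 30 px (post-downsampling) are dropped.

### Contours and corners

Connected foreground components (8-connectivity) are traced with
Moore-neighbor boundary following into closed, 8-connected pixel chains,
oriented consistently; holes are ignored. The corner response function at
contour pixel *p* counts the region's grain pixels within the raster disk
of radius *R* (Euclidean distance on pixel centers, clipped at image
borders) over the disk pixel count. "Grain pixels" means the filled region
bounded by the contour, not the one-pixel contour curve — a curve-only
count could never reach the straight-edge value 0.5 at *R* = 7.

*R* = 7 (at working resolution) and threshold 0.6 are the empirical values
of the source method; both are configurable (*R* over [3, 10]). Corner
*regions* are maximal cyclic runs of contour pixels with CRF above the
threshold; each run is represented by its CRF peak (ties to the lowest
contour index, for determinism). Runs of length 1 count; runs separated by
a single sub-threshold pixel are not merged — the partition stage tolerates
spurious corners by design.

The corner-point estimate is `max(1, n_corners/2 − r_closed + 1)`. Odd
corner counts (raster noise) are rounded up with a warning. The reference
definition of `r_closed` ("number of contour boundary segments between
corner points") is degenerate as written; it is implemented as the count of
segments whose two endpoint corners coincide — possible only for
single-corner contours — and is zero on all scenes generated here. The cp
estimate is retained as the comparison baseline.

### Ellipse fitting

Segments between corners (corner representatives excluded; run pixels kept
— trimming them was tried and measurably hurt) are pooled per candidate
subset and fitted with the conic
a₁₁x² + 2a₁₂xy + a₂₂y² + 2b₁x + 2b₂y + 1 = 0 by linear least squares
(SVD). Coordinates are centered on the centroid and isotropically scaled to
RMS radius √2 before solving — without conditioning the quadratic system is
ill-posed at image-scale coordinates — and the conic is mapped back
afterwards. The stored residual ‖Dα + 1‖² lives in the conditioned frame,
making it comparable across subsets of different physical size and
invariant (to 1e−9 relative) under rigid motion of the input. Validity
requires a positive conic discriminant and a real, positive-axis ellipse.
Fewer than five distinct points is an error; degenerate conics (collinear
input) are returned invalid rather than raised.

### Partition search

All set partitions of a contour's *k* segments are enumerated in
restricted-growth-string order (Bell(*k*) candidates; *k* ≤ 10 by default,
Bell(10) = 115 975; beyond that the contour falls back to the cp estimate,
flagged per contour). Per-subset ellipse fits are memoized across
partitions, so at most 2^k fits are computed. The score of a partition is

    Σ_subsets residual / n_pixels  (+ λ · center-dispersion penalty)

subject to feasibility: every subset needs ≥ 5 distinct pixels and a valid
ellipse fit, and two physical-consistency constraints reject inconsistent
partitions outright:

- **Disjointness.** Fitted ellipses of two subsets may not intersect by
  more than `overlap_max_frac` (default 0.2) of the smaller one's area
  (polygonal intersection, 64-gon approximation). Real grains are disjoint
  objects; ordinary fit error and raster tangency between touching grains
  produce overlaps of a few percent, whereas a duplicate ellipse fitted to
  fragments of an already-counted grain overlaps it by half or more.
- **Support.** A subset must contribute at least `support_min_frac`
  (default 0.3) of its fitted ellipse's perimeter (Ramanujan
  approximation) in pixels. Loosely placed grains expose most of their
  outline — an isolated grain near 100 %, a grain inside a 2–4 cluster
  typically well over 60 % — while a handful of chip-wall fragments
  "supports" only a few percent of whatever large ellipse happens to pass
  through them.

Ties break toward fewer subsets, then enumeration order. The winner's
subset count is the grain count; corner pixels are assigned afterwards to
the adjacent subset whose ellipse explains them best (smaller algebraic
residual).

**Why the dispersion penalty is off by default.** The source method adds a
penalty for subsets whose individually fitted segment ellipses disagree
about the center, normalized by the smallest inscribed semi-minor axis B;
its exact form is not recoverable from the source (figure-rendered), so
this package reconstructs it as the mean distance between per-segment fit
centers and the union-fit center, divided by B, with weight λ. Measured on
seeded scenes (28 contours, grains touching in clusters, 20 % chipped),
λ = 1 counted 11/28 contours correctly (systematic over-splitting) and even
λ = 0.05 degraded accuracy, while the pure normalized residual scored
28/28. The cause is structural: centers of ellipses fitted to partial arcs
are underdetermined by tens of pixels, and the penalty taxes only merged
subsets, so it pushes the argmin toward splitting — the opposite of its
stated purpose. The per-point residual normalization already does the
advertised job (each subset pays a noise-floor term, so consistent segments
merge and inconsistent ones split), and the two feasibility constraints
above implement the penalty's physical intent — several inscribed ellipses
describing one grain indicate incorrect partitioning — robustly. The term
remains available (`lam`), with unreliable sliver fits gated out.

### Baselines and metric

Count accuracy is CR = 1 − |N\* − N| / N: 1 exactly at the true count,
decreasing linearly and symmetrically in the error (reconstructed from the
reported value range; the source formula is figure-rendered). The watershed
baseline marks local maxima of the Euclidean distance transform (minimum
separation = half the configured minimum grain diameter, default 30 px),
floods, and counts basins above the minimum area. It deliberately carries
no shape model and over-segments elongated kernels whose distance ridge
holds several maxima — the weakness the contour methods exist to fix. An
erosion-based baseline is not implemented (no operational description
available).

## Synthetic scenes

`generate_scene` emulates the target imaging setup: a 1984×1488 canvas
(white paper, ~248 mean, σ = 2 noise), tan/brown elliptical grains
(semi-major 48–72 px, axis ratio 1.6–2.4, per-grain color jitter ±18,
per-pixel σ = 3, ~1 % radial boundary wobble), a `touch_fraction` share of
grains placed tangent to an earlier grain in clusters of 2–4 (raster
overlap of a few pixels at the contact), and chips — circular bites of
radius 10–25 % of the minor axis centered on a boundary point away from any
contact — with probability `chip_probability`. All randomness flows from
one seeded generator; a scene is a pure function of (parameters, seed).
Grain sizes were chosen so kernels span ~100–145 px at working resolution,
matching the regime in which R = 7 discriminates notches from convex arcs.

What the generator does **not** emulate: uneven illumination and shadows,
specular highlights, camera noise structure, perspective distortion,
non-elliptical kernels, dust, and dense packing (grains piled on top of one
another). A green test therefore establishes correctness of the geometry
and search machinery under the stated shape model, not robustness to
photographic artifacts.

## Numerical choices

- Rounding is half-up everywhere pixel values are produced.
- Disk membership uses Euclidean distance ≤ R on pixel centers, matching
  the brute-force oracle exactly.
- Corner ties and partition ties are broken deterministically (lowest
  index; fewest subsets; enumeration order).
- The ellipse-polygon approximation for the overlap test uses 64 vertices;
  the perimeter uses Ramanujan's approximation (error ≪ 0.1 % at the
  aspect ratios involved).
- Seeds: every stochastic component takes an explicit integer seed.

## Known limitations

- Contours with more than `max_segments` segments (heavily clustered or
  heavily chipped regions) fall back to the cp estimate, which over-counts;
  the fallback is flagged per contour.
- Corner regions wider than the corner run (very deep chips) leave
  chip-wall pixels inside segments, raising fit residuals; counting
  remains correct in the tested regimes but per-grain ellipse parameters
  near deep chips are less accurate.
- The cp estimator's `r_closed` term is effectively inert (see above).
- Watershed marker policy is a standard reconstruction, not a calibrated
  reference implementation.
- Runtime grows with the Bell number of the segment count per contour;
  densely packed scenes are out of scope.
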