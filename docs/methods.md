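# Methods

## Problem and model

`octlumen` segments the lumen boundary in cross-sectional intravascular
OCT frames. The underlying model of a frame is radial: seen from the
catheter center, the first bright structure beyond the catheter ring is
the vessel-wall band, and the lumen boundary is the near edge of that
band. The algorithm therefore works in polar coordinates about the
catheter center and reduces segmentation to choosing one boundary point
(knot) per angular domain, then interpolating a smooth closed curve
through the knots. The closed interpolating cubic B-spline (a NURBS with
all weights 1) is what makes the method robust to artifacts: domains
erased by guidewire shadows or side-branch openings simply contribute no
knot, and the spline bridges the gap with a smooth arc — no inpainting
or coordinate-system transformation is needed.

Assumptions: the catheter center is known (default: image center) and
lies inside the lumen; the lumen is star-shaped about it (every radial
ray crosses the boundary once); the wall band is brighter than the fixed
binarization threshold while lumen and background are darker.

## Pipeline constants

| Parameter | Default | Units | Role |
|---|---|---|---|
| `median_kernel` | 5 | px | speckle suppression window |
| `morph_kernel` | 5 | px | opening structuring element |
| `binarize_threshold` | 164 | 8-bit intensity | wall/lumen separation (fixed, not per-image) |
| `canny_sigma` | 1.0 | px | Gaussian smoothing before gradient |
| `canny_low`, `canny_high` | 0.2, 0.6 | fraction of max gradient | hysteresis thresholds |
| `n_domains` × `domain_width_deg` | 30 × 12 | — / deg | angular partition (product fixed at 360) |
| `min_edge_count` | 6 | points | domain population floor; sparser domains are artifact gaps |
| `min_knot_spacing_mm` | 0.25 | mm | knot de-duplication floor |
| `max_curvature_per_mm` | 5 | mm⁻¹ | implausible-knot ceiling |
| `center_mask_radius_mm` | 0.4 | mm | excludes catheter-ring edges from knot selection |
| `min_knots_for_fit` | 4 | knots | floor for a closed cubic fit |
| `frame_spacing_mm` | 0.2 | mm | pullback frame interval (speed/frame-rate dependent; configurable) |

Binarization uses the ≥ convention (pixel ≥ 164 → 1); the boundary case
is exposed in config. Median filter and morphology use half-sample
reflect padding so the image border does not generate spurious dark
rims. Canny thresholds are specified as fractions of the maximum
gradient magnitude of the Gaussian-smoothed input, so on a {0,1} image
the detector reduces to clean boundary extraction regardless of scale.

## Design choices where the design was open

- **Angle convention.** Angles run anticlockwise from +x in physical
  (y-up) coordinates; since image rows point down, the pixel-y offset is
  negated. Domains are half-open `[i·12°, (i+1)·12°)`.
- **Shortest-ray tie-break.** Equal radii within a domain resolve to the
  smallest angle.
- **Spacing filter order.** Traversal starts at the first knot
  anticlockwise; of a violating consecutive pair the *later* knot is
  dropped; passes repeat to a fixpoint, wrap-around pair included. The
  postcondition — every surviving cyclic pair ≥ 0.25 mm apart — is the
  contract; it is verified against an independent greedy oracle.
- **Curvature estimator.** Discrete curvature at a knot is the Menger
  (reciprocal circumradius) curvature of its consecutive triple.
  Removal is iterative: remove the single worst offender, recompute
  neighbors, repeat until all κ ≤ 5 mm⁻¹ or the 4-knot floor is reached
  (then the result is flagged). Note the geometric bound κ ≤ 2/|p₁p₃|:
  on a sparse knot set a high-curvature spike is unrepresentable, which
  is why curvature-probe suites use dense knot sets.
- **Spline parameterization.** Chord length, rescaled to [0, 1], via a
  periodic cubic B-spline interpolant; interpolation residual at the
  knots is at machine precision (contract: ≤ 10⁻⁶ mm).
- **Diameters.** The mean/min/max diameter is taken over chords through
  the area centroid at 1° steps (so an ellipse gives exactly its
  principal axes). A Feret-diameter alternative was rejected to keep the
  ellipse-axes convention. "Mean diameter" is the chord mean, not
  2·√(area/π).
- **Loft correspondence.** Rings are resampled at equal polar angles
  about each contour's centroid, angle 0 first, and joined
  index-to-index — exact for star-shaped contours sharing the angular
  parameterization, and it makes plane slices of the mesh reproduce the
  contour area. The pullback axis is straight; curved catheter paths are
  out of scope.
- **Failure policy.** A frame that yields fewer knots than the fit floor
  is returned flagged (`unsegmentable`), never raised, so one bad frame
  cannot abort a pullback run; flagged frames are excluded from the mesh
  and from agreement statistics, mirroring a workflow where such frames
  go to manual correction.

## The phantom generator

The synthetic frames emulate the intensity structure that the fixed
threshold relies on: background 10, lumen 30, wall band 220, catheter
ring 200 (8-bit means), with multiplicative Gamma speckle (mean 1,
CV = `speckle_scale`, default 0.3) and nearest-pixel rasterization on a
512×512 grid at 0.01 mm/px. Lumen shapes are circles, ellipses, and
Fourier-perturbed circles r(θ) = r₀ + Σ aₖcos(kθ+φₖ) (area closed form
π(r₀² + ½Σaₖ²)); guidewire shadows are dark wedges from the catheter
ring outward; side branches are angular gaps in the wall band. Ground
truth (area, centroid-chord diameters) is computed from the analytic
r(θ), not from pixels.

The default validation suite is 50 frames cycling through the three
shape families with effective radii 1–2.5 mm, speckle on, one shadow
wedge of 8–24° per frame, and a 12–20° branch gap on every third frame.
All randomness derives from a single seed; frame i uses a sub-seed from
`SeedSequence([seed, i])`, so runs are bit-reproducible.

What the phantoms do **not** emulate: A-line physics (attenuation,
speckle correlation, sew-up artifacts), residual luminal blood swirls,
eccentric catheter motion between frames, thrombi/dissections, and
non-star-shaped lumens. Passing phantom recovery therefore demonstrates
correctness of the geometry pipeline under the stated intensity model,
not clinical-grade accuracy on pathology.

## Numerical notes

- The `d_min ≤ d_mean ≤ d_max` invariant is enforced with 10⁻⁹ relative
  tolerance: on a circle all chords are equal and float summation can
  place the mean above the max by ~10⁻¹⁶.
- Shoelace area uses 720 samples by default; the inscribed-polygon bias
  for a circle at n = 720 is ~6·10⁻⁶ relative.
- Degenerate inputs: empty edge maps yield empty point lists (not
  errors); an all-dark frame is flagged; a zero-area contour is rejected
  at loft time with its frame index; exporting an empty mesh is an
  error.
- Problem sizes in the test suite (50-frame suites, 10⁶-sample oracle
  polygons, 100-set filter probes) were chosen so the whole validation
  runs in well under a minute on a single core while leaving the
  acceptance tolerances un-saturated.

## Known limitations

- The fixed threshold 164 presumes vendor-normalized 8-bit intensities;
  frames with different normalization need a config override.
- Catheter-center detection is not implemented; an off-center or
  out-of-lumen center violates the radial model.
- Lumens that are not star-shaped about the centroid (strongly lobed
  bifurcation frames) get approximate diameters and a warning.
- The 3D model stacks frames on a straight axis; no angiography fusion.
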