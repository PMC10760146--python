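# octlumen

Automatic lumen segmentation for intravascular optical coherence
tomography (OCT), with per-frame morphometry, lofted 3D lumen
reconstruction, and Bland–Altman/regression agreement analysis.

Intravascular OCT produces high-resolution cross-sectional frames of a
coronary artery during a motorized catheter pullback. The blood-cleared
lumen appears dark, the vessel wall as a bright band, and the frames
carry characteristic artifacts: a bright catheter ring near the center,
dark guidewire-shadow wedges, and angular wall gaps where side branches
open. `octlumen` segments the lumen boundary of each frame in a fraction
of a second without any training data, making it suitable for near-real-
time 3D visualization in the catheterization laboratory. Validation runs
entirely on synthetic phantom frames with analytically known geometry.

## Method

Each frame passes through a fixed chain:

1. **Preprocessing** — grayscale conversion, 5×5 median filtering
   (speckle suppression), grayscale morphological opening (5×5 erosion
   then dilation), binarization at the fixed 8-bit threshold **164**,
   and Canny edge detection on the binary image.
2. **Knot selection** — every edge pixel becomes a ray from the catheter
   center; rays are grouped into **30 domains of 12°** (anticlockwise).
   In each domain with at least **6** edge points, the shortest ray's
   endpoint becomes a knot point; under-populated domains (guidewire
   shadows, branch gaps) contribute nothing.
3. **Geometric filters** — knots closer than **0.25 mm** to their cyclic
   neighbor are dropped (greedy anticlockwise, to a fixpoint), then
   knots whose Menger curvature κ = 1/R_circum exceeds **5 mm⁻¹** are
   removed iteratively with recomputation.
4. **Contour** — the surviving knots are joined anticlockwise by a
   closed interpolating cubic B-spline (a NURBS with unit weights),
   which bridges the artifact gaps smoothly.
5. **Morphometry** — lumen area by the shoelace formula over 720 curve
   samples; minimum/maximum/mean diameter as chords through the area
   centroid at 1° resolution.
6. **3D reconstruction** — per-frame contours stacked along a straight
   pullback axis and lofted into a watertight triangle mesh (binary STL
   or OBJ export).
7. **Agreement** — Bland–Altman bias and 95% limits of agreement
   (bias ± 1.96·SD, n−1 denominator) plus OLS regression of proposed on
   reference, per metric.

## Worked example

Generate a 12-frame synthetic pullback (mixed circular, elliptical, and
Fourier-perturbed lumens with speckle, shadow wedges, and branch gaps),
segment it, and score against the analytic truth:

```sh
octlumen phantom --seed 1 --n-frames 12 --output-dir suite
```

which prints

```
segmented 12/12 phantom frames
area [mm^2] (n=12)
  bias (proposed - reference): -0.0026
  SD of differences:           0.0237
  95% limits of agreement:     -0.0491 to 0.0439
  regression: Y = 1.0002 X + -0.0044  (r = 1.0000, R^2 = 1.0000, p = 8.96e-24)
d_mean [mm] (n=12)
  bias (proposed - reference): -0.0005
  SD of differences:           0.0037
  95% limits of agreement:     -0.0076 to 0.0067
  regression: Y = 1.0003 X + -0.0017  (r = 1.0000, R^2 = 1.0000, p = 2.58e-24)
...
```

All 12 frames segmented; the area bias of −0.003 mm² on lumens of
3–20 mm² and the near-identity regression line say the automatic
contours track the analytic truth to well under a percent. The output
directory contains the rendered frames, per-frame contours
(`contours.csv`/`.json`), a metrics table (`metrics.csv`), the lofted
lumen surface (`lumen.stl`), the analytic ground truth, and the
agreement report.

Other subcommands: `octlumen segment` (your own PNG/TIFF stack →
contours + metrics + mesh), `octlumen validate` (two contour CSVs →
agreement report), `octlumen reconstruct` (contour CSV → STL/OBJ). All
constants are overridable via flags or a flat `key = value` config file
(defaults < file < flags).

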