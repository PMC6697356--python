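# Methods

## Pipeline model and assumptions

The filter assumes a two-sensor RGB-D rig with known pinhole intrinsics for
both sensors and a known rigid extrinsic transform between them (calibration
is an input, never estimated here), an *organized* depth image (one depth
sample per pixel, 0 = missing), and a scene in which the scanned object is
markedly brighter than the platform/background it rests on. Under those
assumptions outliers — which arise at silhouettes, shadows and reflective
edges — sample dark background colors in the mapping image, so thresholding
the HSV value channel removes them together with the background while the
bright object survives.

Stage order: color-to-depth alignment → organized cloud construction →
optional 3D bounding-box zeroing → RGB normalization → HSV → V histogram →
Otsu threshold → binarization → mask refinement → mask-based extraction.

### Alignment conventions

* Pixel centers, 0-based, continuous coordinates; u = column, v = row. The
  same convention is applied to both sensors, so no half-pixel offsets
  appear anywhere.
* Color sampling is **nearest pixel** (round half away from zero), not
  bilinear: the mapping image then contains only RGB triples actually
  present in the color image, which makes the downstream histogram and
  threshold bit-exactly reproducible.
* Projections falling outside the color image mark the pixel invalid rather
  than clamping — clamping would fabricate rim colors.
* Occlusion is **not** resolved: two depth pixels may sample the same color
  pixel. This is a documented limitation of the one-pass alignment; it only
  matters near silhouettes at the (small) stereo baseline.
* Depth is meters internally; 16-bit PNG I/O applies `depth_scale`
  (default 0.001 m/unit, the RealSense convention).
* Alignment in the opposite direction (depth onto the color grid) is the
  same composition with the roles of the sensors swapped; the pipeline only
  uses color→depth, so only that direction is implemented.

### Bounding-box pre-filter

Closed inequalities on all three axes; out-of-range pixels are zeroed
(point, color and validity), never deleted, preserving the grid topology
the mask stage depends on. The box is assumed to live in the depth-camera
frame. Default: disabled (unbounded box) — no universally sensible numeric
box exists.

### Segmentation

* L = 256 levels, 0-based. V in [0, 1] is quantized with
  `level = floor(V·(L−1) + 0.5)`, so 8-bit inputs round-trip exactly (the
  level is the max channel byte).
* The histogram counts **valid pixels only** (depth present, in-box, color
  mapping valid). Zeroed/invalid pixels would flood level 0 and corrupt the
  threshold; the method segments object vs platform/noise, not vs synthetic
  zeros.
* Achromatic pixels have undefined hue; H = 0 by convention. Only V is
  thresholded, so the convention is inert.
* Threshold search scans k = 0..L−2 (both classes nonempty); ties are
  resolved to the **smallest** k for determinism.
* Binarization keeps levels ≥ k_opt as target (a level exactly at the
  threshold is target); invalid pixels are background.
* Refinement: morphological closing (square kernel, default 3×3, one
  iteration), interior hole filling (background flood fill from the image
  border, 4-connected background complementing 8-connected foreground), and
  an area filter erasing 8-connected components smaller than s_th pixels.
  Kernel size and iterations are not canonical; the defaults are
  configurable.
* s_th defaults to 5000 px at 640×480 (a value suited to a last/foot-sized
  object silhouette) and scales linearly with the frame's pixel count, so
  the default synthetic frames (160×120) use 312 px.

**Boundary-convention limitation.** With smallest-k tie-breaking, the argmax
of σ²(k) always lands on the top populated level of the lower class
(σ² is flat across an empty histogram valley), and the closed lower boundary
of the binarization keeps that level as target. Consequently a *perfectly*
two-valued image is not exactly separated — the lower constant sits exactly
at the threshold level and is kept. On images with continuous noise the
effect reduces to a handful of isolated valley-level pixels, which the area
filter erases; the end-to-end tests confirm total outlier removal under the
default study conditions.

### Baselines

SOR and ROR are implemented from scratch against an explicit contract:
exact equivalence with an all-pairs brute-force reference (the k-d tree is
an implementation detail). Self-exclusion in all neighbor queries;
population (ddof = 0) standard deviation in SOR; removal uses a strict
inequality. Reference parameters (SOR k = 15, σ = 0.5; ROR r = 2 mm,
num = 12) presume a dense sub-millimeter structured-light point pitch; on
the synthetic scenes (~4 mm pitch at 0.6 m with f = 150 px) the ROR radius
must be scaled accordingly (the comparison example and acceptance script
use r = 10 mm ≈ 2.5 pitches).

## Synthetic scenes

The generator emulates the study conditions, not a specific sensor:

* **Geometry** — an ellipsoidal dome (semi-axes 0.16 × 0.12 m, height
  0.08 m) on a platform plane 0.6 m from the depth sensor, rendered as a
  height field on the depth grid; 160×120 frames, f = 150 px, principal
  point at the image center; color sensor identical with a 2.5 cm
  horizontal baseline. Gaussian depth noise, sd 2 mm.
* **Photometry** — per-pixel value-channel targets: object albedo 0.8,
  platform 0.2, Gaussian jitter sd 0.02, multiplied by `light_gain` and
  clipped to [0, 1] (gains 0.5/1.0/1.5 emulate weak/normal/strong light;
  `with_contrast_gap` shrinks the albedo gap to emulate dark, low-contrast
  surfaces). Object pixels get a slightly warm tint; V = max(R, G, B) equals
  the gained albedo exactly before 8-bit quantization.
* **Color image synthesis** — forward splatting: every depth pixel is
  projected into the color sensor and painted at the nearest pixel with a
  z-buffer (nearest surface wins); unpainted color pixels get the platform
  color. Because splat targets and alignment resampling use the identical
  projection and rounding, each depth pixel samples exactly the color it
  splatted unless genuinely occluded by a nearer pixel — the background fill
  never leaks into the mapping image.
* **Outliers** — type I: 200 isolated pixels on the platform, ≥ 4 px from
  the object, pairwise ≥ 3 px apart, pulled 3–15 cm toward the camera;
  type II: 3 compact 12-px clusters ≥ 6 px from the object silhouette;
  type III: 2 compact 10-px clusters seeded 8-adjacent to the silhouette,
  1–5 cm off the local surface. Cluster sizes sit in the small-cluster
  range (5–50 px) and are kept modest so that parallax-induced occlusion of
  object pixels by attached outliers stays well below the 1 % retention
  budget. All outliers receive base-V values near the platform albedo
  (knob: `outlier_albedo`), encoding the mechanism that makes the V
  threshold remove them; raising the knob synthesizes the documented
  bright-outlier failure case.
* **Determinism** — all randomness derives from `SceneConfig.seed` (two
  independent streams: scene geometry/photometry and outlier injection), so
  frames, labels and all downstream outputs are bit-identical across runs,
  and `generate_scene(cfg)` equals generating the clean scene and calling
  `inject_outliers(cfg)` explicitly.

What the generator does **not** emulate: realistic sensor noise models
(RealSense speckle, edge fattening), true perspective rendering of the dome
(it is a height field), lens distortion, photometric shading, or multi-view
rigs. Passing tests therefore demonstrate the pipeline's correctness and
its contrast-dependence mechanism, not sensor-accurate performance on real
scans.

## Evaluation semantics

Per valid in-box point: noise = the three outlier labels; valid = object
and platform. `size_points_removed = size_valid_noise_removed +
size_mistakenly_removed` holds by construction. Platform points inside the
box count as valid, so the color filter's removal of the dark background is
reported as "mistaken" — deliberately mirroring the comparison-table
semantics in which contact-surface points removed along with the noise are
counted against the method. Wall-clock time is reported but never asserted.

## Numerical choices

* Rotation matrices validated to 1e-9 (orthonormality and det = +1) at
  construction.
* σ²(k) is defined as 0 when either class is empty; the closed form and the
  two-term form agree to < 1e-9 (tested).
* Histogram probabilities use exact integer counts divided once by N.
* Degenerate inputs fail loudly with typed errors: zero/negative depth,
  behind-camera points, inverted boxes, empty or single-level histograms
  (the pipeline wraps the latter as a degenerate-segmentation error naming
  the stage).

## Problem sizes

Default test and acceptance runs use 160×120 frames (19 200 points),
20-seed aggregates, 100-histogram oracle sweeps and 50-point brute-force
baseline references — sizes at which every oracle comparison is exhaustive
and a full pipeline run takes ~10 ms, chosen so the whole suite exercises
every contract in seconds.
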