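# rgbdclean

Fast color-guided outlier removal for organized RGB-D point clouds.

Consumer RGB-D scanners (e.g. structured-light devices used for anatomical
surface scanning such as foot/last digitization) produce point clouds
contaminated by outliers: sparse floating points (type I), clusters detached
from the object (type II), and clusters attached to the object silhouette
(type III). Density-based filters handle type I well but struggle with
clustered outliers. When the scanned object is clearly brighter than the
platform it rests on, the outliers — which arise at silhouettes and shadows —
map to dark background colors, and a single color threshold removes all
three types at once, in milliseconds. `rgbdclean` implements that pipeline
for people building scanning rigs or studying point-cloud denoising, plus
the classical SOR/ROR baselines, a labeled synthetic scene generator, and
removal-quality metrics.

## Method

Each sensor is a pinhole camera. A depth pixel (u₁, v₁) with depth Z₁
back-projects to X₁ = (u₁ − c_x)Z₁/f_x, Y₁ = (v₁ − c_y)Z₁/f_y; the rigid
extrinsics [R | t] move the point into the color sensor frame, and the color
pinhole projects it to (u₂, v₂), where the color image is sampled
(nearest pixel). This yields the *mapping image*: the color image resampled
onto the depth grid.

The mapping image is normalized to [0, 1] and converted to HSV with
V = max(R, G, B). The gray-level histogram of V (L = 256 levels) is split at
level k into classes C₀ = {0..k}, C₁ = {k+1..L−1} with weights ω₀, ω₁ and
means μ₀, μ₁; the Otsu threshold maximizes the between-class variance

    σ²(k) = ω₀(μ₀ − μ_T)² + ω₁(μ₁ − μ_T)² = [μ_T ω(k) − μ(k)]² / (ω(k)(1 − ω(k)))

over k (ties → smallest k). Binarization maps levels below k_opt to
background; the mask is refined by morphological closing, interior hole
filling and a minimum component area s_th, then drives the extraction: mask-1
pixels form the target cloud, mask-0 pixels the removed cloud. An optional
3D bounding-box pre-filter zeroes out-of-range points first (zeroing, not
deletion, so the pixel↔point correspondence survives).

Baselines: SOR removes points whose mean k-NN distance exceeds the global
mean by more than σ population standard deviations; ROR removes points with
fewer than `num` neighbors within radius `r`.

## Worked example

```bash
python examples/03_full_pipeline.py
```

```
Otsu threshold level: 75 / 255
valid points: 19200, target: 3747, removed: 15453
noise points: 256; removed: 15453 = noise 256 + mistaken 15197
outlier removal: 100.0% (by type: {'OUTLIER_I': 200, 'OUTLIER_II': 36, 'OUTLIER_III': 20})
object retention: 99.84%
```

The synthetic frame holds a bright dome (albedo 0.8) on a dark platform
(albedo 0.2) with 256 injected outlier points. The Otsu threshold (level 75)
falls between the two albedo modes; every injected outlier lands in the
removed cloud and 99.84 % of object-surface points stay in the target cloud.
The large "mistaken" count is the dark platform itself — the V threshold
removes the whole background along with the outliers, mirroring how the
filter behaves on real scans (contact-surface points are the typical
collateral). The other examples cover alignment (`01`), thresholding (`02`),
the SOR/ROR comparison (`04`) and the low-contrast failure mode (`05`).

The same pipeline is scriptable from the shell:

```bash
rgbdclean simulate --seed 0 --out-dir scene/
rgbdclean run --depth scene/depth.png --color scene/color.png \
    --camera scene/camera.json --labels scene/labels.png --out-dir out/
```

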