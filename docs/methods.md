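# Methods

This note records the models, parameter choices and numerical conventions
behind `mangosize`, and what the synthetic-data results do and do not show.

## Imaging model

Both cameras are pinhole models with two-coefficient radial distortion
applied in normalised coordinates about the principal point
(`r' = r(1 + K1 r² + K2 r⁴)`); skew and tangential terms are not modelled.
The shipped intrinsics (`KINECT_RGB`, `KINECT_TOF`) are the calibration
values of the RGB-D unit the pipeline targets: a 1920×1080 colour camera
(3.1 µm pitch, `f_x` = 3.2813 mm, `f_y` = 3.5157 mm) and a 512×424
time-of-flight depth camera (10 µm pitch). Distortion inversion is by
fixed-point iteration, accurate to < 1e-8 px within the field of view.

Depth is stored as integer millimetres with 0 reserved for "no return",
matching ToF dropout. The depth camera is taken to report plane-to-plane
distance, used directly as the thin-lens `D` without ray-length correction.
Registration back-projects every valid depth pixel to 3D, applies the rigid
depth→RGB extrinsic transform and re-projects with the RGB intrinsics;
where two depth samples land on one RGB pixel the nearer surface wins
(occlusion-correct). A constant device bias (front face to sensor origin;
19.1 mm for this unit) is a config offset (`SizingConfig.depth_bias_mm`),
default 0 because synthetic depth has no such bias.

Pixel coordinates are 0-based `(column, row)`, origin top-left; all boxes
are half-open, so width is exactly `x1 − x0`.

## Detector

The reference detector is a staged cascade of AdaBoost decision stumps over
HOG features. Layout: 6×6 px cells (the load-bearing size — a fruit arc
edge at 2 m spans a handful of cells), 9 unsigned orientation bins with
hard assignment, 2×2-cell blocks, L2 normalisation with an ε-guard so a
constant snip yields the zero vector. The sliding window is 48×48 px
(8×8 cells → 7×7 blocks → 1764 features); the pyramid rescales the image by
1.12 per level so the effective window spans 40–160 px, covering fruit of
~50–160 px extent at 1–3 m. The window strides 3 px, implemented as four
offset cell grids per level; levels are edge-padded by two cells so fruit
near the frame border still receive a fully-contained window.

Stages are trained on positives/negatives with a pass threshold set at the
0.5% score quantile of the positives minus half a standard deviation —
the backoff keeps near-boundary positives in unseen data; negatives that
survive feed the next stage, and training stops when the negatives are
exhausted (typically after one stage on the cleanly separable synthetic
task) or at 10 stages. Detection evaluates the stumps directly on the block
grid with numpy (verified in tests to reproduce
`AdaBoostClassifier.decision_function` exactly), which keeps a full frame
under ~0.3 s on one core.

Raw hits are grouped by overlap: the strongest remaining hit seeds a group
and absorbs hits with IoU > 0.4; a group needs ≥ `merge_threshold` = 8 raw
hits to be reported (neighbor-count semantics). The reported box is the
score-weighted mean of the group, shrunk by the training fill factor
(0.875) so it bounds the fruit rather than the window. Localisation is
deliberately loose — the segmentation stage re-measures the fruit — and
false positives on foliage are tolerated here because the chroma gate and
the completeness gate remove them downstream; this mirrors the staged
precision budget of the field system (~81% at the detector, 100% after the
gate).

The detector is a pluggable contract: `size_frame` accepts any callable
mapping a raster to bounding boxes.

## Segmentation and stalk filter

sRGB is converted to CIELAB under D65 with L* on [0, 100]; the printed
chroma thresholds only make sense on that signed scale. Otsu's threshold is
computed on L* quantised to 256 bins over [0, 100], maximising
between-class variance with ties broken toward the lower threshold
(verified against exhaustive search); the brighter class is fruit, since a
convex waxy mango out-reflects foliage under night LED illumination. The
chroma gate keeps pixels with −25 ≤ a* ≤ 25 **and** −20 ≤ b* ≤ 35 (bounds
inclusive). Morphology uses 8-connectivity for foreground and
4-connectivity for holes; both the area opening and the hole filling use a
strict `< 300 px` rule, and "closing" is implemented as area-based hole
filling to match that pixel-count criterion rather than a structuring
element.

The stalk filter zeroes maximal non-zero runs shorter than `w` = 8 px, rows
first then columns, with image borders acting as zero delimiters (otherwise
a stalk exiting the snip would survive). It is idempotent. A radius-1 disk
dilation follows, compensating the truncation of sharp fruit tips; this
dilation adds ≈ 1 px per side and is the main source of the small positive
sizing bias (~1–2 px-equivalents) seen on synthetic scenes.

Stage order within a candidate: Otsu → chroma gate → area opening → hole
filling → stalk filter → dilation.

## Completeness gate

Each component is summarised by the ellipse with its first and second
moments: the covariance eigenvalues `λ₁ ≥ λ₂` give full axes `a = 4√λ₁`,
`b = 4√λ₂`, eccentricity `ε = √(1 − (b/a)²)`. Components with < 5 px or
degenerate (collinear) geometry are errors. The four acceptance criteria:
1000 ≤ A ≤ 8000 px (both ends inclusive), `r = 4A/(πab) > 0.97`,
`ε ≤ 0.75` (0.75 itself passes; rejection is for `ε > 0.75`), and
bounding-box long side minus `a` < 4 px (the long side of the axis-aligned
box, since fruit hang vertically but ellipses may tilt). The first failed
criterion is recorded as the rejection reason. A snip may yield several
accepted components; duplicates captured by overlapping (doubled) boxes are
deduplicated by > 50% mask overlap, keeping the larger component.

A note on occlusion: a perfectly straight-edged truncation of an ellipse
moves `r` down only slowly (the fitted ellipse adapts), and for such cuts
the eccentricity criterion usually fires first. A concave bite — what an
elliptical leaf actually leaves — drives `r` below 0.97 from ~15% coverage
on, which is why the generator occludes with elliptical leaves.

## Sizing

`D` is the mean of the valid (non-zero) entries of the 2×2 depth block
anchored at the bounding-box centre (centre pixel plus right/down
neighbours — "a 2×2 average about the centre" does not fix the anchoring,
so the anchored convention is this package's choice). Fruit with
`D` < 800 mm are excluded
(sensor near field). Vertical extent → length through `f_y`, horizontal →
width through `f_x`: fruit hang vertically, and the worked one-pixel error
example (1.76 mm at 2 m) uses the y-axis focal length, which fixes the
otherwise ambiguous axis-to-dimension assignment. First-order error
propagation: `ΔL = L·ΔD/D`, so the 11 mm depth error typical on fruit costs
±0.55 mm per 100 mm at 2 m; the 2×2 averaging halves the effective σ for
uncorrelated per-pixel noise.

## Allometry and sampling

Mass relations take centimetres and return grams: `M = k·L·W·T`
(k ≈ 0.49–0.51, default 0.5), `M = k·L·((W+T)/2)²`, and `M = 0.42·L·W²`
when thickness is unavailable. The pipeline's internal unit is mm;
conversion happens at the allometry boundary to avoid silent unit drift.
Because fruit orientation on the tree is uncontrolled, an imaged width lies
anywhere between caliper W and T; evaluation therefore scores the
machine-vision width against the closer of the two (ties → W). The
sample-size rule `n = (1.96·SD/e)²` rounds to the nearest fruit (SD = 24.4,
e = 4.9 gives 95.26 → 95); a `ceil` mode is available for conservative
planning.

## Synthetic scenes

The generator emulates the night-imaging conditions: a dark textured
background (L* ≈ 12), foliage as elliptical blobs with chroma outside the
segmentation gate (a* ≤ −35 or b* ≥ 45, L* 25–45), fruit as bright filled
ellipses with chroma safely inside it (L* 65–80, |a*| ≤ 15, 0 ≤ b* ≤ 25),
thin vertical stalks (2–4 px, fruit-family chroma so only the run filter
removes them), and elliptical leaf occluders slid in until they cover the
requested fraction of the fruit. Default sampling: lengths uniform on
60–160 mm, widths length × U(0.72, 0.88) clipped to 50–130 mm (mango are
longer than wide; the width/length ratio of the average assessed fruit is
0.80), distances uniform on 1000–3000 mm. Depth on fruit is the true
distance plus zero-mean Gaussian noise (default σ = 11 mm, the bias-corrected
depth error measured on fruit for this sensor class), truncated at ±3σ,
quantised to integer mm, with optional dropout to 0. Scenes render by
default on a 360×360 px raster with the RGB optics and a centred principal
point — a crop-sized frame chosen as the package's standard problem size —
and all randomness flows from a single seed.

What the generator does **not** emulate: specular highlights and shading
gradients on fruit, leaf venation/texture, fruit-on-fruit clustering,
motion blur, and daylight interference. Passing tests therefore demonstrate
the internal consistency of the pipeline (detector, thresholds, gate,
thin-lens arithmetic and their interaction), not field performance; the
field error level is bounded below by pixel quantisation (≈ 1.76 mm at
2 m) plus segmentation and depth error, and the synthetic end-to-end RMSE
(~2 mm) should be read as that floor, not as an orchard result.

## Numerical choices and degenerate inputs

- Otsu: 256 bins over [0, 100]; constant channels return a degenerate flag
  and an empty mask rather than a threshold.
- Moment fit: raw (unsmoothed) central moments; < 5 px or collinear
  components raise.
- Registration collisions keep the smaller depth; unmapped RGB pixels carry 0.
- The FOV crop computes the overlap rectangle from the depth raster's
  corner rays at a 2000 mm reference depth (exact for identity extrinsics;
  the translation-induced parallax across 1–3 m is sub-pixel for the 55 mm
  baseline).
- `sample_size` rejects non-positive SD or error; `pixels_to_mm` rejects
  non-positive distance.
- All stochastic components (generator, detector training) are
  deterministic given their seed; derived seeds stay below 2³¹.

## Known limitations

- The cascade is trained and validated only on synthetic imagery; real
  orchard snips would need retraining (the detector contract accepts any
  box source).
- The gate constants (area window, r, ε) are tuned for ~2 m working
  distance and roughly elliptical cultivars; strongly non-ellipsoidal fruit
  would need re-derivation.
- Only the imaged width is reported; fruit thickness is not recoverable
  from a single view.
- Sizing error grows with distance (pixel quantisation scales with D), and
  depth beyond ~4.5 m is outside the sensor's reliable range.
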