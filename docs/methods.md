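# Methods

This note records the models, numerical choices and known limitations behind
shredkit, in the order the pipeline runs.

## Synthetic scenes as the validation substrate

No public dataset of blended tobacco-shred inspection images exists, so all
quantitative validation in this package runs on synthetic scenes with exact
ground truth. The generator is first-class code, not a fixture: its geometry
is the reference against which the measurement algorithm is scored.

**Ribbon model.** A shred is a constant-width tube swept along either a
straight segment or a circular arc of curvature `c` (radius `1/c`), with
rounded end caps. `length_mm` is the centerline (medial-axis) arc length;
the caps extend half a width beyond each end, so a 10 mm × 1 mm ribbon at
10 px/mm rasterizes to ~110 px tip to tip. Rendering computes an exact
Euclidean distance transform to a densely sampled centerline and keeps
pixels within `width/2`; a test checks the mask against independently
computed float distances to the analytic curve.

Default geometry draws lengths uniformly in 8–30 mm, widths in 1–3 mm
(capped at length/4), and curvature so the total bend is at most 150°, at
10 px/mm on a 1280×1280 canvas — the size range manual measurements of
shreds typically report. Placement is rejection sampling; a configurable
fraction of ribbons is deliberately placed to overlap a previous one,
mirroring the multi-labeling convention for overlapped shreds.

**Appearance.** Classes are distinguished by fixed base colors with additive
speckle (Y yellow-brown, G pale stem, P light expanded, Z uniform dark
sheet). Colors are chosen class-separable, not photorealistic, under one
constraint: the luma of every class stays ≳15 gray levels below the darkest
background the shadow model can produce. Without that constraint the palest
class is locally indistinguishable from a shadowed background and no
intensity-based segmentation — including the one validated here — is
well-posed.

**Shadows.** A low-frequency multiplicative gradient (≤ 30% of the strength
parameter) plus a soft penumbra per ribbon: the ribbon mask shifted by
~0.8 mm and blurred at a 1 mm scale, darkening the background by at most
half the strength parameter. Offsets and blur are physical (mm-scaled, hence
ppmm-scaled in pixels) rather than canvas-relative, as cast by an overhead
diffuse panel; shadows therefore hug their ribbons and are broader and
shallower than the shreds themselves. Default strength 0.3.

**What the generator does not emulate:** real shred texture and translucency,
specular highlights, camera noise and optics, non-constant shred width,
torn/branched shreds, and shreds touching the image border. Passing tests
demonstrate correctness of the algorithms under the tube model and this
illumination model, not performance on real inspection imagery.

**Manifests.** Train/test splits are per-label: the test count is
`floor(n · test/(train+test))`, the remainder trains, assignment is a seeded
shuffle. Ratios that divide the counts are honored exactly (4×1000 at 7:3 →
2800/1200; 4×1700 → 4760/2040). The split is a partition by construction.

## Background-shadow elimination

Five steps: (1) grayscale + repeated 3×3 dilation, (2) 3×3 median filter,
(3) absolute difference of original vs. filtered, (4) min–max normalization
to 0–255 (a constant difference maps to all-zero), (5) local-mean adaptive
threshold with window `max(15, min_dim/20)` (odd) and offset 10, followed by
morphological closing, hole filling and a 2×2 opening.

The dilation/median pass builds a *background estimate*: the max filter
erases dark shreds but tracks the smooth shadow field, so the difference
image cancels shadows and lights up shreds. The number of dilation
iterations sets the widest foreground it can erase (default 16 → ~32 px ≈
3 mm at 10 px/mm, the widest default shred); the single-op default for
`gray_dilate` remains one iteration. The output image keeps foreground
pixels unchanged and replaces the background with its median color; the
step-5 `gain` (default 1.2) boosts the *difference image*, not the output
colors, which keeps a second pass over an already-clean image a near no-op
(idempotence is tested: < 2% of pixels change by > 5 levels).

Limits: the max-filter background estimator requires shadows to be broader
and shallower than the foreground; shadow edges at the foreground scale
produce false-positive rims. Measured on default scenes: foreground-mask
IoU vs. truth 0.96–1.0, background std reduced by ~20×.

## Augmentation

Standard YOLO-style chain, in order: hsv jitter (fractional gains 0.015 /
0.7 / 0.4), translate (±0.2) and scale (±0.5) about the image center,
horizontal flip (p=0.5), 2×2 mosaic (p=1.0), mixup with a Beta(8,8) weight
(p=0.05), paste-in of a ribbon mask (p=0.05). Boxes are transformed with the
pixels, clipped to the frame, and dropped when fully outside. Mosaic and
mixup draw partners from an explicit scene pool and are skipped without one.

## Detection-network components

The components are built on a small in-repo reverse-mode autodiff engine
over numpy (float32, im2col convolution, −inf-padded running max pooling,
nearest ×2 upsampling). They are validated structurally — shapes, parameter
counts, gradient checks, loss behavior — not by full-scale training, which
is out of scope on one CPU.

* **CBS** = convolution + bias + SiLU. Batch normalization is deliberately
  omitted: at desk scale (batches of a few images) batch statistics are
  noise, and the bias absorbs the affine shift. Parameter-count comparisons
  are unaffected in direction.
* **Re-I-block**: 1×1 reduction to `C_out/2`, two stacked 3×3 convolutions,
  concatenation of {input projection, reduction, both taps} fused by 1×1 to
  `C_out` (the ELAN-style multi-branch path), plus an identity skip
  (1×1-projected when channels change). Backbone stages use 1:2:2:1 blocks
  (compressed from the 3:4:6:3 residual convention) over channels
  (64, 128, 256, 512); the compressed backbone has ~0.44× the parameters of
  the 3:4:6:3 layout at equal channels.
* **Taps**: the stem downsamples ×4; stages sit at strides 4/8/16/32.
  Stage 1 reaches P3 via CBS + a stride-2 max pool, stage 2 via CBS;
  stage 3 feeds P4; stage 4 feeds P5 through SPPFCSPC. A light top-down
  fusion (upsample + concat + 1×1) produces the three head inputs.
* **SPPFCSPC**: cross-stage-partial block whose pyramid pooling is three
  *serial* 5×5 stride-1 max pools; two chained 5×5 pools equal one 9×9 and
  three equal one 13×13 exactly (tested on random arrays), so the receptive
  field of the parallel 5/9/13 variant is preserved while each pool pays
  only for a 5×5 window. The same weights can be run in either pool mode.
* **Decoupled head**: shared 1×1 reduction, then a convolutional
  classification branch and a localization branch (1×1 convolutions — the
  per-location equivalent of a dense layer, which a literal dense layer
  cannot be under variable spatial size) with an objectness/IoU output.
  Branch parameters are disjoint after the reduction (tested via gradients).
  Output layout per anchor: (x, y, w, h, obj, classes), 3 anchors per level.
* **Loss**: CIoU on decoded boxes (YOLO v5-style decode; decoded sides are
  floored at 0.01 px because squared sigmoids underflow float32 for very
  negative logits), binary cross-entropy objectness over the full maps, and
  binary cross-entropy classification at assigned cells. Assignment: each
  truth goes to the level/anchor with the best size ratio and the cell
  containing its center.
* **Smoke training**: 20 epochs of Adam (lr 1e-3) over 8 two-ribbon
  256×256 scenes at 5 px/mm, with a narrow-width config (channels
  16/32/64/128, head width 32) sized so the run takes well under a minute on
  one CPU. The run is deterministic given its seed; loss falls roughly
  30-fold. It exercises the objective end to end and nothing more.

## Detection metrics

Greedy matching in descending confidence (ties broken by input order);
a prediction is TP when its best-IoU unmatched same-class truth reaches the
threshold; each truth matches at most once. AP uses all-point interpolation —
the exact discrete analogue of the `∫ p dr` definition (11-point
interpolation was rejected as a lossy approximation). mAP averages classes
that have ground truth; mAP@.5:.95 averages the ten thresholds 0.50–0.95.
Both matching and AP are verified against brute-force reference
implementations on all fixtures with ≤ 6 predictions.

## Length/width calculation

Given a detection box: crop, Otsu-binarize (foreground = darker phase;
invertible), keep the connected component whose centroid is nearest the box
center (ties → larger area), rotate so the minimum-area rectangle (convex
hull + rotating-calipers rectangle) is horizontal, and slice into `n`
vertical strips (`Δx = x1/n`, default `n = 50`, strips narrower than 2 px
rejected, `n` reduced automatically for short objects).

**Length.** Strip centroids are first-order moments of each strip's
foreground. The centerline is a *chord-length-parametrized* cubic smoothing
spline through the ordered centroids (smoothing `s = 0.5·m`; polyline when
fewer than 4 centroids). A plain `y(x)` spline was rejected: strongly bent
shreds have near-vertical centerline sections whose strips see only edge
slivers, and a function of `x` cannot follow them (a semicircle loses ~10%).
Beyond the end centroids the residual path is measured geodesically: every
mask pixel is assigned to its nearest curve sample; pixels owned by an end
sample form that end's residual region; the extension is the largest
within-mask geodesic distance from the curve end to a residual pixel in the
forward cone (±60°) of the outward tangent. Total tip-to-tip arc length
minus one mean width (the two half-width cap overhangs) is the reported
length. The arc length of the fitted path is never allowed below the chord
between end centroids.

**Width.** The interior Euclidean distance transform is computed once on the
rotated mask (padded by one pixel so the tight crop edge counts as
boundary). Per strip, the maximum distance value is the inscribed-circle
radius — proven equal to exhaustive search over interior centers on random
masks — and the reported diameter is `2·max − 1` px (the half-pixel
correction from pixel-center distances to a continuous diameter; a w-px bar
measures w ± 1 px depending on subpixel placement). The object width is the
mean diameter over non-empty strips; end-cap strips bias it slightly low.

**Calibration.** `pixels_per_mm = block_pixel_length / block_mm_length`,
with the block's long side (9 mm) as the calibration length. The block is
auto-detected by color and its long side measured by the same minimum-area
rectangle routine.

**Accuracy, measured on generator output** (mask-level, 10 px/mm): straight
bars ±1.5%, a slender semicircle ±3%, the mixed-curvature panel family
length within ±5% per object and ~±2% in aggregate; widths ±10% per object
(raster quantization on 8–30 px widths) and −5…−7% in aggregate. Accuracy
degrades for thick, strongly bent shreds (width ≳ 0.4 of the bend radius),
where the strips degenerate to edge slivers — consistent with width being
the dominant error in curved-shred measurement generally. Overlapped shreds
are measured as their visible mask; no occlusion completion is attempted.

**Error reporting.** Signed relative error `100·(measured − actual)/actual`
per object; aggregates compare summed measured sizes against summed true
sizes per class (`Total-Y` … `Total-Z`) and overall (`Total`).

## Pipeline and reproducibility

A run is fully specified by a YAML config plus a seed; each stage derives
its own seed by hashing `(seed, stage, index)`, all kept below 2³¹. Outputs
are PNG images, YOLO label text, and CSV tables; identical config + seed
gives byte-identical files (no timestamps in outputs). Ground-truth-box mode
is the default measurement path so the size pipeline is testable without
trained weights; inference mode loads an `.npz` weight file and runs the
detector with confidence filtering and per-class NMS.

## Problem sizes used by the test suite and acceptance script

Scenes of 512–1280 px with 2–20 ribbons; 50 random ≤ 64×64 masks for the
inscribed-circle oracle; 1000 random box pairs for the CIoU oracle; 8
scenes × 20 epochs for smoke training. The full suite runs in about half a
minute on one CPU; the acceptance script in about 20 seconds.
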