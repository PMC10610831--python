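# shredkit

Synthetic-scene morphometry and detection toolkit for **blended tobacco
shreds** — images that mix the four shred varieties found on cigarette
inspection lines (Y tobacco silk, G cut stem, P expanded tobacco silk,
Z reconstituted tobacco shred), both isolated and overlapping, on a light
background.

Quality control on inspection lines needs two things from such images: the
*class* of every shred (multi-object detection) and its *two-dimensional
size* (length along the curved centerline, width across it), from which
blend composition and shred-integrity indices are derived. Real inspection
imagery is proprietary, so this package pairs every algorithm with a
synthetic scene generator whose ground truth is exact — each rendered shred
is a constant-width tube swept along a circular arc with known centerline
length, width, class color and bounding box — which makes every claim
testable.

## What is inside

| module | purpose |
| --- | --- |
| `shredkit.synthgen` | curved-ribbon scene generator with exact truth, YOLO labels, calibration block, dataset manifests and exact-ratio train/test splits |
| `shredkit.preprocess` | background-shadow elimination (grayscale dilation → 3×3 median → background difference → 0–255 normalization → adaptive threshold + enhancement) and YOLO-style augmentation (hsv / translate / scale / fliplr / mosaic / mixup / paste-in) |
| `shredkit.model` | detection-network components on an in-repo numpy autodiff engine (`shredkit.nn`): compressed residual/ELAN backbone (Re-I-blocks, 1:2:2:1 stages), SPPFCSPC serial-pooling neck, decoupled head, CIoU loss, desk-scale smoke training |
| `shredkit.metrics` | precision, recall, AP (all-point interpolation), mAP@.5 and mAP@.5:.95 with greedy confidence-ordered matching |
| `shredkit.lwc` | the length/width calculation (LWC) algorithm: crop → contour selection → rotation to the minimum-area rectangle → strip slicing → centerline spline length and maximum-inscribed-circle width, calibrated in mm |
| `shredkit.pipeline` / `shredkit.cli` | end-to-end runs (`generate → preprocess → detect → measure → report`), YAML config, `shredkit` command line |

## The measurement model

A shred is treated as a constant-width tube around a curved centerline.
After a detection box is cropped and binarized (Otsu), the connected
component whose centroid is nearest the box center is kept, rotated so its
minimum-area bounding rectangle (long side `x1`, short side `y1`) is
horizontal, and cut into `n` vertical strips of width `Δx = x1/n`
(default `n = 50`):

* **Length** — the foreground centroid of every non-empty strip is fitted
  with a chord-length-parametrized cubic smoothing spline; the arc length is
  integrated by dense chordal sampling, extended to the mask tips, and
  reduced by one measured width to discount the two rounded end caps.
* **Width** — in each strip the maximum inscribed circle of the object is
  found from the interior Euclidean distance transform (the strip maximum is
  the radius); the object width is the mean diameter over strips.
* **Calibration** — a rectangular reference block of known size (3 mm × 9 mm)
  is located in the scene; `pixels_per_mm = block_pixel_length / block_mm_length`.

Detection quality is scored with the standard single-stage conventions:
`Precision = TP/(TP+FP)`, `Recall = TP/(TP+FN)`, `AP = ∫₀¹ p(r) dr` with the
exact all-point discretization, `mAP` the per-class mean, and mAP@.5:.95 the
further mean over IoU thresholds 0.50–0.95 in steps of 0.05. The training
objective is the complete-IoU loss
`CIoU = 1 − IoU + ρ²(b, b_gt)/c² + αv`, with `v` the arctan aspect-ratio
consistency term and `α = v/(1 − IoU + v)`.

## Worked example

Generate a 20-shred scene (5 per class, soft shadows, calibration block) and
measure every object:

```bash
$ shredkit generate --n-scenes 1 --per-class 5 --canvas 1280 --seed 11 --out demo
wrote demo/scene_0000.png
$ shredkit measure --image demo/scene_0000.png --labels demo/scene_0000.txt \
      --auto-block --out demo/report.csv
20 objects -> demo/report.csv (scale 10.00 px/mm)
$ head -4 demo/report.csv
object_id,class,length_mm,width_mm,rel_err_len_pct,rel_err_wid_pct,error
0,Y,10.9782,1.7465,,,
1,Y,11.2423,2.3619,,,
2,Y,29.3054,2.2147,,,
```

The block was found automatically and its 90 px long side against the known
9 mm gives the 10.00 px/mm scale; each row is one shred's centerline length
and mean inscribed-circle width in millimetres. Scoring the same scene
against its generator ground truth aggregates the signed relative errors
(`100·(measured − actual)/actual`, summed sizes per class):

```
 sample  n_objects  rel_err_len_pct  rel_err_wid_pct
Total-Y          5             1.53            -6.14
Total-G          5             1.51            -6.16
Total-P          5             2.44            -7.14
Total-Z          5             1.66            -6.25
  Total         20             1.74            -6.42
```

Lengths are recovered to within ~2% and widths to within ~7% on this panel;
width is the harder quantity because shreds are only 8–30 px wide at
10 px/mm, so a one-pixel raster error is already several percent.

Dataset bookkeeping uses exact-ratio splits:

```bash
$ shredkit split --counts '{"Y":1000,"G":1000,"P":1000,"Z":1000}' --out manifest.csv
2800 train / 1200 test -> manifest.csv
```

Other subcommands: `preprocess` (shadow removal), `augment`, `train-smoke`
(20-epoch CPU training on tiny scenes), `detect`, `evaluate` (per-class
AP/mAP tables), and `run` (the full YAML-configured pipeline).

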