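# grapefit

Phenotype measurement for overlapped grape particles from images, in two
steps:

1. **Edge detection** — a dense-side-output edge network (VGG16-style
   backbone; every conv layer of stages 3–5 feeds a 1×1, depth-25 side
   conv; per-stage maps are superimposed and reduced to one channel;
   bilinear upsampling; five-stage fusion), class-imbalance-aware losses
   (weighted cross-entropy, reciprocal soft-Dice, and their α-mix), and
   multi-scale image-pyramid inference. A classical gradient-magnitude +
   hysteresis fallback detector lets the pipeline run without trained
   weights.
2. **Contour fitting** — inside detector-supplied candidate boxes, edge
   pixels are grown into 8-connected contour segments and fed to an
   iterative least-squares ellipse fit driven by random sample consensus
   (theoretical iteration count, perimeter-normalized fitness, minimal
   5-pixel draws, converged inlier refit). Each accepted fit yields the
   grape's long axis (2a) and projected area (πab) in pixels.

The package also ships the full evaluation-metric suite (tolerance-based
edge matching, Dice / recall / redundancy, ODS/OIS threshold sweeps,
non-maximum-suppression thinning, fitting recall, AARD) and a synthetic
scene generator (overlapping ellipse clusters with z-order occlusion,
contour dropout, spurious noise, full ground truth) so every stage is
testable without external data.

## Command-line usage

```bash
# generate synthetic scenes (edge map PNG + boxes CSV + ground-truth JSON)
grapefit simulate --out-dir scenes --n-scenes 2 --n-grapes 5 --seed 1

# edge detection (classical fallback when no weights are given)
grapefit detect-edges scenes/img.png --out-dir edges --scales 0.5,1.0,1.5

# fit ellipses in candidate boxes and write phenotype records
grapefit fit --edge-map scenes/scene000_edges.png \
             --boxes scenes/scene000_boxes.csv \
             --out records.csv --seed 0

# evaluate edge predictions (D, R, A, F, ODS/OIS) and optional AARD
grapefit evaluate --predictions edges/pred.png --truths scenes/gt.png \
                  --out report.json

# run the flip / 22.5°-rotation / scale augmentation over a directory
grapefit augment images/ --out-dir augmented/
```

All subcommands log their resolved configuration and seeds to stderr and
document every default in `--help`.

## Library layout

| module | contents |
| --- | --- |
| `grapefit.geometry` | `Ellipse`, direct least-squares ellipse fit (ellipse-specific constraint), perimeter via the complete elliptic integral, orthogonal foot-point distance, arc rasterization |
| `grapefit.ransac` | `RansacConfig`, iteration-count formula, perimeter-normalized fitness, consensus fitting loop |
| `grapefit.edges` | losses (+ analytic gradient), `NetworkSpec` / `build_improved_hed`, `pyramid_predict`, `fallback_edge_detector` |
| `grapefit.pipeline` | candidate boxes, contour region growing, per-box fitting, time-series aggregation |
| `grapefit.metrics` | edge-pixel matching, D/R/A, ODS/OIS, NMS thinning, fitting recall, AARD |
| `grapefit.synthetic` | cluster scene generator, occlusion geometry, noise, augmentation, area time series |
| `grapefit.io` / `grapefit.cli` | PNG/CSV/JSON I/O, bundled benchmark tables, CLI |

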