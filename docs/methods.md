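# Methods

`bassdet` is a single-stage, anchor-based fish detector and counter for
top-view imagery of circular aquaculture tanks. This note records the
model, the numerical choices, and what the synthetic benchmark does and
does not demonstrate.

## Detection model

The network is the small CSP-backbone architecture of the YOLOv5 family
(depth multiple 0.33, width multiple 0.50 by default):

- **Stem** — a Focus block: the input is de-interleaved into four
  half-resolution slices stacked channel-wise (3 → 12 channels), followed by
  a 3×3 conv+BN+SiLU.
- **Backbone** — alternating stride-2 convolutions and C3 blocks (CSP
  bottleneck stacks), ending in an SPPF block (three cumulative 5×5 max
  poolings, concatenated) at stride 32.
- **Neck** — FPN top-down fusion followed by PAN bottom-up fusion, mixing
  the stride 8/16/32 feature maps.
- **Heads** — one 1×1 convolution per scale emitting
  `3 × (5 + num_classes)` channels: box offsets, objectness, class logits
  for three anchors per cell.

Boxes are decoded with the bounded parameterization
`center = (2σ(t_xy) − 0.5 + grid) · stride`,
`size = anchor · (2σ(t_wh))²`, so a cell can place a center in
(−0.5, 1.5) cells around itself and sizes are confined to (0, 4·anchor).

### Coordinate attention

The coordinate-attention (CA) unit pools a C×H×W feature map along width
(→ C×H×1) and along height (→ C×1×W), concatenates the two pooled maps,
passes them through a shared 1×1 conv + BN + SiLU down to
`max(8, C/r)` channels (reduction `r` = 32 by default), splits them back,
and maps each direction through its own 1×1 convolution to a sigmoid gate.
The output is the input rescaled by both gates — attention that is
direction-aware (where along H, where along W) as well as channel-aware,
which is what helps separate elongated, mutually occluding fish bodies.

Two insertion sites are configurable:

- `backbone_c3`: every backbone C3 becomes **C3CA** — CA is applied to the
  bottleneck branch, and the 1×1 conv+BN on the secondary branch is
  *removed*, replaced by a channel-split identity (the first `c/2` input
  channels). At standard widths the removed convolution outweighs the small
  CA unit, so C3CA has strictly fewer parameters than C3.
- `neck`: a standalone CA unit after each of the four neck fusion C3
  blocks.

### Parameter accounting

`count_parameters(model)` counts raw trainable scalars; with
`fused=True` it counts the deployed form in which every conv+BN pair is
fused into a biased convolution (one bias vector replaces the two BN affine
vectors, i.e. one scalar fewer per normalized channel). Detector summaries
in this architecture family conventionally print the fused count at
inference time; the single-class baseline here is 7,012,822 fused and
7,022,326 raw (the difference, 9,504, is exactly the total number of
batch-normalized channels).

## Training objective

`Loss = L_bbox + L_cfd + L_cls`, with per-component scale factors.

- **L_bbox** — mean of `1 − CIoU` over positive matches, where
  `CIoU = IoU − ρ²/c² − αv`: `ρ` is the center distance, `c` the diagonal
  of the minimum enclosing box, `v = (4/π²)(arctan(w_g/h_g) − arctan(w/h))²`
  the aspect-ratio penalty and `α = v/((1−IoU)+v)`. Gradients are
  analytic, with `α` treated as a constant (the standard CIoU convention);
  the implementation is verified against finite differences and an
  independent scripted evaluation of the definition.
- **L_cfd** — binary cross-entropy on objectness: the sum over object
  positions plus `λ_noobj` (default 0.5) times the sum over background
  positions, both normalized by the batch size. By default the target at a
  positive position is the (detached) CIoU of the current prediction rather
  than the constant 1. This choice is deliberate: with constant-1 targets
  every positive saturates at score 1.0, so duplicate and coarse-scale
  boxes cannot be ranked, decayed or thresholded away, and AP at match-IoU
  0.5 collapses under short training schedules. IoU-valued targets make
  the score an estimate of localization quality. `LossConfig(
  iou_objectness=False)` restores the constant-1 reading (which is also
  the selection metric, below, and the form used by the one-image overfit
  check, since the IoU-valued objective has an intrinsic entropy floor
  `H(target) > 0` at its optimum).
- **L_cls** — BCE over class probabilities at object positions only
  (single class "fish" by default).

**Target assignment.** A ground-truth box is positive for an anchor when
both side ratios lie below a threshold (4.0 for the generic rule; the tiny
CPU training profile uses 3.0, which empirically yields cleaner box
regression when optimization steps are scarce), in its containing cell and
the two nearest neighbor cells, at every scale whose anchors pass the
ratio gate. Probabilities inside logs are clamped to `[1e-7, 1 − 1e-7]`,
and decoded sizes are floored away from zero before CIoU.

## Optimization

Adam with single-cycle cosine annealing from the base learning rate to 1%
of it, a one-epoch linear warmup from 10%, and global-norm gradient
clipping (25). The CPU profile defaults to batch 4, lr 0.012, 20 epochs.
The published-style recipe (Adam, lr 0.01, batch 32, 200 epochs) is
available as `RunConfig.paper_preset()`; the small-batch/short-schedule
defaults were chosen for desk-scale CPU runs.

**Checkpoint selection.** By default the epoch with the best validation AP
at IoU 0.5 is kept (ties resolved toward the later epoch). Selection by
lowest composite validation loss is available (`selection="val_loss"`) but
is unreliable at desk scale: the confidence term dominates the composite
and plateaus while localization is still improving, and with IoU-valued
targets an early low-quality epoch can post an unbeatably low loss by
honestly predicting low confidence against low targets.

**Augmentation.** Mosaic-8 (below) and photometric jitter are available;
the CPU profile trains with per-axis mirror flips only (probability 0.5
each). Top-view tank scenes are statistically mirror-symmetric, so flips
are label-exact and substantially reduce the train/test gap on small
datasets.

## Mosaic-8 and photometric augmentation

Mosaic-8 composites eight independently scaled and cropped labeled images
onto one canvas in a 4×2 cell layout with per-boundary jitter up to 20% of
the cell size. Every ground-truth box follows the same scale-and-shift
affine map as its pixels, is clipped to its cell, and is dropped when the
clipped area falls below 8 px² or 20% of the transformed box area —
degenerate slivers make poor regression targets. Brightness is a single
multiplicative factor per image; noise is additive Gaussian per pixel,
both clipped to [0, 255].

## Prior boxes

Nine anchors come from k-means over training-box `(w, h)` pairs under the
distance `1 − IoU` of origin-aligned rectangles, with k-means++ seeding and
10 restarts. The component-wise mean is only a heuristic center update
under this metric, so an update is accepted only when it lowers the
objective — the objective sequence is non-increasing by construction. The
anchors are interpreted as (width, height), sorted by area and split 3/3/3
across the stride-8/16/32 heads. A Euclidean metric is available behind a
flag for comparison.

## Suppression

Classical NMS zeroes every remaining box whose IoU with the current best
box reaches the threshold `N_j`; linear Soft-NMS instead rescales
`s ← s·(1 − IoU)` and keeps the box for further screening, discarding only
boxes that fall below `final_score_min`. Suppression is per class, and
ties are broken by score, then area, then coordinates, making the result
independent of input order. The published formulation prints both
inequalities transposed relative to the original definitions (and to its
own prose); the standard orientation is the default, and
`strict_paper_mode=True` preserves the printed orientation for comparison.
Only the linear decay is implemented; the Gaussian variant is out of
scope.

## Evaluation

Greedy one-to-one matching in score order at IoU ≥ 0.5; AP is the area
under the precision envelope over recall (all-point interpolation; an
11-point mode exists behind a flag). The summary precision/recall pair for
F1 = 2PR/(P+R) is the ranked-list cut that maximizes F1, since the
operating point behind published summary tables is generally unstated.
Counting uses a stricter score threshold (0.5) than the PR-curve floor so
that soft-decayed duplicates do not inflate the tally.

## Synthetic scenes

The generator renders a top-view circular tank (dark disc, radial shading)
with ellipse-bodied fish (torso + triangular tail, dorsal stripe) at
random positions and orientations, in four occlusion modes: `none`
(disjoint boxes), `parallel` / `cross` (pairs rejection-sampled to a
minimum pairwise box IoU, side-by-side or crossing), and `dense` (free
packing). Emitted boxes are tight silhouette bounds measured before noise.
Everything is reproducible from one integer seed; per-image seeds are
derived from the master seed.

Default scene scale mirrors 1080-class top-view captures downscaled to the
training-native 640×640, with a 160×160 tiny preset whose fish span 28–44
px. The *easy* preset used by the training smoke benchmark has four
non-overlapping fish per 160×160 scene and near-noiseless photometry.

**What passing the synthetic benchmark shows — and what it does not.**
The benchmark demonstrates that the full pipeline (rendering → annotation
→ anchors → training with the composite loss → decoding → Soft-NMS →
AP/F1) is wired correctly and can learn to localize high-contrast
elongated blobs on a single CPU in minutes. It does not demonstrate
performance on real tank footage: real fish have texture, specular water
reflections, caustics, motion blur and depth-dependent scale, none of
which the renderer models. Published-scale accuracy claims require
training the full-width model on real annotated images.

**Problem sizes.** The smoke benchmark trains the tiny preset (width
0.125, input 160, ~446k parameters with CA) on 64 scenes for 20 epochs at
batch 4 — about 75 s on one CPU — and evaluates on 16 held-out scenes.
With the default seed this reaches AP₀.₅ ≈ 0.88; across other seeds the
spread is roughly 0.73–0.88, so the threshold of 0.8 is met at the pinned
seed but is not a seed-free guarantee at this problem size. The one-image
overfit check (200 steps) drives the constant-target composite loss to a
few percent of its initial value.

## Known limitations

- The numpy engine is single-threaded and eager; it is sized for the tiny
  preset and desk-scale experiments, not for full-resolution training.
- Objectness calibration under the IoU-valued target caps scores near the
  model's typical localization quality (~0.7–0.9 here), so absolute score
  thresholds are dataset-dependent.
- Fish counting equals thresholded detection counting; no tracking or
  multi-frame aggregation.
- The Mosaic-8 cell geometry (4×2, 20% jitter) follows the composition
  figure of the source method, which does not fully specify geometry.
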