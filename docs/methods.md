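# Methods

This note documents the models, the synthetic data, and the numerical and
design choices behind the package. It is written for users who want to know
what the code computes and what passing tests do and do not demonstrate.

## Density-map counting

A density-map counter is a network `M` mapping an RGB dish image `x` to a
non-negative map `y = M(x)` whose pixel sum equals the number of objects.
Ground-truth maps are built from bounding-box annotations: each colony
contributes a single impulse at its box center, blurred by a Gaussian
kernel.  We truncate each kernel at 4σ, clip it at map edges, and
renormalise it **per colony** to unit mass. The pixel sum therefore equals
the colony count exactly (to float rounding), superposition holds
(rendering A∪B = rendering A + rendering B), and counting any map is just
`count_from_map = map.sum()`.

Choices the annotation format does not pin down:

- **Kernel σ.** Adaptive by default: σ = 0.25 × mean bounding-box side at
  target resolution, floored at 0.4 px. The floor keeps an isolated
  kernel's discrete peak at or below 1 so the map is a valid argument of a
  per-pixel binary cross entropy; the 0.25 factor keeps mass localised
  within the colony footprint. A fixed-σ mode exists for ablations.
- **Targets for the BCE loss.** Overlapping colonies superpose kernels and
  can push target pixels above 1. Counting always uses the unclipped map;
  the loss consumes a view clipped to [ε, 1−ε] (ε = 10⁻⁶), and a warning is
  logged whenever clipping actually changed a pixel at the top end.
- **Coordinates.** 0-based pixel indices; boxes are half-open integer
  intervals; the box center is the arithmetic midpoint. Box centers are
  mapped to target resolution by multiplying by (target size / image size).

## Network

The trunk is a two-level nested U-shape: the top level is a U-Net whose
encoder/decoder blocks are themselves small residual U-blocks (RSU — inner
encoder, dilated bottom convolution, inner decoder, residual skip). With
`n_stages` encoder stages there are `2·n_stages − 1` top-level blocks. Each
decoder block, plus the deepest encoder block, emits a 1-channel side logit
map `S_1..S_K` (K = `n_stages`); deeper maps are upsampled bilinearly to
output resolution; their channel concatenation passes through a 1×1
convolution to the fused logit map `S_0`. Probability maps are
`P_i = σ(β·S_i)`, and the predicted count is the pixel sum of `P_0`.

Two presets:

- **full_scale** — 6 encoder stages (11 blocks), 64 base channels, inner
  depths [7,6,5,4,4,4], 6 side outputs, output maps at 1/4 of the input
  side (4032 → 1008). This preset is constructable and structurally tested;
  training it is far outside desk scale and is not attempted here.
- **miniature** (default) — 3 stages (5 blocks, 3 side outputs), 8 base
  channels, 96-px inputs. All training in tests and examples uses
  miniatures.

**Self-normalization (SNDM).** A per-image scalar β is produced by a bypass
head on the deepest encoder block: global average pool → dense(32) → ReLU →
dense(1) → activation. The default activation is λ·σ(z) with λ = 1.5, so
0 < β < 1.5; a ReLU variant exists. Because the sigmoid is nearly linear
around zero (σ(z) ≈ ½ + z/4), rescaling the logits by β rescales the output
map almost linearly — the network can correct the global normalisation of
its own density map per image, which is exactly the failure mode of plain
density-map counters on crowded dishes. β multiplies **all** logit maps,
including the fused `S_0`. In `dm` mode β is fixed at exactly 1 and no head
exists; forcing β = 1 in an `sndm` model reproduces the `dm` forward pass
bit-exactly (a tested invariant).

Head initialisation: the final dense bias is set so an untrained head emits
β = 1 (no rescaling proposed), with small final-layer weights. This is an
engineering choice of this implementation: it removes a spurious rescaling
transient at the start of training without constraining where β ends up.

**Dropout.** Spatial (channel-wise) dropout, rate 0.1 by default, applied
inside every RSU at the end of its inner encoder and its inner decoder —
identical placement in `dm` and `sndm` modes. The same layers are kept
active for MC-dropout inference.

## Loss and optimisation

Deep supervision: the loss is the **pixel-sum** binary cross entropy of
every probability map (fused plus all side maps) against the clipped
target, summed over maps and over the images of a batch, plus a penalty
`½(1−β)²` per image that anchors the normalisation at "no correction"
(β = 1). The BCE is deliberately a sum, not a mean, so per-map terms scale
with map area; the penalty's relative weight is 1 (configurable). Training
is Adam with learning rate 10⁻⁴, L2 weight decay 5·10⁻⁴ and batch size 2
by default; the checkpoint returned is the epoch with the best validation
count-MAE (patience-based early stopping, default patience 10).

The network and optimiser run on an in-package NumPy engine: a minimal
reverse-mode autodiff with exactly the operators this architecture needs
(patch-gathered convolutions in NHWC layout, pooling, bilinear upsampling,
channel dropout, a numerically stable logit-space BCE). Every operator's
gradient is verified against central finite differences in the test suite.

## Uncertainty quantification

- **Bootstrap (pairs sampling).** B subsets of b = round(0.63·N) training
  images drawn with replacement; one freshly initialised model per subset,
  all selected on the shared validation split. Defaults: B = 20,
  fraction 0.63.
- **MC dropout.** r = 20 stochastic forward passes with dropout active.

Both aggregate identically: prediction = member mean; squared 1σ
uncertainty = **population** variance (divisor B or r, not B−1). Count
statistics are computed on per-member scalar counts (each member's map
summed first); per-pixel mean and σ maps use the same formulas pixelwise.
Summing per-pixel variances would misstate the count variance because
pixels are strongly correlated, so it is never done. Exact member agreement
short-circuits to σ = 0 rather than reporting accumulated rounding noise.

## Synthetic dish scenes

The generator emulates the statistical shape of annotated Petri-dish
benchmarks, not their photographic appearance:

- circular dish (radius ≈ 0.46 × image side, small jitter) on a dark table,
  with a darkened rim;
- three illumination variants — uniform, linear gradient, radial vignette —
  drawn per scene by default;
- counts 0–100 from a mixture placing exactly 85% of its mass below 50
  colonies (discretised exponential below the threshold, uniform above);
  empty dishes occur and matter for false-positive behaviour;
- colony radii log-normal (median 2.5 px at 96-px scenes, σ_log 0.35), so
  dishes mix large and tiny colonies; overlaps and near-edge placements are
  allowed; colonies render as soft-edged disks with per-colony tint jitter;
- additive Gaussian pixel noise (σ = 0.01 by default).

Per-scene covariates are computed exactly: the coverage factor is the pixel
fraction of the dish interior covered by the union of hard colony disks,
and the mean colony size is the mean equivalent diameter √(w·h) of the
boxes (NaN — an explicit undefined flag — for empty dishes).

What this generator does **not** model: species-specific morphology,
condensation, reflections, annotation noise, or the image statistics of
real agar. Results on these scenes demonstrate that the machinery (targets,
losses, β mechanism, ensembles, metrics) behaves as designed; they are not
evidence about accuracy on real laboratory images.

## Evaluation

Per-image records (true count n, predicted count ñ kept unrounded, 1σ, β,
coverage, mean colony size) feed: MAE = mean |n−ñ|; sMAPE =
100/N · Σ|n−ñ|/|n+ñ| with the 0/0 term (an empty dish predicted empty)
defined as 0; the fraction of images with |n−ñ| ≤ k·σ (σ = 0 counts as
covered only when exact); uncertainty averaged in bins of mean colony size
or coverage (empty bins flagged, never silently dropped); and per-size-group
ordinary-least-squares fits of β against coverage (groups with fewer than
two points or zero coverage variance are flagged unfit). Stratified tables
split at 50 colonies by default, mirroring the usual crowded/sparse split.

## Study conditions used by the acceptance suite

The full-scale experiments behind the method (thousands of 4000² images,
GPU-weeks) are not reproducible at desk scale, so the acceptance suite
checks exact properties plus a scaled-down trend study whose conditions
are fixed a priori:

- 300 scenes at 96×96, counts 0–60 from a discretised exponential
  (mean 15), split 240/30/30;
- miniature DM and SNDM, output stride 2 (48² maps — mirroring the
  full-scale input→map downscale), dropout 0.1;
- 20 epochs of Adam at learning rate 2·10⁻³ (the miniature's operating
  point; the full-scale default 10⁻⁴ is far below the miniature's useful
  range), batch 2, weight decay 5·10⁻⁴;
- bootstrap B = 5 (fraction 0.63) and MC dropout r = 20 on the SNDM model;
- the crowded-dish stratum boundary is 30 colonies (half the count range,
  as 50 is to 0–100 in the full-scale analyses).

Under these conditions the suite asserts trends, not published numbers:
SNDM's count-MAE ≤ DM's with the gap concentrated in the crowded stratum,
and bootstrap vs MC-dropout mean σ within a factor of 2 of each other.

## Numerical notes and limitations

- The engine is float32; metrics and ensemble statistics are float64.
- Identical seeds give bit-identical scenes, initialisations, training
  histories and predictions on a fixed platform.
- `maxpool2` splits gradient equally across exact ties (ties are measure
  zero in practice).
- Bilinear upsampling uses half-pixel centers; the factor-2 kernel is
  (¾, ¼) with edge clamping.
- Counts predicted by an untrained network are large (≈ half the map area)
  because σ(0) = ½ — background suppression is the first thing training
  learns; count metrics on untrained models are meaningless.
- The miniature presets underfit relative to the full-scale design; their
  purpose is mechanism verification and CPU-scale experimentation.
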