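# Methods

## Problem setting

Chest CT slices are Hounsfield-unit (HU) valued images in which lung
nodules — soft-tissue-density foci inside aerated parenchyma — occupy a
tiny fraction of the pixels (well under 1%). The package segments them
in two stages: a lung region-of-interest (ROI) model restricts
attention to the pulmonary area, and a nodule model labels pixels
within it. Both stages are encoder-decoder convolutional networks
trained with soft dice loss; the nodule stage can be trained against
the original mask, its pixelwise complement, or a two-channel hybrid of
both, which is the labeling-imbalance experiment the pipeline exists to
run.

## Pre-processing chain

Order: HU window → resize → CLAHE → Wiener. Windowing subsumes
normalization: `(hu − low)/width` clipped to [0, 1], with the lung
window (center −600 HU, width 1500 HU → [−1350, 150]) as the default
input mapping and a soft-tissue window (50/400) available. The order of
the two filters follows the design that denoising acts on the
contrast-enhanced image; resizing precedes both so their neighborhood
parameters refer to the working grid.

* **Resize** — bilinear with anti-aliasing when downsizing (the working
  resolution halves the native 512×512 grid); masks use nearest
  neighbor and stay binary. Interpolated values are clipped to the
  input range so interpolation never invents out-of-range intensities.
* **CLAHE** — per-tile histogram equalization where each bin is capped
  at `clip_limit × tile_pixels` (default clip 0.01, 8×8 tiles,
  256 bins) and the excess is redistributed equally over all bins in a
  single pass; per-pixel output blends the four surrounding tile maps
  bilinearly, clamped at borders. Each tile map is anchored so the
  tile's lowest occupied bin maps to 0 and is clamped into [0, 1]
  (values below a tile's observed minimum map to 0). With one tile and
  an unbounded clip this reduces to plain histogram equalization, which
  the tests exploit as a reference limit.
* **Wiener** — locally adaptive: with local mean m and variance v over
  an odd kernel (default 5×5) and noise power σ² (estimated as the mean
  local variance when not supplied), output is
  `m + max(v−σ², 0)/max(v, σ²) · (x − m)`. Local moments use reflective
  boundaries, so a constant image passes through unchanged — this is
  why the moments are computed in-package from uniform filters rather
  than with zero-padded library variants.

## Networks

`SegModelSpec` describes the graph declaratively: depth (down/up
levels), base channels with a per-level growth factor, LeakyReLU slope
α = 0.3, He initialization (std `sqrt(2/fan_in)`) from a caller seed,
and a residual flag. Each level is two 3×3 same-padded convolutions;
2×2 max-pooling descends, 2×2 transposed convolutions ascend, and
encoder features are fused into the decoder by channel concatenation.
The residual variant wraps each convolution pair as branch + shortcut
(1×1 projection when channel counts change) with no activation after
the addition, so a zero branch is exactly the shortcut. The head is a
1×1 convolution with an independent per-channel sigmoid — hybrid
channels are trained independently, not softmax-coupled. Batch
normalization is deliberately absent by default.

The implementation is plain numpy (float32) with hand-written
forward/backward passes (im2col convolutions, analytic gradients
verified against central differences in the tests) and an Adam
optimizer. Everything is deterministic given the seed: two builds are
bit-identical and repeated training runs produce identical loss
histories.

## Losses, decoding, metrics

Soft dice per (sample, channel): `1 − (2Σpt + ε)/(Σp + Σt + ε)` with
ε = 1e−6 (the smoothing keeps empty-mask gradients finite; the plain
binary dice is recovered as ε → 0). The batch loss is the mean
over samples and channels, which for the hybrid head equals the
unweighted mean of the per-channel dice losses. Predictions binarize at
0.5; hybrid outputs decode as `pos ≥ 0.5 AND neg < 0.5` — the only
rule under which a perfect two-channel prediction returns the ground
truth exactly — with both-channels-asserting conflicts resolved to
background, the conservative choice for a screening aid.
Mono-negative predictions are complemented back to positive polarity
before scoring. Metrics pool confusion counts over all test pixels
(per-case rows are also emitted); pooled dice uses the binary identity
`2TP/(2TP+FP+FN)`. Dice of two empty masks is defined as 1.0: a
no-nodule slice predicted clean is correct. Sensitivity/specificity are
reported as undefined (None) when the truth has no positives/negatives.

## Phantom generator

Each case is a stack of axial slices: soft-tissue body ellipse
(+100 HU) on air (−1000 HU), two lung ellipses (−650 HU, inside the
−700..−600 parenchyma band), and 1-3 nodule discs (+60 HU,
soft-tissue-like so they are visible but not trivially the brightest
structure) placed strictly inside the eroded lung region, plus
i.i.d. Gaussian noise (σ = 20 HU — the constant-power additive model
the Wiener filter assumes). Default in-plane spacing is 0.7 mm, a
plausible chest value, and the radius range (3-8 px at the 256 default)
keeps every nodule diameter below the 30 mm inclusion cap. Nodule
foreground stays below 1% of pixels, the imbalance regime of interest.
Per-case seeds derive from a master seed, so datasets regenerate
bit-identically.

What the phantom does *not* emulate: anatomical shape, texture,
ground-glass opacity, partial-volume effects, vascular confounders.
Passing tests therefore demonstrate that the pipeline's mechanics —
windowing, enhancement, ROI masking, label algebra, optimization —
work and interact correctly, not that the trained models would transfer
to clinical images.

## Desk-scale study conditions

The default experiment sizes are chosen for single-CPU runs: 64×64
working resolution, depth-2 U-Net with 8 base channels, batches of 8,
Adam at 1e−3 (1e−4 to 1e−2 behave similarly on the phantom), up to 20
epochs on roughly 200 nodule-bearing slices. Under these conditions the
mono-positive model reaches held-out pooled dice ≈ 0.85-0.92 and the
ROI Res-U-Net ≈ 0.9-0.98 lung dice; splits are always case-level, and
early stopping on the epoch loss is available but off by default.

## Known limitations

* **Complementary-mode collapse at desk scale.** With a >99%
  foreground target, soft dice has a strong trivial attractor —
  predict foreground everywhere — whose basin the small networks enter
  within a few epochs; the sigmoid then saturates and the gradient that
  would carve out the sub-1% nodule holes vanishes. At this scale the
  mono-negative and hybrid cells of the experiment grid therefore
  decode to empty nodule masks (dice 0), across learning rates
  1e−4..1e−2, widths 8-16 and up to 80 epochs. The harness records
  these outcomes as measured; whether the full-scale setting (256×256,
  64 base channels, hundreds of epochs) escapes the attractor is not
  decidable from the phantom study.
* The numpy networks are CPU-sized: no batch-norm, no GPU, no 3D
  variant; convolution padding is always "same".
* ROI masking at test-fixture time may use the oracle lung mask to
  decouple stage testing; production inference chains the trained ROI
  model instead.
* DICOM support covers single-frame CT series with rescale metadata,
  one series per directory; no multi-frame/enhanced DICOM, no
  de-identification tooling.
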