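# Methods

## The model

`bscn` implements a bidirectional symmetric cascade network for retinal
vessel segmentation. The design treats a vessel map `Y` as a sum of
diameter-specific contour maps `Y = Σ_d Y_d` (d = 1..D, D = 5) and trains
one *scale detection block* (SDB) per diameter scale.

**Backbone.** A VGG16-derived stack: the three fully connected layers and
the last pooling layer are removed and the remaining 13 convolutions are
split into five blocks of (2, 2, 3, 3, 3) convolutions with
(64, 128, 256, 512, 512) channels; 2×2 max pooling sits between
consecutive blocks, so block d runs at stride 2^(d−1) and the deepest
stride is 16 (inputs must be at least 16×16). A `width_multiplier`
scales every channel count so the same architecture runs at desk scale on
a CPU; `0.125` gives (8, 16, 32, 64, 64) channels and ≈1.65 M parameters.

**DDCM.** Every backbone convolution is followed by a dense dilated
convolution module: K cascaded branches (default K = 5), branch k being a
3×3 convolution with dilation rate 2^(k−1) followed by a linear 1×1
convolution. Branches are densely connected by addition (branch k sees
the module input plus all earlier branch outputs) and the module output is
a residual sum of the input and every branch output. The deepest cascade
path has receptive field 1 + 2·(2^K − 1) (63 pixels at K = 5), verified in
the tests by an impulse-footprint oracle. The dense topology is additive
rather than concatenative so channel counts stay constant; branch 1×1s are
linear, with an optional ReLU on the module output (default on).

**Heads and fusion.** Within each SDB the DDCM outputs are summed and fed
to two 1×1 heads, one per cascade direction, giving ten side logit maps.
Each map is bilinearly upsampled (half-pixel-centre convention, fixed, not
learned) to the input resolution; a 1×1 convolution over the ten upsampled
logits produces the fused map, and sigmoids turn all eleven maps into
probabilities.

## Cascade supervision

Stage d is trained against two complementary targets built from the other
stages' current (detached) predictions:

    y_l2h(d) = clamp(Y − Σ_{i<d} P_i^l2h, 0, 1)
    y_h2l(d) = clamp(Y − Σ_{i>d} P_i^h2l, 0, 1)

so the low-to-high chain starts from the full label at stage 1 and hands
each later stage the residual, and the high-to-low chain mirrors this from
stage 5. Before clamping the two targets sum to
`2Y − Σ_{i<d}P_i^l2h − Σ_{i>d}P_i^h2l` exactly (a tested identity).
Targets are stop-gradient constants; the package also ships a numeric
diagnostic (`naive_gradient_degeneracy`) showing why the naive
alternative — supervising the *sum* of all stage predictions with Y —
hands every stage an identical gradient (spread < 1e−6 in finite-difference
evaluation), whereas the bidirectional targets differentiate the stages
(spread > 1e−3 on generic inputs).

## Loss

Per-map loss is a class-balanced cross-entropy. With positives
`Y+ = {i : target_i > η}`, negatives `Y− = {i : target_i = 0}` (pixels in
(0, η] are excluded), and N = |Y+| + |Y−|:

    L = [ −(|Y−|/N)·Σ_{Y+} log p_i  −  λ·(|Y+|/N)·Σ_{Y−} log(1 − p_i) ] / m

Defaults: η = 0.4, λ = 1.1. The total loss is
`w_side · Σ_d [L(P_d^l2h, y_l2h) + L(P_d^h2l, y_h2l)] + w_fuse · L_fuse`
with w_side = 0.5, w_fuse = 1.2; the fusion loss is balanced BCE by
default with a mean-L1 option. Choices worth flagging:

- The positive/negative weights follow the holistically-nested
  edge-detection convention (positive weight = negative-class frequency,
  negative weight = λ × positive-class frequency); the two published
  weight statements are mutually inconsistent for λ ≠ 1 and this reading
  reproduces both up to the λ factor.
- The sum is normalised by the total pixel count m (not by N) so the loss
  scale is resolution-independent; class frequencies are computed over the
  whole mini-batch.
- Predictions are clipped to [1e−7, 1 − 1e−7] before the logs; clipped
  pixels carry no gradient.

## Training

Mini-batch SGD with momentum 0.9, weight decay 1e−4, batch size 8, and a
polynomial schedule `lr = base_lr · (1 − iter/max_iter)^0.9`, stepped per
epoch (150 parameter updates cannot traverse a patch corpus at batch 8,
so "iteration" is read as epoch; a per-update option exists). Full-scale
defaults: base_lr = 2e−3, max_iter = 150. The per-epoch shuffle is
derived from (seed, epoch), which makes runs bit-reproducible and lets a
resumed run continue identically to an uninterrupted one (momentum
buffers are checkpointed). Model selection uses validation Dice of the
fused map at threshold 0.5. A non-finite loss aborts with the offending
term named.

## Synthetic scenes

Real vessel ground truths do not record calibre, so the width-resolved
parts of the pipeline are validated on generated scenes. Vessel trees are
branching random walks: starts on a circle at 0.42·min(H, W) heading
inward, 3 px steps with Gaussian heading perturbation scaled by a
tortuosity parameter (default 0.25), trunk widths stratified across
`width_range` (default 1.5–7 px; one tree per calibre band, so every
scene carries the full thin-to-thick mix) and tapering to 35 % toward
the tips,
branch probability 0.07 per step with width ×0.7, two branching levels.
Strokes are rasterised exactly: a pixel is vessel iff its centre lies
within width/2 of a stroke segment; overlaps record the maximum width.
The image composites a reddish base colour under a radial illumination
falloff, Gaussian bright/dark lesion discs (distractors, under the
vessels), width-dependent vessel darkening, and additive Gaussian noise
(σ = 0.02). The field of view is an inscribed disc.

The scenes emulate the *structural* difficulties of fundus data —
curvilinear trees of mixed calibre, crossings, uneven illumination,
lesion-like background — not its photometric statistics, inter-image
variability, or annotation noise. Passing tests therefore demonstrate
that the cascade machinery behaves as designed, not benchmark-level
accuracy on real datasets.

## The desk-scale overfitting study

`bscn.experiments.overfit_demo` trains a width-0.125 model on eight 50×50
vessel-rich patches (vessel fraction ≥ 4 %) from one synthetic scene for
200 epochs at batch 2 (800 parameter updates) and reports the training-set
Dice of the fused map. The learning rate for this study is 0.05: the
full-scale default 2e−3 at batch 8 is tuned for hundreds of thousands of
updates from a pretrained backbone, and a convergence sweep at this
problem size showed 2e−3–0.01 still far from convergence within the
epoch budget, 0.2 unstable, and batch 8 (one update per epoch)
convergent only for some initialisations. With batch 2 and lr = 0.05 the
run reaches Dice ≳ 0.95 across seeds in ≈2 CPU-minutes.

Scale specialisation is measured per cascade direction: thin-vessel
(width ≤ 3 px) affinity on the low-to-high side maps (stage 1 leads that
chain at full resolution) and thick-vessel affinity on the high-to-low
maps (stage 5 leads at the coarsest scale). Averaging a stage's two maps
mixes a map trained on the label with one trained on a residual and
cancels the signal. After the run, stage 1's l2h map correlates far more
with the thin mask than stage 5's, and stage 5's h2l map far more with
the thick mask than stage 1's.

Optimisation sanity is asserted on the smoothed loss: the 10-epoch moving
average may rise by at most 0.01 between steps (SGD at the overfit
learning rate oscillates by a few 1e−3) and must at least halve over the
run.

## Numerical engine

The network runs on a small reverse-mode autodiff engine over NumPy
arrays (NCHW layout): same-padding dilated convolution via an im2col
buffer and one batched GEMM, 2×2 max pooling (first-index tie-break),
separable bilinear resampling expressed as two interpolation matrices
(which makes the backward pass their exact transpose), and the balanced
BCE as a fused op with an analytic gradient. Parameters are float32;
losses accumulate in float64. He-normal initialisation for backbone
convolutions; DDCM branches use a smaller gain (0.5) so the residual
modules start near identity; all initialisation is driven by one seeded
generator, making builds and runs bit-reproducible on fixed hardware.

## Known limitations

- Benchmark numbers on DRIVE/STARE/HRF/CHASE_DB1 require the external
  datasets and GPU-scale training; the loaders and split protocols are
  implemented and tested on synthetic layouts, but no claim is made about
  real-data accuracy.
- An ImageNet-pretrained VGG16 backbone can be loaded from an `.npz`
  file but is not shipped.
- The rotation augmentation is implemented but disabled by default; the
  published description of its angle grid is incomplete.
- Class frequencies for the balanced loss are computed per batch, not per
  image; at batch size 8 on 50×50 patches the difference is minor.
- The dense DDCM topology (additive skips, residual aggregation) and the
  summed — rather than concatenated — head input are design choices where
  the published description is ambiguous; both alternatives are noted in
  the code and the per-block DDCM placement is available as a config
  switch.
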