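# Methods

This note documents the models, the numerical choices and the open design
decisions behind `octpyramid`, and what the synthetic experiments do and do
not demonstrate.

## Scale-adaptation autoencoder

**Purpose.** Pretrained feature extractors want fixed-size inputs; OCT
devices produce arbitrary sizes, and plain interpolation discards detail.
The scale-adaptation module is a convolutional autoencoder that learns the
resizing: its high-resolution branch replaces the naive resize as the
pyramid input.

**Architecture.** The text-level description of this module leaves the
layer hyperparameters open; the package uses the smallest stack that
satisfies the stated shape contract:

* encoder: `encoder_stages` (default 3) repetitions of 3×3 conv + ReLU +
  2×2 max pool with channel widths b, 2b, 4b (default b = 8); then a 3×3
  projection conv to 3 channels and a bilinear resize to the first target
  scale, giving the latent map `F_AE` (224×224×3);
* processed branch: 3×3 conv → ReLU → stride-1 transposed 3×3 conv → ReLU
  → 3×3 conv to 12 channels (224×224×12). The published "reshape" to 12
  channels is implemented as a channel-projection convolution, since the
  spatial size is unchanged;
* heads: `F_AE` ⊕ processed (15 channels) → 3×3 conv → high-resolution
  output; in parallel 3×3 conv → bilinear resize back to the input size →
  low-resolution reconstruction.

The 112 and 56 pyramid scales are 2×2 and 4×4 average pools of the
high-resolution branch: parameter-free and content-preserving. Non-integer
ratios (custom scale lists) fall back to bilinear resizing.

**Loss.** Two pseudo-Huber terms on the high-resolution side — the branch
output and `F_AE`, both against an antialiased bilinear downsample of the
input to the first scale (a reconstruction target must exist; none is
prescribed, and the downsample is the natural choice) — plus one log-cosh
term on the reconstruction at the original size. This reading of "two
pseudo-Huber functions for high resolution and a log-cosh for low
resolution" (two *terms*, not two δ values) is a design decision; the
weights `(w_hi, w_lo)` default to (1, 1) and δ to 1. Pseudo-Huber is
quadratic for |x| ≪ δ and linear beyond, so speckle spikes do not dominate;
log-cosh is used where twice-differentiability matters. `log cosh x` is
evaluated as `|x| − log 2 + log1p(e^(−2|x|))`, exact and overflow-safe to
|x| ~ 10⁸.

**Training.** Adam (lr 10⁻³ default) on mini-batches grouped by image size;
unsupervised — labels are never consulted. Weight initialisation and
shuffling derive from the single config seed, so training is
bit-reproducible; `learning_rate = 0` provably leaves parameters untouched.
The module is trained separately and then frozen; joint training with the
classifier is not attempted (whether the original system did so is
unstated).

## Dense backbone

Dense connectivity with explicit channel arithmetic: layer *l* of a block
receives `FM(l) = k₀ + k(l−1)` maps; dense layers are BN → ReLU → 1×1 conv
(width `bottleneck_factor·k`, default 4k — the conventional bottleneck
width, which the source text does not print) → BN → ReLU → 3×3 conv (k
maps). Transitions are BN → ReLU → 1×1 conv (compression 0.5 by default —
required for the reference topology to reach 1920 terminal channels) → 2×2
average pool with floor division on odd sizes. The stem is a 7×7/stride-2
conv plus 3×3/stride-2 max pool. BN runs in inference mode on running
statistics (ε = 10⁻⁵); a freshly built network carries mean 0 / variance 1.

The backbone is *frozen*: by default it carries seeded He-initialised
random weights, which at desk scale already yield discriminative features
(random convolutional projections preserve class structure); a checkpoint
loader replaces parameters from a saved archive and reports the first
mismatched array on topology errors. Every dense layer asserts at run time
that its input width equals the growth-rate formula's prediction, so the
channel ledger is audited on every forward pass.

Feature extraction is global average pooling of the terminal map: the
vector length is a pure function of the topology (1920 for the reference
configuration) and independent of input size.

## Pyramid fusion

Three backbone instances (independent seeds by default; optionally shared
weights) embed the three scale-adapted images; the per-scale vectors are
concatenated largest-scale-first. No per-scale standardisation is applied
at fusion time — the fused vector is the raw concatenation — and
scale-sensitive classifier heads standardise on their own side instead.
Weighted or attention-based fusion is out of scope.

## Cascade classifier

Stage 1 is binary (NORMAL vs. everything else); samples whose abnormal
score reaches the threshold (default 0.5, configurable for ROC sweeps) go
to the three-class stage 2. Gating is sound by construction: a sample gated
normal can never receive a disease label. Stage-2 argmax ties break to the
lowest class index (CNV < DME < DRUSEN), keeping prediction deterministic.

Heads are scikit-learn estimators behind a uniform spec surface with these
defaults: SVM rbf/one-vs-rest; DT gini/best; RF gini/100 trees; NB Gaussian
with 10⁻⁹ smoothing; LR liblinear (wrapped in an explicit one-vs-rest
meta-estimator, since liblinear itself is binary-only); MLP (256, 128)
hidden layers, ReLU, Adam at 10⁻³, 50 epochs, batch 128. MLP, LR and SVM
are standardised (fit on training data only); trees and NB use raw
features. Two departures from the published training recipe are inherent to
the scikit-learn MLP: it has no dropout layer and no reduce-on-plateau
scheduler (its exact hidden topology was not published either, so the
printed parameter counts are not reproducible regardless). The SVM head
keeps probability calibration off (matching the printed defaults), so its
scores are logistic-squashed margins: correctly ranked for ROC but not a
probability distribution; the other heads emit normalised distributions.

## Evaluation

Acc/Sen/Spc follow the standard confusion-count formulas; multiclass
Sen/Spc are *macro* one-vs-rest averages (the averaging scheme is not
stated in the source and macro is the neutral choice). Any metric with a
zero denominator returns an explicit NaN marker and is excluded from macro
averages — never silently zero. AUC is the Mann–Whitney statistic (midranks
on ties), macro one-vs-rest for multiclass. Cross-validation is stratified
(the source says only that data were "mixed"), seeded, and places *all*
fitting — including the autoencoder — inside each training fold; a
memorizing-classifier canary in the test suite confirms no leakage. The
paired t-test is two-sided with n−1 degrees of freedom on fold-wise
differences; zero-variance differences return the NaN marker.

## Synthetic data

The generator emulates the discriminative morphology of the four classes:
stacked smooth bands (six sub-bands with distinct reflectivity) over a dark
vitreous with a faint decaying choroid; CNV lifts the deep bands into a
Gaussian dome over moderately reflective material; DME inserts one or two
dark intraretinal ellipses; drusen adds small periodic bumps to the RPE
band. Speckle is clipped multiplicative uniform noise (default ±15%) plus
per-acquisition gain jitter — a fixture choice, not a physical speckle
model. Default canvas 256×320, deliberately different from every pyramid
scale so the any-size input path is always exercised. Generation is a pure
function of the spec (seed included); images are grayscale in [0, 1] and
replicated to three channels at the backbone boundary.

What passing tests show: the architecture wires correctly, learns above
chance on morphology resembling the real classes, and fusion does not
discard signal. What they do not show: performance on real OCT data —
real speckle statistics, device artifacts, anatomical variability and class
imbalance are all absent, and the backbones here are random-weight rather
than ImageNet-pretrained.

## Problem sizes and numerical choices

The test suite and the synthetic study run at desk scale by the package's
own defaults: 50 images per class at 96×128, the tiny backbone (growth 8,
stem 16, blocks 2/2, compression 0.5 → 32 features per path), an
autoencoder with base width 4 trained for one epoch per fold on a 40-image
subsample (it learns low-level statistics, for which this suffices), and
LR heads. Under these conditions the 5-fold study completes in a few
minutes on one CPU and yields cascade/all-at-once accuracies near 0.62/0.65
versus 0.25 chance. Training-path unit tests use a reduced scale list
(56/28/14) with identical arithmetic to the default 224/112/56.

All arrays in the neural core are float32 NCHW; bilinear resizing is
expressed as a pair of row-stochastic linear operators so its transpose is
the exact gradient; max-pool gradients route through stored argmaxes;
odd spatial sizes floor everywhere (trailing row/column dropped). Every
stochastic component (generator, weight init, shuffling, fold assignment,
classifier seeds) derives from explicit integer seeds, and repeated CLI
runs are byte-identical.

## Known limitations

* Random-weight backbones stand in for ImageNet-pretrained ones; the
  checkpoint loader accepts externally converted weights but none ship with
  the package.
* The published headline accuracies on the UCSD/Duke corpora require those
  corpora and GPU-scale training and are outside this package's scope.
* The scikit-learn MLP head approximates the published MLP training recipe
  (no dropout, no plateau scheduler).
* The autoencoder's published layer hyperparameters are unspecified; the
  implementation here is the smallest faithful reading of the shape
  contract, not a weight-level reproduction.
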