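# Methods

## The procedure

`cytosemi` implements ensemble-voted self-training for single-cell
cytology crops. Given a pool of grey images with a small labelled subset,
one run executes:

1. *(optional)* clarity screening: SMD2 focus scores, mean-threshold
   partition, one regularized-deconvolution rescue attempt per failing
   image, discard on second failure; then size standardization to the
   half-up-rounded mean edge length (aspect-preserving rescale, white
   padding).
2. a stratified 5:1:1 train/validation/test split, the training cell split
   4:1 into unlabelled and labelled pools (largest-remainder rounding per
   class, seeded).
3. per round: balance the (real + pseudo) training set; train every
   backbone (warm start) for the round's epoch budget; set fusion weights
   to validation macro-precision; accept pseudo-labels in two passes;
   update the pool; discard leftovers once the unlabelled pool falls below
   10% of its initial size.
4. evaluate the fused ensemble on the held-out test set.

Assumptions inherited from the underlying scheme: the image collection is
exchangeable (no slide-level batch structure), classifier confidence is
informative about correctness, and nucleus darkness is stoichiometric for
DNA content (Feulgen staining), so integrated optical density (IOD) is a
meaningful similarity feature within a class.

## Thresholds: the one deliberate reinterpretation

The two filtering passes are nominally governed by a "maximum" (first pass,
single classifier) and a "minimum" (second pass, fused ensemble) confidence
threshold. If both are set to the same value T — the package's literal
default — the second pass is provably inert: every item remaining after the
first pass has all classifier confidences ≤ T, and a weighted average
cannot exceed its largest element. The standard benchmark configuration
therefore pins the first pass at a fixed high bar (0.95) and lets the
decaying trust schedule (0.9 → 0.5, step 0.1, floor 0.5) govern the fused
pass, which restores the ensemble vote as the main acceptance mechanism.
Both thresholds are independent `ThresholdSchedule` config fields.

Relatedly, filtering and training are decoupled at termination: when the
unlabelled pool drains below the stop fraction, filtering ceases but the
remaining training rounds still run, so every run — semi-supervised or
labelled-only baseline — spends exactly `rounds × epochs_per_round` epochs.
Without this the semi-supervised arm would train fewer epochs precisely
when it succeeds at labelling everything, biasing any comparison.

## Backbones

Convolutional networks at full scale are replaced by scaled-down analogues
sized for 32×32 crops and one CPU: each backbone is a whitened PCA
embedding of the flattened crop (16–64 components, fitted once on the first
training batch and then frozen so warm starts keep a consistent input
space) feeding an MLP head (1–2 hidden layers, 16–96 units) trained with
Adam at the protocol's settings (lr 0.001, β₁ 0.9, β₂ 0.999, ε 1e−8) under
cross-entropy. Registry entries differ in embedding dimension and head
capacity, which preserves the ensemble diversity the voting step needs.

Two numerical choices matter at this scale. L2 penalty (`l2_penalty`,
default 0.1) keeps the heads calibrated — with the default weak penalty,
confident predictions on unseen data were measurably less accurate than
their confidence implied, which poisons threshold-based pseudo-labeling.
And the minibatch size adapts to the training-set size (`n // 24`, clipped
to [4, 32]): Adam's per-step movement is bounded by the learning rate
regardless of gradient magnitude, so a small fixed epoch budget only
converges if each epoch contains enough updates.

Training-time augmentation applies, with probability 0.5 per image per
epoch, one of: centre crop (re-inflated), rotation uniform in ±180°,
brightness or contrast scaling by a factor in [0.8, 1.2]. The protocol
names the operations but not their magnitudes; the ranges are config-level
defaults.

## Balancing

The balancing target c̄ is the mean class count excluding the largest and
smallest classes, rounded half-up; the largest and smallest classes are
still resampled to c̄ (required for "every class equal"). Downsampling
pairs members at random without repetition; a pair whose centred-cosine
angle (features `[IOD, area, mean absorbance]`, centred on the class
centroid; degenerate zero-norm vectors treated as maximally similar) is
below 15° loses one member to the unlabelled pool. Rounds number
`N = ceil(cᵢ/(k·c_min))`, k drawn from {1/2, 1/3, 1/4}; a round removes at
most `floor(c_min/2)` items; a uniform-random fallback enforces the exact
target when similarity rounds don't converge (the two printed rules are not
self-consistent for all count patterns, so the cap is a hard constraint and
early stopping reconciles them).

Two label-hygiene choices: when a similar pair mixes a real and a
pseudo-labelled member, the pseudo member is the one returned to the
unlabelled pool (a real annotation is never traded for a model guess), and
upsampling replicates only real-labelled members where any exist, because
augmenting a mislabelled item multiplies its error. The upsampling palette
(replication, rotation, grey stretch, inversion, log, inverse-log, gamma)
is drawn with weights 0.30/0.40/0.06×5: the photometric transforms remain
available but rare, since stain darkness is the quantitative signal both
the IOD features and the classifiers read.

## Clarity stage numerics

SMD2 uses absolute differences (signed products can cancel and rank a
blurrier image sharper), 0-based x-columns / y-rows coordinates, and sums
over pixels owning both a right and a down neighbour. Screening passes on
score ≥ mean (≥, not >, so a uniform-quality collection survives).
Deblurring is fixed-kernel regularized deconvolution: gradient descent
(default 30 steps, step 0.4) on a Gaussian-reblur data-fidelity term plus
the bounded gradient penalty `Σ D/(D+ε)` (forward differences, replicate
borders, ε = 1e−3, weight 0.05), clipped to [0, 255] each step. It
assumes, rather than estimates, the blur kernel width (`kernel_sigma`);
blind kernel estimation is out of scope.

Absorbance is `γ = log₁₀((I₀+1)/(I+1))` clipped at 0, with background
I₀ = 255 and +1 offsets against log(0). The nucleus region Ω for feature
extraction is an Otsu threshold mask, declared empty when no pixel is at
least 20 grey levels darker than background — a stand-in, since the
procedure never defines how Ω is obtained.

## The synthetic generator

The generator emulates what the pipeline assumes about Feulgen-stained
single-cell crops: eight morphological families (single round nuclei with
occasional nucleoli, paired nuclei, clumps of 3–6, small dense pyknotic
nuclei, 2–5-lobed neutrophils, enlarged deeply-stained abnormal nuclei, and
two debris types — scattered opaque black-spot speckles and light glassy
smudges), rendered as radially decaying absorbance stamps with irregular
boundaries, converted to intensity via Beer–Lambert over a light
background, with seeded per-class counts, an exact blur fraction (Gaussian,
sigma from a configurable range) and additive grey noise. Abnormal-family
radius and stain depth are set so the mean abnormal/normal IOD ratio clears
the 2.5 N ploidy criterion with margin (measured ≈ 6, asserted ≥ 2.5 in
tests). Within-class nuisance variability (centre jitter, radius and
stain-depth ranges, background level) is deliberately wide so that the
supervised learning curve is steep — about 0.76 macro-P at 43 labels/class
versus 0.92 at 250/class for a single backbone — because a benchmark whose
labelled baseline saturates cannot probe semi-supervised learning at all.

What the generator does *not* emulate: real stain calibration and
chromatin texture, touching/overlapping cytoplasm, slide-level illumination
gradients, scanner artefacts, and class frequencies of real screening data.
Passing tests therefore show the machinery is correct and the mechanism can
help under the stated statistical structure, not that it will match
clinical accuracy figures.

## The standard benchmark

Six families (single round, paired, lobed, pyknotic, abnormal, black-spot
debris) × 300 crops = 1,800 images; 5:1:1 split then 4:1, leaving ~43 real
labels per class; three backbones (`vgg19`, `resnet18`, `resnext29_2x64d`
analogues); 4 rounds × 50 epochs; first pass fixed at 0.95, fused schedule
0.9 → 0.5; clarity screening disabled — in a morphologically heterogeneous
collection the between-family SMD2 spread dwarfs focus effects, so the
mean-threshold screen would discard by morphology, and screening is instead
validated on single-family fixtures where score variation reflects focus.
The labelled-only baseline trains the identical ensemble for the identical
budget on the labelled data alone. Across seeds the semi-supervised run
matches or beats the baseline (median gap ≈ +1 to +3 macro-P points,
seed-dependent); pseudo-label precision of the trained rounds is ≈ 0.93.

## Known limitations

- Pseudo-label errors are confident mistakes, concentrated near class
  boundaries; at precision below ≈ 0.9 the loop can underperform the
  baseline (confirmation bias). The discard rule and the high first-pass
  bar are the built-in mitigations.
- The PCA embedding is frozen after round 0, so later rounds improve only
  the head.
- Balancing returns real annotations to the unlabelled pool when they lose
  a similarity pairing; they may later be re-admitted with a wrong
  pseudo-label. This is faithful to the procedure but wasteful; a
  production system would pin real annotations.
- The deconvolution assumes a known Gaussian kernel width; mismatched
  widths sharpen less (they still cannot diverge, being gradient descent on
  a convex-ish energy with clipping).
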