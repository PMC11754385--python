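# Methods

This note documents the models, the synthetic data, the numerical choices,
and what the test suite does and does not establish.

## Translation model

Unpaired translation between the PET-like and SPECT-like domains uses the
cycle-consistent adversarial design: generators G_PS (PET→SPECT) and G_SP
(SPECT→PET) with discriminators D_S and D_P on the respective target
domains. Per optimization step (batch size 1) the discriminators are updated
first on one real and one generated volume each (mean BCE of per-patch
probabilities against real/fake labels, halved so real and fake contribute
equally), then both generators jointly minimize

L_G = w_adv·[BCE(D_S(G_PS(p)), real) + BCE(D_P(G_SP(s)), real)]
    + w_cycle·[‖G_SP(G_PS(p)) − p‖₁ + ‖G_PS(G_SP(s)) − s‖₁]
    + w_id·[‖G_PS(s) − s‖₁ + ‖G_SP(p) − p‖₁]

with w_cycle = 10 and w_adv = w_id = 1. Optimization is Adam (β₁ = 0.5,
β₂ = 0.999) at a constant learning rate; the full-scale defaults are 2e-4
and 200 epochs. Inputs are assumed max-normalized to [0, 1]; translated
outputs are clamped at 0.

**Architecture.** Generators are slim residual encoder–decoders: a 3³ conv
at full resolution, 2× average-pool + conv to twice the channels, one
residual block, channel reduction, nearest-neighbour upsampling, and a final
3³ conv; instance normalization and LeakyReLU(0.2) throughout. The output
layer is *linear*, with clamping to ≥0 applied only at inference: a
rectifying output activation multiplies the reconstruction gradient by its
negative-side slope wherever the pre-activation dips below zero, which can
trap a run in a zeroed-background basin. Discriminators are
three-conv patch networks emitting an 8³ grid of sigmoid probabilities.
Channel reduction *before* upsampling keeps every full-resolution
convolution at few input channels, which dominates CPU cost. Depth/width sit
in `arch_config`; the slim default (base 6 channels) targets 32³ phantom
grids. These layer counts are this package's own design; only the loss
structure, weights, optimizer, batch size and schedule are protocol givens.

**Numerical stack.** The networks run on a small NumPy layer library
(`datbridge.nn`): im2col + BLAS matmul convolution (stride 1, same padding),
with the backward data pass expressed as a same-padding convolution with the
channel-transposed flipped kernel. Every layer's analytic gradient is
verified against central finite differences in the test suite. Float32 is
the default compute type; gradient checks run in float64.

**Desk-scale preset.** `slim_train_config` (5 epochs, lr 2e-3) exists
because a network with ~10⁵ parameters seeing 12 volumes for 30 steps needs
a larger constant step than the full-scale run; nothing else differs. With
it, the cycle loss falls several-fold within 5 epochs and translated
phantoms keep the NC/PD ranking by striatal SBR (AUC ≳ 0.95 on held-out
cohorts in the acceptance suite).

## Synthetic phantoms

Each phantom is an ellipsoidal "brain" of unit intensity containing mirrored
caudate and putamen ellipsoids (striatum = their union) and an occipital
background ellipsoid, on a 32³ grid at 2 mm spacing by default. Geometry is
a fixed constants table in fractions of the grid; centers use
`frac·(N−1)` so the hemispheres are exact mirror images and left/right voxel
counts match. Region intensities are 1 + target ratio, so on a noiseless,
blur-free phantom the measured binding ratio *equals* the target exactly
(the occipital region stays at 1). The rendering order is: paint → Gaussian
PSF blur → additive Gaussian noise inside the brain (blur models scanner
resolution, noise models counts; additive rather than Poisson noise is a
deliberate simplification). Blur therefore *lowers* measured ratios below
the painted targets — the partial-volume effect, asserted as a monotonicity
property.

Population centers follow published NC/PD cohort statistics per modality:
striatal SBR 2.05 (NC) / 1.10 (PD) SPECT-like and 1.57 / 0.92 PET-like,
SPECT-like caudate 2.02 (NC) / 1.19 (PD) and putamen 0.96 (PD), PD
asymmetry 0.19 (SPECT-like). The remaining region-level values (e.g. the
PET-like putamen) are not published per structure; they are solved so the
pooled striatal ratio hits the cohort center under the fixed geometry, and
are emulation choices, not reproductions. Cohort generation jitters the
targets with a common additive Gaussian offset using the published cohort
SDs (0.42/0.33 SPECT-like, 0.20/0.30 PET-like NC/PD), truncated at 0.1, and
jitters asymmetry at half its default SD, truncated at 0. Modality character
is PSF FWHM 5 mm (PET-like) / 9 mm (SPECT-like) and relative noise SD
0.04 / 0.06 — chosen once as plausible emission-imaging values.

What the phantoms do **not** emulate: anatomy beyond ellipsoids, projection
and reconstruction physics, attenuation, scatter, Poisson counting
statistics, or inter-scanner harmonization effects. Passing tests therefore
show that the *pipeline* preserves and measures a disease-like contrast
structure under realistic blur/noise magnitudes — not that it reproduces
clinical image statistics.

## Preprocessing

Training-side order is fixed: smooth (10 mm PET / 6 mm SPECT FWHM) →
divide by the training-dataset maximum (frozen, reused verbatim at test
time; test volumes may exceed 1) → brain-mask. Synthesis-side order:
mask → post-generation smooth (default 1.7 FWHM). Gaussian smoothing uses
per-axis sigma = FWHM / spacing / (2√(2 ln 2)) voxels with reflect padding
(preserves interior sums; avoids edge dimming inside a masked brain). The
post-generation filter width carries no unit in the protocol it mirrors
("1.7", versus the explicit "10 mm"/"6 mm"); both interpretations are
selectable (`units="mm"` default, `units="voxels"` ≈ sigma 0.722 voxels).
The per-dataset (not per-volume) maximum is deliberate and the only option.

## Quantification

Binding ratios use the occipital region as reference; bilateral ratios pool
voxels of both hemispheres (a hemisphere-mean variant is a flag; whether the
original analysis pooled or averaged is not stated). Background SD in the
CNR uses the population (divide-by-N) convention — also unstated upstream;
fixed and documented here. ROI membership is binary. All measures are
invariant under global positive rescaling, so max-normalization never
changes them. A noiseless phantom has zero background SD: the standalone
`cnr` operation raises, while `report` records NaN for that field (possible
only for synthetic data).

## Fréchet distance and embedder

d²(a,b) = ‖μ_a−μ_b‖² + Tr(Σ_a + Σ_b − 2(Σ_a Σ_b)^½), evaluated through the
symmetric form Tr((Σ_a^½ Σ_b Σ_a^½)^½) via eigendecompositions with
eigenvalues clipped at 0; a rounding residue > −1e-6 is clamped to zero.
Covariances are sample covariances; when n ≤ d a shrinkage term
(1e-6·trace/d)·I is added. The default embedder is a fixed-seed Gaussian
random projection (d = 8) of the three axis-wise maximum-intensity
projections: deterministic, offline, and sufficient to make the metric's
mathematics testable. A pretrained 2-D network can be plugged through the
same interface, but absolute distances are embedder-dependent and never
comparable across embedders. The bootstrap comparison resamples each set
independently with replacement per draw (default n_boot 1000; degenerate
all-identical resamples are redrawn, capped at 100 retries) and compares the
two bootstrap distributions with a two-sided t-test and the 95% CI of the
difference.

## Classifier

A residual volumetric CNN ends in concatenated global average + maximum
pooling, a 2-unit linear layer and log-softmax; the higher log-probability
is the prediction, exact ties resolve to NC. The max half of the head reads
the striatal hot-spot intensity directly instead of diluting it by the
volume size. The classifier deliberately contains **no** instance
normalization: the diagnostic signal is the absolute striatal intensity
level, and the spatial mean of an instance-normalized field is constant, so
nothing informative would survive an average-pooling head. Training uses NLL
loss,
Adam with gradient accumulation over small batches, a plateau schedule
(halve the LR when validation loss has not strictly improved for
`lr_patience` epochs) and early stopping (when validation accuracy has not
strictly improved for `early_stop_patience` epochs; the final weights are
returned — the stopping rule only halts). Full-scale defaults: 50 epochs,
patience 30/10, lr 1e-4, factor 0.5. The validation split (when no
validation set is given) is stratified 80/20 at a fixed seed — the upstream
protocol does not state its split. The headline protocol trains on
translated volumes and evaluates on native SPECT-like volumes; across the
domain gap the argmax threshold can be miscalibrated even when the ranking
is nearly perfect, which is why AUC is the primary transfer metric.

"Log sigmoid activation" with two classes and NLL is internally tension-
laden as a specification; it is implemented as two log-probabilities
normalized over classes (log-softmax), which keeps the quoted argmax rule
and the NLL loss coherent.

## Reader-study statistics

VGAS for one criterion and image source is the sum of all observer×image
scores divided by N_i·N_o — algebraically the mean, bounded in [1, 3]. The
real-vs-synthetic comparison uses the two-sided Mann-Whitney U on per-image
mean scores, with the exact null distribution for group sizes ≤ 20 (ties are
not corrected in the exact branch; the asymptotic branch applies the tie
correction). A binary reader has a two-point ROC whose trapezoidal area is
(sensitivity + specificity)/2; this identity is asserted against the generic
sweep-based AUC for every confusion matrix. `compare_groups` gates on
Shapiro-Wilk at α = 0.05: both samples normal → Student's t with the 95% CI
of the mean difference, else Mann-Whitney U; Cohen's d on the pooled SD is
always reported and undefined (None) for zero-variance samples.

## Problem sizes and determinism

The shipped study sizes are desk-scale: 32³ grids, 6+6 unpaired training
phantoms, 5-epoch slim training, 24 held-out translated volumes, 20 native
test volumes, 200 bootstrap draws. They were chosen so the full suite and
the acceptance script run on a single CPU in minutes while leaving the
stochastic acceptance margins (AUC ≥ 0.9, ≥ 9/10 seeds) comfortably met.
Every stochastic component draws from a seeded generator; stage seeds derive
deterministically from one master seed, and repeated runs with the same
configuration are bit-identical (inference is exactly deterministic).

## Known limitations

- The phantom world is geometric; none of the claims here transfer
  automatically to clinical volumes.
- The slim GAN learns an intensity/texture mapping adequate for 32³
  phantoms; no claim is made about full-resolution template grids, and no
  attempt is made to reproduce published FID/AUC values from clinical
  cohorts.
- The default embedder makes FID values internally consistent but not
  comparable to Inception-based values.
- Additive Gaussian noise underestimates the variance structure of real
  emission reconstructions, which inflates CNR stability relative to real
  data.
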