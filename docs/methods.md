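# Methods

`radiogen` studies whether a conditional GAN can translate per-patient
multi-omic latent features into 3D breast-MRI-like volumes that retain
enough molecular signal for downstream mutation-status and subtype
prediction.  Because the corresponding clinical data (TCGA/TCIA cohorts,
pretrained medical-image feature networks) cannot be redistributed, every
claim here is exercised on synthetic phantom cohorts whose generative
ground truth is known, which turns the pipeline's qualitative claims into
testable properties.

## Phantom cohort model

Each simulated patient i carries a latent vector z_i ~ N(0, I_d) with
d = 17 by default, standing in for the per-patient loadings of a
Bayesian-style factorization of expression / methylation / copy-number
data.  The factor model behind real multi-omic latents does not publish a
reference distribution, so the standard-normal prior is a scale-free
stand-in, not a calibrated emulation.

Labels follow generalized linear links:

* mutation status of gene g: y_ig ~ Bernoulli(sigma(w_g' z_i + b_g)),
  with the intercept b_g solved (Gauss-Hermite quadrature + Brent) so
  the *marginal* prevalence matches the cohort rates used throughout
  (TP53 235/690 ≈ 0.341, PIK3CA 247/690 ≈ 0.358, CDH1 112/690 ≈ 0.162)
  — with a nonzero effect the marginal is flatter than logistic(b), so
  the naive logit intercept undershoots;
* subtype: categorical draw from softmax(S z_i), coded Normal=0,
  Basal=1, LumA=2, LumB=3, HER2=4.

Because the phantom renders exactly one image scalar (the lesion score
on a single latent axis), a label is image-predictable only through its
loading on that axis.  The study cohorts therefore give every gene a
mixed effect — a shared loading on the lesion axis, graded so the
image AUCs are ordered TP53 > PIK3CA > CDH1 as in the reference
experiments, plus a private axis that keeps the genes from being
deterministic functions of one another — and grade the subtype softmax
loadings along the lesion axis, which separates the extreme classes
well and leaves the middle classes hard (softmax without intercepts
makes intermediate classes non-modal in a single direction).

Volumes are rendered as a fixed ellipsoidal "breast" of baseline
intensity 0.35 containing one Gaussian lesion blob at a fixed off-center
position.  The blob's amplitude (0.15 + 0.45·sigma(s)) and radius
(base·(1 + 0.3·tanh(s/2))) are strictly monotone in the scalar lesion
score s = u' z_i, so any monotone summary of the lesion region is an
invertible readout of the latent direction u.  I.i.d. Gaussian voxel
noise (sd 0.05 by default) is added and intensities are clipped to
[0, 1].

What the phantom deliberately omits: anatomy, contrast-agent dynamics,
acquisition physics, multi-focal or irregular lesions, and any
correlation structure between latent axes.  Passing tests on phantoms
therefore demonstrate that the *pipeline machinery* (conditioning,
metric, classifiers, bookkeeping) behaves as claimed — not that the
models would reach any particular performance on clinical MRI.

## Conditional GAN

The generator projects the 17-dim condition (optionally concatenated
with a noise vector; `noise_dim` defaults to 0 so inference is a pure
omics-to-image map) through a dense layer to a coarse
(D/8, H/8, W/8) grid and upsamples through three learned 2x
transposed-convolution blocks (instance normalization, leaky ReLU slope
0.2), ending in tanh.  The discriminator scores (volume, condition)
pairs: the condition is linearly projected to 4 constant channels,
broadcast-concatenated to the volume, and passed through three strided
convolution blocks and a dense head.  Non-overlapping kernel-2/stride-2
(de)convolutions were chosen over the classical kernel-4 variant because
each such layer reduces to a single matrix product, which is what makes
CPU-only training of many models per test session practical; at phantom
scale the block-structured upsampling costs nothing measurable in FID or
conditioning fidelity.

Training is a least-squares GAN: discriminator targets 1 (real) / 0
(fake), generator target 1, one D step then one G step per batch, Adam
with beta1 = 0.5 (the usual low-momentum choice for adversarial
stability).  Because the data are *paired* (every latent has its real
volume) and the default generator is deterministic, the generator loss
adds a paired mean-squared reconstruction term with weight
`recon_weight` (default 10): the model is a conditional regression whose
output distribution the discriminator sharpens.  Without this term a
small GAN on a few hundred volumes drifts too much for the conditioning
properties to hold at all.  An `adversarial_loss` of BCE or L1 swaps the
least-squares criterion per score.

Full-scale defaults mirror the reference training table: batch 2,
generator lr 2.5e-5, discriminator lr 1e-5, MSE adversarial loss, 1200
epochs, leak 0.2.  The desk-scale recipe used by the analysis scripts
and the test suite is batch 16, lr 1e-3 / 2e-4, 500 epochs, 8 base
channels — chosen, as the reference work chose its own table, by
comparing Fréchet distances across candidate settings: with it the
discriminator equilibrates near the LSGAN fixed point (loss ≈ 0.25),
the generated high-frequency energy matches the real volumes', and the
generator keeps improving on the distance well after the autoencoder
baseline has plateaued.

## Autoencoder baselines

The "plain" baseline is a vanilla autoencoder (conv encoder to a 17-dim
bottleneck, decoder of the same family as the GAN generator) trained on
reconstruction alone.  A vanilla autoencoder has no conditional sampling
path, so after training the bottleneck codes are ridge-regressed onto
the multi-omic latents and generation decodes the bridge-predicted code.
The decoder only ever saw real encoder codes, so decoding predicted
(conditional-mean) codes is exactly the distribution shift that makes
autoencoders weak conditional generators — the honest mechanism behind
the GAN-beats-autoencoder ordering.  The `pretrained_frozen` variant
freezes the encoder at a fixed-seed random initialization, standing in
for a generic pretrained volumetric backbone (true pretrained weights
are external downloads and 2D besides); only its decoder and bridge are
fitted.

## Fréchet distance

Realism is scored by the squared Fréchet distance between Gaussians
fitted (mean, covariance with n−1 denominator) to features of real and
generated volume sets:

    d^2 = |mu_r − mu_g|^2 + Tr(S_r + S_g − 2 (S_r S_g)^{1/2}),

computed through the symmetric eigendecomposition route
Tr((S_r^{1/2} S_g S_r^{1/2})^{1/2}) with eigenvalues clipped at zero and
an epsilon-jitter retry on numerical failure.  Tests cross-check against
an independent `scipy.linalg.sqrtm` implementation of the asymmetric
product.

The default feature extractor is a frozen, fixed-seed, randomly
initialized 3D conv net (three stride-2 blocks of 8/16/32 channels).
Features are the per-channel spatial mean and standard deviation of
*every* block, not just the deepest: shallow-layer statistics carry the
high-frequency content that separates sharp from blurry volumes, which
is the perceptual axis a realism metric must see (and which pretrained
medical-image networks are sensitive to).  Random frozen features
preserve the *ranking* behaviour of the metric at phantom scale, but
absolute values are not comparable to scores computed with a pretrained
network — reported distances are on their own scale.

The ± spread on a distance is the standard deviation over bootstrap
resamples (default 20).  Resampling is paired — when the two sets are
patient-matched one index draw drives both — so identical sets score
exactly zero; a single resample reports spread 0 by convention.
Cross-validated evaluation trains one model per fold on the remaining
folds, scores generated-vs-real on the held-out patients, and keeps the
fold with the lowest mean distance.

## Classifiers

The volume classifier is the fixed reference architecture: three
conv(3³, stride 1, pad 1) + 2× max-pool blocks with 32, 16, 8 channels,
flatten, a 128-unit dense layer with dropout 0.5, then either one
sigmoid output (mutation status, threshold 0.5) or five raw scores
(subtype, argmax).  ReLU elsewhere; kernel/stride/pool values are the
only common defaults compatible with three pool stages on a depth-32
volume.  Training uses Adam (SGD available), batch size 1 at full scale
per the reference table (tests batch 16 for speed), binary or
categorical cross-entropy, and a reduce-on-plateau learning-rate halving.
Per-task epoch presets follow the reference budgets (CDH1 1300,
PIK3CA 1500, TP53 2000, subtype 2500, real-MRI 300); desk-scale runs use
15 epochs, which suffices for the phantom signal.  Class imbalance is
left unweighted, matching the reference protocol's silence; a weighting
flag exists.

The multi-omic baseline is an L1-penalized logistic regression on the
latent features with penalty strength chosen by internal 5-fold
cross-validation (liblinear solver, fixed random state).

## Evaluation conventions

* ROC-AUC is the Mann–Whitney concordance probability, ties counted ½.
* PR-AUC uses step-wise interpolation (average precision); trapezoidal
  PR interpolation is biased and not used.  With all scores equal the
  curve degenerates to a single point and the AUC equals prevalence.
* Precision/recall/F1: per class from counts; zero-denominator ratios
  score 0 with a warning; multiclass aggregation is the unweighted
  (macro) mean; binary experiments report the positive class.
* Splits: stratified by label, per-image (multiple scans of one patient
  are treated as separate cases, matching the reference protocol; a
  per-patient grouping flag exists because the default leaks patient
  identity across splits).  Per-stratum test counts are
  round(stratum·fraction) adjusted to round(n·fraction), largest strata
  first; strata with fewer than 2 members go to train with a warning.
  Folds come from a seeded shuffled K-fold.

## Numerical and reproducibility choices

All networks run in float32 on a hand-rolled numpy engine
(im2col + BLAS convolutions, manual backprop) with every source of
randomness drawn from explicit `numpy.random.Generator` seeds; training
is serial, so loss histories, parameters, generated volumes, and the
pipeline's consolidated report are bit-reproducible for a fixed config
on a given platform.  The end-to-end pipeline fans a single global seed
out to per-stage seeds by a fixed counter scheme, so stages can be rerun
independently.  Checkpoints are self-describing zip archives (config
JSON + parameter arrays) that reload to bit-identical parameters.

## Problem sizes

The analysis scripts and the test suite run the study at n = 200
patients with 8×32×32 volumes, 500 GAN epochs and 15 classifier epochs,
three seeds where a property is stochastic; the full 32×128×128
resolution and the reference epoch budgets are supported by every
component.  These sizes are the package's own desk-scale choice: large
enough for stable Fréchet statistics and clearly separated
signal/null AUC bands, small enough that the whole suite trains a dozen
networks in minutes.

## Known limitations

* The phantom's one-blob geometry makes the image manifold essentially
  one-dimensional given the latent; all models saturate it, so FID
  differences between trained models are small (the ordering, not the
  gap, is the tested claim).
* Absolute Fréchet values depend on the random extractor seed and are
  not comparable across extractors or to published scores.
* The frozen-encoder baseline's bridge regresses latents onto codes of
  an untrained encoder; its generations are correspondingly poor, which
  is the intended role of that arm.
* With `noise_dim = 0` the generator is deterministic and cannot model
  the phantom's voxel noise; the adversarial term calibrates texture
  amplitude instead.  A noise input is available but unexercised by the
  default study.
* Five-class subtype prediction from a one-scalar image manifold is
  intrinsically partial: macro metrics sit well above the 0.2 chance
  level but far below what a richer image phenotype would allow, and
  most of the shortfall is concentrated in the middle classes.
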