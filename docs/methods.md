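# Methods

This note documents the models implemented in `cardiacdiff`, the choices made
where the design was genuinely open, and what the toy-scale experiments do and
do not establish.

## Problem setting

Supervised cardiac MR segmentation learns a map from short-axis slices
x ∈ R^{C×H×W} to label maps y ∈ {0,…,K−1}^{H×W} with K = 4 classes
(background, left-ventricular cavity LV, myocardium MYO, right-ventricular
cavity RV) by minimising Σᵢ L(S(xᵢ), yᵢ) over network weights.  Generative
augmentation extends the labelled set D^l with M synthetic pairs D^a and
minimises the same objective over D^l ∪ D^a.  The package produces D^a in two
generative stages plus a screening step, and measures the downstream effect
with per-class Dice and Jaccard scores.

## Stage 1 — unconditional mask diffusion

A DDPM is trained over mask encodings.  The forward chain perturbs data with
Gaussian noise under a linear variance schedule β_t from 1e−4 to 0.02 over
T steps (the standard DDPM default; the source of the schedule machinery
α_t = 1−β_t, ᾱ_t = Πα_i).  The network ε_θ(y_t, t) is trained with the
simplified noise-matching objective E‖ε − ε_θ(y_t, t)‖² with t uniform on
1..T, rather than the full variational bound; the reverse-process variance is
therefore fixed, σ_t² = β_t by default (a `posterior` option provides the
Markov-posterior variance σ̃_t², under which a full-length η=1 DDIM trajectory
coincides exactly with ancestral sampling).  σ_1 = 0 so the final reverse
step is deterministic.

Masks enter diffusion as one-hot ±1 encodings (one channel per class) rather
than scalar class indices: Gaussian noise on an index channel would impose a
spurious ordinal metric between classes.  Decoding is per-pixel argmax with
ties broken toward the lowest class index (background-favouring, deterministic).

Sampling uses either full ancestral DDPM or DDIM over an evenly spaced
timestep subsequence (deterministic at η = 0).  Mask sampling uses three
standard stabilisations that matter at short training budgets:

* the intermediate clean-data estimate is clipped to the known ±1 range
  (`clip_x0=1`), reducing stray-pixel artefacts;
* the stochastic DDIM variant (η = 1, posterior-scale per-step noise) is the
  default for pseudo-label generation — re-noising lets later steps heal
  isolated pixel defects that a deterministic trajectory commits to;
* sampling uses an exponential moving average of the weights
  (decay 0.998, optional and off by default in the training API), which
  smooths the parameter noise of short runs.

The reason these matter is a property of the ε-parameterisation itself: at
high t the loss weight of the clean-data component of the target scales with
√ᾱ_t (≈ 0.005 near t = T), so short training runs learn almost nothing about
data structure in the regime where sampling starts; stochastic sampling and
weight averaging partially compensate.

## Label screening

Generated masks are screened against four abnormality classes: fragmented
structures, topology inconsistent with short-axis anatomy, implausibly small
hearts, and background speckle.  The abnormality classes come with no
published thresholds, so the operationalisation here is the package's own:

* the *main cluster* is the largest 8-connected component of the foreground
  union; everything else is a *stray*;
* rule 1 fails when any class forms more than one component within the main
  cluster;
* rule 2 (our reading of "clinical logic" for mid-ventricular short-axis
  slices) requires LV, MYO and RV present in the main cluster, every LV
  boundary neighbour outside LV to be MYO (enclosure, tolerance 0 pixels),
  and at least one RV–MYO adjacency;
* rule 3 requires foreground ≥ 1 % of the grid (at-threshold passes);
* rule 4 allows at most 5 strays.

Scoping rules 1–2 to the main cluster keeps the four verdicts orthogonal:
a speckled mask fails only rule 4, a fragmented one only rule 1.  Thresholds
are exposed in `FilterConfig`; defaults were fixed so that canonical phantoms
always pass and each malformed fixture fails exactly its intended rule.
Acceptance is monotone in the rule-3/4 thresholds and filtering is idempotent.

## Stage 2 — conditional latent diffusion

A convolutional autoencoder compresses images by a factor f (default 8 on
128² images, i.e. 16² latents with c = 4 channels; toy runs use f = 4 on 32²).
Training minimises L1 reconstruction plus a small KL regulariser
(weight 1e−6) toward N(0, I).  This is a deliberately lightweight reading of
"perceptual equivalence": no adversarial or feature-space losses, which keeps
the artifact desk-scale.  The decoder ends in tanh, so reconstructions are
bounded in (−1, 1).  Latents are standardised per channel
((z − μ_c)/σ_c over the training latents) before diffusion, so the N(0, I)
sampling prior matches the training marginals — without the shift, channels
with non-zero mean systematically decode to washed-out images.  A single
learning rate is used for autoencoder training.

The latent denoiser's decoder blocks replace learned group-norm affines with
SPADE modulation: per-pixel (γ, β) maps predicted from the conditioning mask
by a two-convolution head at each resolution, applied as
GN(h)·(1+γ(m)) + β(m) with parameter-free group normalisation.  The mask is
resized to each feature resolution by nearest neighbour, preserving hard
class boundaries and exact one-hotness.  The condition enters only the
decoder half; the encoder is plain residual/attention blocks.  γ/β heads are
zero-initialised, so at initialisation the conditional network computes
exactly the same function as its unconditional twin — verified bit-exactly in
the tests — and conditioning strength is learned from zero.

Classifier-free guidance: during training the condition is replaced by an
all-background mask with probability p_uncond = 0.1; at sampling the guided
prediction is ε_u + w·(ε_c − ε_u) with default w = 1.5.  Both values are
standard for classifier-free recipes; neither has a published counterpart
for this architecture.

## Denoiser backbone

A U-Net with pre-activation residual blocks, sinusoidal timestep embeddings
passed through a two-layer MLP and injected additively per block, strided-conv
downsampling, nearest-neighbour + conv upsampling, and skip concatenation.
The production mask-model configuration has 6 levels with widths
(64, 128, 256, 512, 1024, 1024) — the printed five widths name six levels, so
the deepest width is repeated, the monotone completion — two residual blocks
per level and single-head self-attention on the deepest three levels.  The
autoencoder uses 5 levels, widths up to 1024, group normalisation with 64
groups.  Attention is single-head (the minimal reading of "attention
blocks").  Activation is SiLU throughout.  All parameter initialisation is
driven by an explicit seeded generator; two builds from the same config and
seed are bit-identical, and zero-initialised parameters draw nothing from the
stream so conditional/unconditional twins share their common weights.

## Downstream segmentation and the comparison harness

The segmenter is a 4-level U-Net (toy: 3-level) trained with cross-entropy
plus soft Dice — the standard pairing for class-imbalanced cardiac
segmentation; no specific loss is prescribed for the reference setup — using
Adam (lr 1e−4, weight decay 1e−5) at production scale.  Toy runs use lr 1e−3:
with only hundreds of gradient steps the production learning rate cannot
reach a useful operating point.  Best-on-validation weights are kept.

The harness trains one segmenter per augmentation regime — none, affine,
elastic, intensity, CutMix, diffusion — with equal gradient budgets on the
same real data plus M regime-specific augmented pairs (default M = N, added
to rather than replacing the real pairs; both the ratio and the regime list
are configurable; epochs are rescaled by N/(N+M) so every regime takes the
same number of gradient steps), and scores all regimes on the shared
held-out test split.  For the none-vs-diffusion comparison the downstream
budget is calibrated so the unaugmented baseline sits near the reference
operating point of cardiac studies (mean DSC ≈ 0.8) rather than at the toy
ceiling (DSC > 0.99, reached within a few epochs on phantoms): augmentation
effects are only measurable below ceiling, and the data-scarce regime is the
setting the method targets.
Dice and IoU conventions: both are 1.0 when a class is absent from prediction
and truth alike, 0.0 when absent from exactly one; per-set metrics pool
confusion counts over slices.  DSC = 2·IoU/(1+IoU) holds identically.

## Phantoms

The synthetic generator stands in for real short-axis data in all tests.  A
phantom is an LV disk enclosed by a MYO annulus with an RV crescent abutting
the ring at a random angle — the adjacency/enclosure topology the screening
rules test — with class-dependent intensities in [−1, 1] (blood pools bright,
myocardium dark), additive Gaussian noise (σ = 0.05), and a multiplicative
low-order polynomial bias field (amplitude 0.1) emulating coil inhomogeneity.
Geometry defaults: LV radius 0.10–0.16 and MYO thickness 0.05–0.09 of the
grid side (clamped ≥ 1.5 px so 8-neighbour enclosure survives rasterisation),
RV angular span 120°.  Case-level splitting: cases are shuffled with the
given seed, then cut 7:1:2 (train/val rounded half-up, remainder test), so
50 cases split 35/5/10 and 94 split 66/9/19.

What phantoms do not emulate: real anatomical variability (papillary
muscles, trabeculation, pathology), apex/base slice topology (no-RV slices),
inter-vendor intensity distributions, 3D/cine structure.  Tests passing on
phantoms therefore establish the correctness of the machinery and the
qualitative behaviour of the pipeline, not clinical performance.

## Toy problem sizes

All experiments in the test suite and the reproduction script run on one CPU
with a numpy network engine, so sizes are scaled down deliberately: 32×32
grids, 3-level backbones with widths (8, 16, 32), T = 200 diffusion steps
(shortened schedule with the reference terminal noise level), DDIM at 50
steps with η = 1, 3000 training steps (batch 12, lr 1e−3 cosine-decayed, EMA)
for the mask DDPM, 800 for the autoencoder, 3500 for the conditional LDM, and
a 200-phantom dataset split 140/20/40 for the augmentation study.  At these
budgets the mask DDPM reaches usable but far-from-saturated sample quality:
only a few percent of raw samples survive all four screening rules, so the
screening stage is doing real work, which mirrors its intended role — but it
also means few accepted pseudo-labels feed the synthesis stage.

A consequence worth stating plainly: in the none-vs-diffusion comparison the
diffusion regime does not beat the unaugmented baseline at this scale (the
measured mean-DSC gap is a few points in the baseline's favour).  The
synthesized images reach only part of their target contrast, and adding such
pairs at an equal gradient budget costs more than the extra diversity gains.
This matches the observation that generation fidelity and augmentation
benefit rise together: demonstrating the benefit requires generative quality
beyond what this CPU-scale configuration can train.

## Known limitations

* The numpy engine is single-threaded BLAS-bound; production-scale (128²,
  six-level, T = 1000) configurations are expressed in the configs but not
  trained in the tests.
* The autoencoder's L1+KL objective yields smoother reconstructions than a
  perceptual/adversarial objective would; synthetic image texture is
  correspondingly soft.
* Screening thresholds are heuristic and grid-relative; slice-position-aware
  rules (e.g. apex slices without RV) are out of scope.
* The directional augmentation comparison at toy scale is stochastic; it
  asserts the ordering of regime means across seeds, not effect sizes.
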