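# Methods

This note documents the models implemented in `ctharmony`, the
parameter choices that matter, what the synthetic data does and does not
emulate, and the numerical conventions adopted where the design was
genuinely open.

## Study design

The package models a test-retest CT phantom study: one object scanned
repeatedly under eight reconstruction-protocol arms ("groups") that
differ in reconstruction algorithm (FBP for groups 1–4, IR for 5–8),
kernel (26f vs 30f family), slice thickness (1–3 mm) and slice spacing
(0.75–2 mm). Group 7 (IR, I30f, 2 mm / 1 mm) is the designated
reference: its parameters sit near the middle of the design and IR is
the clinically common choice. Four liver-region tissue classes are
annotated as integer ROI labels 1–4: normal liver, benign cyst,
hemangioma, metastasis.

## Synthetic data

Two generators make the whole pipeline testable without any external
scans. Their defaults are the study conditions; they are set once and
not tuned per experiment.

**Phantom volumes.** `generate_phantom` builds a body ellipsoid
(soft tissue, 20 HU) containing a liver super-ellipsoid (55 HU) in an
air background, and places ellipsoidal ROI blobs with seeded random
centers inside the liver: two normal-liver blobs, two cysts, one
hemangioma, one metastasis — mirroring the annotated multiplicity of a
liver phantom. Each ROI is filled with spatially correlated Gaussian
texture (white noise convolved with a Gaussian kernel at the tissue's
correlation length) at that tissue's HU statistics. Tissue defaults are
chosen to be radiologically plausible within the [−45, 125] HU analysis
window: normal liver 60 ± 12 HU, cyst 5 ± 8 HU (fluid), hemangioma
45 ± 12 HU, metastasis 30 ± 15 HU (hypodense lesion), correlation
lengths 1.5–3 mm. `apply_acquisition` then simulates one protocol arm:
additive Gaussian noise (5 HU for IR, ×1.5 for FBP — the simplest
mechanism that makes the algorithm families differ texturally), Gaussian
PSF blur with a per-kernel sigma (0.6 mm for the sharper 26f kernels,
1.0 mm for 30f; the kernels are named qualitatively, so a parametric
stand-in is required), and an axial slice profile (box average over the
slice thickness, sampling at the slice spacing, linear resampling back
to the native grid). In `simulate_study`, scan *s* shares one phantom
realization across all groups while acquisition noise is drawn per
(group, scan): that is what makes scans *paired* across groups, the
structure every downstream CCC and paired test relies on.

What this does **not** emulate: printed-phantom physics (iodine
densities), projection-domain reconstruction (sinograms, ADMIRE),
dose/kVp effects, and real lesion morphology. Passing tests therefore
demonstrate that the harmonization and evaluation machinery behaves
correctly under a controlled location/scale + blur/noise batch
structure — not that any particular clinical effect size is reproduced.

**Feature tables.** `simulate_feature_table` draws directly from the
batch model `y = α + β·X + γ_i + δ_i·ε`, with ground-truth γ, δ attached
to the table for recovery tests. The paired test-retest structure is
carried by the covariate term: the default design gives every scan index
a latent covariate value shared across batches (scan latent sd 1,
per-feature coefficients ~U(8, 12)), so the same scan is correlated
between any two groups. Without such a shared component, cross-batch
correlation would be ~0 for any harmonization and CCC would be
uninformative. Default batch effects: γ ~ N(0, 3²) and
δ ~ LogNormal(0, 0.25) per (ROI, batch, feature), unit noise. Under
these conditions roughly half the features fail the CCC ≥ 0.95 bar
before harmonization and nearly all pass it after — a regime where the
benefit of harmonization is visible but not trivial.

## Preprocessing

Volumes are resampled to isotropic (1, 1, 1) mm (linear for
intensities, nearest-neighbour for masks), cropped to the bounding box
of voxels above −500 HU (air/bed removal; the threshold separates air
from any plausible phantom material), resampled to a fixed grid —
default (256, 256, 246), configurable; the odd z-value is kept as the
documented default rather than second-guessed to 256 — and clipped to
[−45, 125] HU, the window in which the liver-region tissues are
distinct. Features are computed in HU; rescaling to [0, 1] happens only
at the GAN boundary.

## Radiomic features

93 non-shape features per ROI: 18 first-order, 24 GLCM, 16 GLRLM,
16 GLSZM, 14 GLDM, 5 NGTDM — the unique standard partition of the
non-shape classes summing to 93. Definitions follow the IBSI
conventions; notable choices:

- Discretization: fixed bin width, default 25 HU
  (`floor(x/w) − floor(min/w) + 1`).
- GLCM/GLRLM: the 13 unique 3D offsets at distance 1, matrices
  symmetrized, features averaged over offsets that produce at least one
  pair/run. This makes aggregated features invariant to 90° in-plane
  rotations of isotropic ROIs (verified by test).
- GLSZM zones and GLDM/NGTDM neighbourhoods use 26-connectivity.
- GLDM dependence = 1 + number of neighbours whose level differs by at
  most α (default 0); an isolated voxel has dependence 1.
- Degenerate single-level ROIs: GLCM correlation and MCC are defined as
  1, the information-measure features as 0, first-order entropy as 0.

First-order skewness/kurtosis/variance are population moments; kurtosis
is not excess-corrected.

## Reference-batch ComBat

Per feature, batch means are absorbed by batch indicators in the OLS
design (so unbalanced batch effects cannot bias covariate coefficients);
α̂ is the reference batch's intercept and the standardization variance is
the reference batch's residual variance, so reference samples
standardize to mean 0 / variance 1 and are returned bit-near-identical.
Empirical Bayes shrinks per-batch moments with a normal prior on γ
(prior mean/variance from the spread of per-feature batch means) and an
inverse-gamma prior on δ² (shape/scale moment-matched to the per-feature
batch variances). The posterior point estimates are taken in a single
non-iterative pass — γ* from the δ̂²-weighted posterior mean, then δ*²
from the posterior given γ* — which is the simplest method-of-moments
form; iterative refinement of the pair is deliberately not performed.
The reference batch's γ*, δ* are pinned to 0 and 1. Constant features
(reference variance < 1e-12) are passed through unchanged with a
warning rather than dropped, keeping table shapes stable. Per-ROI
harmonization fits an independent model on each ROI stratum. The study
itself has no biological covariates (X defaults to intercept-only), but
the design-matrix path is implemented and tested because the model
includes β·X.

The printed form of the harmonization equation is ambiguous about the
grouping of the division; the standard reading
`(y − α̂ − β̂X − γ*)/δ*` rescaled back is adopted.

## Image harmonizer

Generator: seven consecutive stride-1 ReLU convolutions with kernels
15, 13, 11, 9, 7, 5, 3 (default 16 filters each), all seven outputs
aggregated — concatenation by default, summation available, since the
aggregation is not further specified — into a final 3×3 convolution
with tanh, added elementwise to the input (the minimal reading of
"combined with the inputs"), then a ramp activation interpreted as clip
to [0, 1] on images scaled from the [−45, 125] HU window. Critic: four
convolutions with filters (32, 64, 128, 256), kernel 5, stride 2,
LeakyReLU (0.2), dropout 0.25, and exact spectral normalization
(largest singular value of the unfolded weight), with global average
pooling and a dense head producing one unbounded scalar per image.

Training: WGAN-GP with gradient-penalty weight 10 and a 5:1
critic:generator update ratio (the standard WGAN-GP convention);
RMSprop for both networks at initial learning rate 2e-4 with per-step
exponential decay (default rate 0.999, exposed in config); batch size 1;
75/25 train/test split at the slice level by seeded permutation;
augmentation by random rotations (±15°), horizontal/vertical flips and
intensity jitter (±0.05) applied identically to both members of a pair.
The composite generator loss is
`1·L_adv + 1000·L_perc + 100·L_L1 + 100·L_NMSE + 100·L_PSNR`, where
L_PSNR = −PSNR/100 dB so that minimizing the total increases PSNR, and
NMSE carries a 1e-12 guard in its denominator. All five components are
logged per step, and the logged total always equals their weighted sum.

The perceptual term compares feature activations of a pluggable
backbone. The default backbone is a fixed-seed random-convolution
feature extractor (3 strided conv+ReLU stages); any callable mapping an
image batch to a list of feature tensors — e.g. a pretrained deep
network — can be plugged in. The loss contract is backbone-agnostic.

The networks run on the in-repo autodiff engine (`ctharmony.nn`):
reverse-mode differentiation over numpy arrays whose backward closures
are themselves built from differentiable primitives, so the gradient
penalty (a function of ∇_x critic) can be differentiated again with
respect to the critic weights. Spectral normalization divides by the
exact largest singular value, treated as a constant during
differentiation (a projection, not a differentiated op). ReLU-family
activations use the a.e. derivative; clip uses subgradient 0 outside
[0, 1].

## Evaluation

- **CCC** (Lin): `2·cov(x,y) / (var x + var y + (mean x − mean y)²)`
  with population moments, computed per (feature, ROI, non-reference
  group) over the scan-paired vectors against the reference group. A
  feature with sample variance < 1e-12 on either side of any comparison
  is excluded from all CCC summaries and listed. Reproducibility
  threshold 0.95.
- **Stability**: paired differences per (feature, ROI, group vs
  reference) tested with Shapiro-Wilk at 0.05; paired t if normal, else
  Wilcoxon signed-rank (zero differences dropped, standard practice);
  all-zero difference vectors short-circuit to p = 1 ("maximally
  stable"). Bonferroni over the group comparisons (7 in the full
  study; the count defaults to the number of comparison groups actually
  present so partial studies are corrected consistently). A feature is
  stable for an ROI when every adjusted p > 0.05; per-ROI results are
  reported as k/93 and percent.
- **Power**: two-sided paired t-test power from the noncentral t
  distribution (noncentrality d·√n, df n−1). At d = 0.5, α = 0.05,
  n = 30: 0.754.
- **Discrimination**: correlation filter removes the later member of
  any feature pair with |Pearson r| > 0.95 (deterministic keep-first by
  column order; constant columns removed first), features standardized,
  RBF-SVM with grid search over C ∈ {0.1, 1, 10, 100} and
  γ ∈ {scale, 0.01, 0.001} under seeded stratified 3-fold CV.
  Hyperparameters are selected on balanced accuracy (margin scores need
  no probability calibration); the reported metric is per-class
  one-vs-rest AUC from cross-validated decision scores, macro-averaged.
- **Image quality**: NMSE = ‖g−t‖²/‖t‖², PSNR = 10·log10(range²/MSE)
  capped at 100 dB for identical images, SSIM with standard windowed
  constants (window shrunk for small images).
- **Method comparison** (`compare_methods`): macro AUC is the mean of
  per-ROI AUCs rounded to 2 decimals; relative changes versus the
  non-harmonized baseline are `100·(m − base)/base` on those rounded
  summary metrics, and the formula is embedded in the output. On the
  four-method per-ROI AUC rows (0.88/0.73/0.73/0.84 baseline vs
  0.98/0.85/0.85/0.95 for ComBat) this yields macros 0.79 and 0.91 and
  a +15.19% change. Derived percentages quoted elsewhere for
  reproducibility/stability do not all follow from one formula; the
  comparison reports its own documented formula rather than asserting
  equality to any externally quoted percentage.

## Problem sizes

Desk-scale runs use reduced sizes chosen to keep the full suite fast
while preserving every contract: phantoms of 24³–32³ voxels with 2–4
scans for pipeline round trips, 16×16–32×32 slices with narrow networks
(4 generator filters, critic (8, 16, 32, 32)) for GAN smoke training,
and the full 93 × 8 × 30 × 4 layout for feature-table simulations,
which are cheap. The architecture defaults remain the full-size ones.

## Known limitations

- The phantom generator produces stationary Gaussian textures; it does
  not reproduce heavy-tailed or structured lesion textures, so absolute
  feature values are not comparable to clinical data.
- Feature definitions are IBSI-aligned but have not been cross-checked
  against an external extractor binary; toy-grid oracles and invariance
  tests are the compliance surface.
- The EB posterior is the single-pass method-of-moments form; packages
  that iterate the posterior pair will differ slightly in γ*, δ*.
- The default perceptual backbone is untrained; perceptual-loss
  magnitudes are not comparable to VGG-based setups, only the contract
  (zero at identity, differentiable, weighted sum) is.
- GAN training at full architecture width on CPU is slow; the engine is
  written for correctness and testability, not throughput.
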