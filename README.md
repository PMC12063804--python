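# ctharmony

Harmonization of CT acquisition variability for radiomics, at the image
level and the feature level, with a complete evaluation suite.

Radiomic features — quantitative intensity and texture descriptors mined
from medical images — are notoriously sensitive to how a CT volume was
reconstructed: reconstruction algorithm (filtered back projection vs
iterative reconstruction), convolution kernel, slice thickness and slice
spacing all shift feature distributions, which undermines multi-center
models. `ctharmony` implements and compares three remedies on a study of
eight reconstruction-protocol arms ("groups") of test-retest scans with
four liver-region tissue classes (normal liver, benign cyst, hemangioma,
metastasis):

1. **Feature-level: reference-batch ComBat.** Features follow the
   location/scale batch model
   `y_ijg = α_g + X_j·β_g + γ_ig + δ_ig·ε_ijg`,
   with additive (γ) and multiplicative (δ) batch effects per protocol
   group *i*. Effects are shrunk by empirical Bayes (normal prior on γ,
   inverse-gamma prior on δ², hyperparameters by the method of moments),
   and every batch is mapped onto a designated reference batch:
   `y* = (y − α̂ − X·β̂ − γ*)/δ* + α̂ + X·β̂`, with the reference batch
   returned untouched.
2. **Image-level: paired WGAN-GP translation.** A shallow-CNN generator
   (seven convolutions with kernels 15, 13, 11, 9, 7, 5, 3; outputs
   aggregated into a final tanh convolution, blended residually with the
   input and clipped to [0, 1]) maps each source group's slices onto the
   reference group's, trained against a spectral-normalized convolutional
   critic under the Wasserstein loss with gradient penalty (weight 10).
   The generator minimizes
   `L = 1·L_adv + 1000·L_perc + 100·L_L1 + 100·L_NMSE + 100·L_PSNR`.
3. **Sequential combination:** GAN-harmonized images feed feature
   extraction, then reference-batch ComBat — in that order.

Evaluation covers reproducibility (Lin's concordance correlation
coefficient against the reference group, threshold 0.95), stability
(Shapiro-Wilk-gated paired t / Wilcoxon signed-rank tests with
Bonferroni correction), discriminative power (grid-searched RBF-SVM
tissue classification, per-class one-vs-rest AUC under 3-fold
cross-validation), achieved power of the paired design, and image
quality (NMSE, PSNR, SSIM).

Everything runs on a built-in synthetic phantom generator (labeled HU
volumes under the eight protocol arms, plus feature tables drawn from
the batch-effect model with known ground truth), so no external dataset
is needed. The neural components run on a small self-contained
reverse-mode autodiff engine over numpy with double-backprop support
(required by the gradient penalty); the 93 non-shape radiomic features
(18 first-order, 24 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM) are
computed natively with IBSI-style definitions.

## Worked example

Feature-level harmonization of the default study simulation (93 features
× 8 groups × 30 scans × 4 ROIs, group 7 as reference):

```python
from ctharmony.synthetic import simulate_feature_table, default_sim_design
from ctharmony.combat import harmonize_per_roi
from ctharmony.evaluation import reproducibility_report, paired_power

table = simulate_feature_table(default_sim_design(seed=0))
harmonized = harmonize_per_roi(table, reference_batch=7)
before = reproducibility_report(table, reference_group=7)
after = reproducibility_report(harmonized, reference_group=7)
print(f"rows: {len(table)}, stored values: {len(table) * 93}")
print(f"average CCC before ComBat: {before.average_ccc:.3f} "
      f"({100*before.fraction_reproducible:.1f}% of features with CCC >= 0.95)")
print(f"average CCC after  ComBat: {after.average_ccc:.3f} "
      f"({100*after.fraction_reproducible:.1f}% of features with CCC >= 0.95)")
print(f"paired t-test power (d=0.5, alpha=0.05, n=30): {paired_power(0.5, 0.05, 30):.3f}")
```

prints

```
rows: 960, stored values: 89280
average CCC before ComBat: 0.909 (47.9% of features with CCC >= 0.95)
average CCC after  ComBat: 0.986 (99.7% of features with CCC >= 0.95)
paired t-test power (d=0.5, alpha=0.05, n=30): 0.754
```

Before harmonization, the injected protocol effects leave fewer than
half of the features concordant with the reference group; per-ROI
reference-batch ComBat removes the location/scale shifts and nearly all
features pass the CCC ≥ 0.95 reproducibility bar. The power value is
the achieved power of a two-sided paired t-test at Cohen's d = 0.5 over
30 test-retest pairs — the per-feature sensitivity of the stability
analysis.

The same study can be driven from the shell:

```bash
ctharmony run --experiment all --seed 0 --out out/        # image / feature / combined
ctharmony simulate --groups 1-8 --scans-per-group 4 --seed 0 --out vols/
ctharmony extract --in vols/ --out features.csv
ctharmony combat --features features.csv --reference 7 --out harmonized.csv
ctharmony evaluate --features features.csv --harmonized harmonized.csv --out report/
```

## Layout

```
src/ctharmony/
  types.py          study domain types (protocol groups, tissues, volumes)
  synthetic.py      phantom + acquisition + feature-table simulators
  preprocess.py     resampling, cropping, HU clipping, ROI relabeling
  features/         93 non-shape radiomic features (native, IBSI-style)
  combat.py         reference-batch ComBat (sklearn-style transformer)
  nn/               numpy autodiff engine + conv/dense layers
  gan_harmonize.py  shallow-CNN generator + WGAN-GP critic + training
  evaluation.py     CCC, stability tests, power, SVM AUC, image quality
  pipeline.py       sub-experiment orchestration + method comparison
  cli.py            `ctharmony` command-line interface
docs/methods.md     model assumptions, parameter choices, limitations
```
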