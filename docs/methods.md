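# Methods

This note documents the models, statistics and numerical conventions behind
`segaudit`, the design choices made where the design was genuinely open, and
what the synthetic experiments do and do not establish about real data.

## Data model and conventions

The unit of analysis is a patient: an ordered stack of 2-D slices, each a
4-channel image (T1, T1-Gd, T2, FLAIR), with a binary whole-tumor mask and a
brain mask per slice. Slices are treated as independent 2-D samples, but
every reported quantity is pooled *per patient first* (pixels pooled across
a patient's slices, one value per patient) before any cohort averaging —
patient-level granularity is the point of the audit, since population
averages wash out exactly the failures it is designed to expose.

All computation is restricted to the brain mask. For model-input
(skull-stripped, normalized) images the brain mask is defined as the union
of nonzero support across the four channels; background pixels are exactly
zero by convention, and every operation is invariant to padding the image
with extra zero border. The whole-tumor label is the union of tumor
sub-components (core, enhancing rim, edema) merged into a single binary
class. The ALL cohort is the plain concatenation of a GBM and an LGG cohort
of the same split — no reweighting, no deduplication — so ALL-cohort tables
are, verifiably, the vertical concatenation of the two sub-cohort tables.

A "summary slice" is the slice with the largest tumor cross-section (ties:
lowest index). Conformal intervals are fitted and summarized on summary
slices only, bounding that axis's cost at one slice per patient.

Undefined ratios (0/0, e.g. PPV of an all-negative prediction) propagate as
missing values and are excluded from means — never coerced to 0 or 1. PPV
and NPV use the standard definitions (PPV = TP/(TP+FP), NPV = TN/(TN+FN)).

## Synthetic cohorts

The generator emulates the *statistical shape* of a skull-stripped,
co-registered glioma cohort, not its anatomy:

* **Geometry.** An elliptical brain roughly filling a 144×144 frame (the
  full-scale convention; tests use smaller frames). The tumor is a randomly
  placed, randomly oriented 3-D ellipsoid whose in-plane radius shrinks away
  from a central slice; radii are calibrated per patient so the whole-tumor
  voxel count lands at a target fraction drawn uniformly from 6.5–8.5% of
  the brain volume (realistic whole-tumor burden, and safely inside the
  6–9% band the generator promises).
* **Phenotypes.** GBM-like tumors have three components — heterogeneous
  core, strongly T1-Gd-enhancing rim (+85 raw units vs a tissue baseline of
  ~95–120, i.e. far above the per-site noise σ of 6–13), FLAIR-bright
  edema. LGG-like tumors are a single diffuse mass, FLAIR-hyperintense
  (+55) and T1-Gd-isointense (0 ± 5), with a wider boundary blur (σ 2.5 px
  vs 1.2) to mimic ill-defined margins. These reproduce the qualitative
  radiology: rim enhancement with perifocal edema for GBM, non-enhancing
  FLAIR hyperintensity for LGG, and they make the two grade groups
  statistically separable (rank-sum p < 0.01 over 20 patients), so
  stratified generalization experiments are non-degenerate.
* **Sites.** Each site applies a fixed per-channel affine intensity
  distortion, a noise level, and optional smoothing, identically to all its
  patients. GBM sites carry numeric codes, LGG sites alphabetic codes, with
  disjoint rosters — mirroring the TCGA convention — so site and grade are
  confounded the same way they are in the real collections.
* **Raw vs model-input images.** Quality features are computed on
  *pre-normalization* volumes, which carry a faint background air-noise
  floor (raw scans are not skull-stripped); the model-input images are
  skull-stripped (background exactly zero) and per-channel normalized by
  the 99th-percentile brain intensity, applied after the site effect. The
  percentile choice is this package's convention for "pixel-intensity
  normalization". Consequently the site-PCA separates cohorts strongly on
  raw features and much less after normalization — the audit's own check
  that preprocessing homogenizes scans. If a user supplies already
  skull-stripped raw volumes, background-dependent features (SNR1, SNR2,
  SNR4, CNR, CJV) are reported missing rather than fabricated.

Default synthetic slice count is 16 per patient (configurable); audits and
tests use reduced patient counts (e.g. 5–6 per test cell) and, in tests,
72×72 frames. These sizes were chosen so a complete nine-condition audit is
a coffee-break computation while every statistic still has enough pixels
(10⁴–10⁵ brain pixels per patient) to be stable.

What passing on synthetic data shows: the machinery — metric algebra,
calibration fitting, coverage guarantees, attack gradients, FDR control —
is correct, and every qualitative direction the framework is meant to
detect (under- vs over-segmentation signatures, calibration improvement,
lower confidence on tumor than brain, sensitivity collapse under attack,
site batch effects) is detectable when present. What it does not show:
performance levels on real MRI. Elliptical single-focus tumors with
Gaussian noise are far easier than BraTS; the toy segmenter's Dice ≈ 0.95
is a property of the phantom, not a claim about any real model.

## Toy segmenter

A pixelwise logistic scorer: logit zᵢ = Σ_c wd_c x_ci + Σ_c wl_c m_ci + b,
where m_c is a zero-padded box mean (5×5 default) of channel c — eight
weights and a bias. It is trained by full-batch gradient descent (learning
rate 2.0, 300 iterations, seeded slice sampling) on soft Dice loss
L = 1 − (2Σpy + ε)/(Σp + Σy + ε), ε = 1, over brain pixels pooled from up to
48 tumor-bearing slices. The soft-Dice gradient is scale-free in the pixel
count, so one step size works across cohort sizes.

Because the box filter with zero padding is a self-adjoint linear operator,
the input gradient of the loss has the closed form wd_c·g + wl_c·box(g)
with g = ∂L/∂z — verified against central finite differences to ≤ 1e-4
relative error. That closed form is what the FGSM axis consumes; real
models supply the same two methods (`predict_logits`,
`loss_input_gradient`) through the `Predictor` contract, typically via
autodiff.

## Calibration

Platt scaling p = σ(a·z + b), with (a, b) minimizing NLL on
validation-cohort pixels (L-BFGS on the convex two-parameter problem;
label-stratified subsample of ≤ 200,000 pixels, seeded — a two-parameter
fit does not need more). A non-positive fitted slope is allowed but warns,
since it means probabilities decrease with the logit.

Quality metrics per patient, then averaged: NLL (probabilities clipped to
[1e-7, 1−1e-7] inside the log only), Brier score, and binned calibration
errors with 10 equal-width bins on the foreground probability — ECE% is the
count-weighted mean absolute gap between mean predicted probability and
empirical foreground fraction, MCE% the maximum gap over nonempty bins.
The binning statistic is foreground-probability vs foreground-fraction
(not confidence-of-argmax), which is the natural binary-segmentation
convention and keeps p = 0.5 well-defined. With one bin, ECE reduces to
100·|mean(p) − mean(y)|; MCE ≥ ECE always. Ten bins is the convention of
the calibration literature this metric family comes from.

AUROC is invariant under Platt scaling whenever a > 0 (monotone
transform); the suite asserts this rather than assuming it.

## Conformal prediction intervals

Intervals quantify *regression* uncertainty of the calibrated probability
given the logit — the targets are Platt-calibrated probabilities in [0, 1],
not the 0/1 labels. Pipeline: pool (logit, calibrated probability) pairs
from validation summary slices; shuffle (seeded) and split 50/50 into a
proper-training half and a conformal-calibration half; fit two
pinball-loss quantile regressors at levels α/2 and 1−α/2 on the basis
(1, z, σ(z)); compute conformity scores Eᵢ = max(q_lo(zᵢ)−yᵢ, yᵢ−q_hi(zᵢ))
on the held-out half and set the offset Q to their ⌈(1−α)(n+1)⌉/n-th
empirical quantile. Test-time intervals are [q_lo(z)−Q, q_hi(z)+Q], clipped
to [0, 1] and clamped so lower ≤ upper (clamped-pixel counts are recorded).

Design choices: α defaults to 0.1 and is exposed in config. The regression
basis includes σ(z) because the 1-D regression from logit to calibrated
probability is sigmoid-shaped; a purely affine basis would leave large
systematic residuals that inflate Q and misattribute basis misfit to model
uncertainty, whereas with the sigmoid term the noiseless case (targets
exactly σ(z)) is representable with essentially zero width. The 50/50
validation split is required for the finite-sample marginal coverage
guarantee (coverage ≥ 1−α), which the suite verifies empirically on
heteroscedastic synthetic data with n_cal = 2,000.

The per-patient summary is the API — mean interval width over the brain or
the tumor-only region of the summary slice. On the default synthetic audit
the tumor-region API exceeds the brain-region API (models are least
confident exactly where the clinical question is), with condition-level
medians and quartiles serialized for violin plots.

## FGSM robustness

One-step attack x′ = x + ε·sign(∇ₓL) per slice, using the model's own
training loss (Dice), with sign(0) = 0 and the perturbation restricted to
brain pixels so the background stays exactly zero. ε = 0 returns the input
bit-identically, making the first sweep column the clean evaluation by
construction. The schedule (0, 0.005, 0.01, 0.05, 0.1, 0.2, 0.4, 0.6, 0.8,
1.0) is dense at the low end to resolve small perturbations; ε is on the
normalized-intensity scale, so ε = 1 is a drastic attack. Perturbed images
are not clipped to the input range by default (clipping is available behind
a flag). Aggregation: per-patient metric values, mean, and Student-t 95%
CIs across patients (appropriate at small n; bootstrap was considered and
rejected as needlessly stochastic for a deterministic audit). Only two
curve facts are asserted as hard properties — ε = 0 identity and
sensitivity loss at the endpoint — because adversarial decay need not be
monotone per patient. A control comparison against an independent random
±ε sign field verifies the gradient direction is genuinely adversarial.

## Quality features and batch effects

Thirteen per-modality features computed on the pre-normalization volume
(F = brain voxels, B = background): MEAN, RNG, VAR (population), CV;
PSNR = 10·log₁₀(max(F)²/MSE(F, median-filtered F)); SNR1 = mean(F)/sd(B);
SNR2 = median(F)/sd(B); SNR3 = mean(F)/sd(F − local-mean F);
SNR4 = mean(F)/MAD(B); CNR = (mean(F)−mean(B))/sd(B); CVP = sd/mean of an
11×11 patch at the brain centroid of the middle slice;
CJV = (sd(F)+sd(B))/|mean(F)−mean(B)|; EFC = Shannon entropy of the
energy-normalized intensities divided by its maximum √N·ln√N (scale-
invariant). These formulas are this package's fixed, testable definitions
of the MRQy-style feature family; CV, CJV, EFC and PSNR are invariant to
intensity scaling, MEAN and RNG scale linearly — asserted by dimensional-
analysis tests.

The per-patient performance vector has six entries per model: mean
calibrated foreground probability over the TP, TN, FP and FN pixel sets
(missing when a set is empty), Dice, and AUROC. The correlation screen
computes Spearman ρ (midrank ties, large-sample p) for every cell of the
17-feature × 4-sequence × 6-metric × 3-model grid — 1,224 comparisons — and
applies Benjamini–Hochberg at α = 0.25 across all non-missing p-values.
The four stochastic embedding coordinates of the full MRQy roster (TSNEX,
TSNEY, UMAPX, UMAPY) are enumerated but never computed; their 288 cells are
reported as explicitly missing, preserving comparison-count conservation
(grid size = product of dimensions; missing cells logged). Cells with
fewer than 3 complete pairs or a constant column are likewise missing.

Site tests: z-score each feature column (constant or NaN-containing
columns dropped with a log entry), PCA (full SVD, deterministic), then
one-way ANOVA of PC1 and PC2 across site codes plus all pairwise
two-sample Welch t-tests. Welch was chosen because "paired" tests across
sites of different sizes are not literally possible; unequal-variance
pairwise comparisons are the coherent reading.

## Orchestration and reproducibility

`run_audit` trains the three models (M_GBM, M_LGG, M_ALL on their
respective training cohorts), calibrates each on its own validation
cohort, fits each model's CQR on that same validation cohort, and runs the
enabled axes over all nine conditions, writing per-axis CSVs, plots, a
consolidated `summary.md`, and a `manifest.json` with package/numpy
versions, seeds, cohort content hashes, per-axis timing and per-condition
status. An axis failure is recorded per condition and the audit continues;
the CLI exits nonzero if any failure occurred. All randomness derives from
the single config seed, and rerunning an identical config reproduces every
CSV byte-for-byte (asserted in the suite).

## Known limitations

* The phantom is 2.5-D (an ellipsoid sliced), single-focus, and noise is
  Gaussian; no bias fields, motion, ghosting, or multi-focal disease.
* The toy segmenter is linear in 8 features; it cannot emulate the failure
  *modes* of a deep network, only exercise the evaluation machinery with a
  genuinely differentiable model.
* Conformal coverage is marginal, not conditional: tumor-region coverage
  can fall below 1−α even when overall coverage holds.
* Spearman p-values use the t approximation, optimistic below ~10 pairs
  (an exact permutation option exists for small n).
* The audit evaluates whole-tumor segmentation only; sub-region labels and
  boundary-distance metrics (Hausdorff, ASSD) are out of scope.
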