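# Methods

## Problem and model

`sectorvit` predicts whether a renal-cell-carcinoma patient's estimated
glomerular filtration rate (eGFR, mL/min/1.73 m²) will drop by more than a
threshold (10 or 20) after partial (PN) or radical (RN) nephrectomy.  The
inputs are heterogeneous: a clinical table, radiomic features of the tumor,
and two CT-derived image crops per axial slice (tumor only; kidney plus
tumor).  The classifier is a *sector-split* vision transformer: the
concatenated 1-D input is split by fixed sector lengths, and every sector —
class-token (length 0), demographics (age, sex, BMI), comorbidity
(peripheral vascular disease, diabetes, liver disease), habit (smoking,
alcohol), surgical (ischemia time, blood loss, surgery type, procedure,
approach, operative time), selected radiomics (32), and the two flattened
128×128 crops — is processed by its own patch embedding, learned class
token, pre-norm transformer encoder (alternating multi-head self-attention
and two-layer GELU MLP blocks, residual connections, layer norm before each
block and a final layer norm), and an MLP classification head with four
hidden layers and a softmax.  The model output is the elementwise mean of
the per-sector probability vectors ("voting").

Default architecture hyperparameters: patch dimension 32, head dimension 64,
2 heads, MLP dimension 64, depth 8.  Model width (`embed_dim`) is not
determined by those five values; we default to 64, with attention projecting
`embed_dim → n_heads·head_dim` and back, the decoupled-width formulation
standard for ViT-family models.  Each sector has its own learned class token
and learned positional embeddings (disable with `use_pos_embed=False`);
positional information is irrelevant for the class-token output under token
permutation (a property the test suite checks), but we keep the embeddings
as the conventional extension point.  Partial final patches are zero-padded;
because all features are z-scored, zero is the training mean.

Everything — forward pass, analytic backpropagation, Adam — is implemented
in NumPy.  Two independent checks guard the numerical core: an
explicit-loop attention oracle (agreement to 1e-6) and a central
finite-difference gradient check (1e-4 on a depth-1, width-8 model).

## Training

Binary cross-entropy optimized by Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8,
weight decay 0, AMSGrad off), 200 epochs by default, probabilities clamped
to [1e-7, 1−1e-7].  Mini-batches (default 32) sample slices, so one
patient's slices may straddle batches.  After every epoch the image-level
training accuracy is computed and the parameters of the best epoch (ties →
earliest) are kept.  The loss attaches to the voted positive probability by
default.  A per-sector summed BCE (`loss_mode="per_sector_sum"`) is provided
because where the loss attaches is an open choice given softmax sector
heads; in our experiments it trains every sector to confident memorization
of the small training cohort and generalizes clearly worse, so the voted
attachment is the default.

One optimization property of the voted loss is worth recording: the
gradient reaching a sector's logits carries a factor p₀p₁ of that sector's
own softmax, so a sector that saturates early (e.g., by memorizing the
training patients from a patient-constant payload such as age/BMI) stops
receiving gradient and its memorized noise is frozen into the vote.  With
cohorts of tens of patients this measurably dilutes held-out performance:
in desk-scale diagnostics the held-out AUC peaks in the first few epochs
and collapses once the uninformative sectors saturate.  Two mitigations are
exposed, both off by default and both enabled in the desk-scale
configuration: inverted dropout on the token embeddings and the head's
hidden activations (`TrainConfig.dropout`), and a held-out checkpoint
monitor (`monitor="validation"`): a stratified 15% of the training patients
is excluded from gradient updates and the checkpoint with the best
image-level accuracy on those patients is kept — early stopping by
checkpoint selection.  The monitor patients are drawn from the training
split only and never overlap the test set.  Learning rate defaults to 1e-3
(Adam convention); it is not annealed.

## Cohort handling

ΔeGFR = preoperative − postoperative eGFR; positive = deterioration; labels
are ΔeGFR > threshold.  For RN patients a missing ischemia time is defined
as 0 (no residual kidney is clamped).  Exclusions, in order: (i) any of the
14 clinical fields missing; (ii) missing pre/post eGFR; (iii) no slice whose
tumor annotation has ≥ 256 pixels (the threshold is per slice; the patient
goes only when no usable slice remains); (iv) usable-slice count outside
mean ± SD over the survivors of (i)–(iii).  We use the sample SD with
inclusive bounds.  Class balance (v) is established at the image level:
whole patients are removed first from the image-majority class (uniformly
among patients whose removal does not overshoot), then individual slices are
trimmed uniformly, never emptying a patient.  The train/test split is
stratified by label and always per patient; patient ids are canonically
sorted first, so the split is invariant to row order.  The default test
fraction is 0.265 for the 10-point threshold and 0.24 for the 20-point one,
matching the cohort proportions those thresholds are reported with.

## Imaging and radiomics

Crops are the minimum axis-aligned rectangles containing the tumor mask and
the union of kidney and tumor masks (0-based, inclusive boxes), resampled to
a square model input with Pillow's Lanczos (a=3) kernel, then windowed to
[−200, 500] HU and mapped to [0, 1].  The window is our choice (a
conventional soft-tissue window); bit-exact equivalence with any specific
Lanczos implementation is not claimed — tests assert tolerance properties
(constant preservation, near-identity, mean preservation on ramps).

Radiomics are computed per slice on raw HU over the tumor ROI: a fixed,
versioned catalogue of 44 features — 19 first-order statistics, 15 GLCM
texture features (symmetric, normalized co-occurrence matrix averaged over
the four standard 2-D offsets, fixed bin width 25 HU anchored at the ROI
minimum), and 10 shape descriptors (area, boundary-edge perimeter, inertia
tensor axes, convex-hull maximum diameter, compactness, extent,
eccentricity).  Degenerate conventions: constant ROI → skewness/kurtosis 0,
entropy 0, uniformity 1, GLCM contrast 0, joint energy 1; GLCM correlation
is 1 when a marginal variance vanishes.  Feature selection keeps the top 32
features by one-way ANOVA F computed on the training split (descending;
ties broken lexicographically; infinite F first, undefined F last); the
selection and all z-scoring statistics are frozen on the training split.

## Evaluation and statistics

Nine metrics: accuracy, sensitivity, specificity, PPV, NPV, F-score,
AUC-ROC (Mann-Whitney rank formulation, ties ½), log-loss (same clamping as
training), and Cohen's kappa.  Undefined ratios are reported as NaN with a
warning.  95% CIs are percentile bootstrap (B = 1000, seeded), resampling
patients for patient-based analysis and slices for image-based analysis;
degenerate resamples with one class absent are skipped.  Patient-level
aggregation: probability = mean of the slice voted probabilities; binary
label = majority vote of slice predictions with ties toward the positive
(decline) class — conservative for a screening-style question.

Model comparison: McNemar on paired correctness (exact binomial below 25
discordant pairs, chi-square with continuity correction above), DeLong on
correlated AUCs via midrank placement values, and two-sided Mann-Whitney U
(exact for tie-free samples with n_x·n_y ≤ 400, else normal approximation
with tie correction).

## Sector permutation importance

For each sector, a uniformly random non-identity permutation of the test
patients reassigns that sector's patient payloads (slice lists are moved
wholesale; a donor's list is cycled to the recipient's slice count), the
patient-based accuracy is recomputed, and the drop from the original
accuracy is recorded; 100 repeats per sector.  The identity permutation is
excluded because with cohorts of ~25 patients it would occur often enough to
dilute the statistic.  Negative mean drops are meaningful (a sector whose
permutation *helps* held-out accuracy) and are never clipped.  Sectors are
compared pairwise with Mann-Whitney U (stars at 0.05 / 0.001 / 0.0001, no
multiplicity correction by default).

Because sectors are processed independently and the vote is an elementwise
mean, permuting a sector's payloads permutes that sector's cached per-slice
output probabilities in exactly the same pattern.  `run_importance`
therefore evaluates permutations on cached probabilities by default — an
exact algebraic identity, not an approximation — and a test verifies it
against direct permute-and-re-forward on a small model.

## Synthetic cohort generator

The generator emulates a nephrectomy cohort at desk scale.  Clinical
marginals: age ~ N(61, 10) clipped to [30, 90]; BMI ~ N(30.5, 6); 57% male;
comorbidity and habit frequencies typical of such series; 38% RN; ischemia ~
Gamma(mean 19 min, SD 8) for PN and 0 for RN; blood loss ~ lognormal (mean
≈ 300 mL); operative time ~ N(250, 60) min.  Images are Gaussian noise
fields with a brighter elliptical "kidney" and an inner elliptical "tumor"
(≥ 256 px by construction) whose speckle SD is 12·(1 + image_beta·tanh(L))
for a per-patient latent texture signal L ~ N(0, 1).  Outcomes: pre-eGFR ~
N(74, 14); ΔeGFR = surgical_beta·(RN + ischemia/100 min) + radiomic_beta·L
+ demographic_beta·(age−61)/10 + N(0, noise_sd), floored at −10; post =
max(pre − Δ, 0).  The same latent L drives the image speckle and the
outcome, so ANOVA selection and the image sectors have a recoverable
target.  Defaults: 60 patients, 8 slices each, 64×64 images, surgical_beta
14, radiomic_beta 4, image_beta 1, demographic_beta 2, noise_sd 3 — the
surgical sector carries the dominant signal with a secondary texture
signal, and the positive fraction lands near 0.4 before balancing.

What the generator does *not* emulate: anatomy, contrast phases, scanner
effects, slice correlation beyond shared texture, or any nonlinear
feature-outcome relation.  Passing the planted-signal tests shows the
pipeline recovers known signal at desk scale; it says nothing about
real-cohort performance.

## Desk-scale configuration and problem sizes

The default pipeline configuration (`pipeline.default_config`) is sized for
a single CPU: 60 patients × 8 slices of 64×64 images, model width 32, depth
2, head dimension 16, patch dimension 128, 50 epochs, dropout 0.2, a
validation checkpoint monitor, bootstrap B = 1000, 100 permutation repeats.
The full-scale architecture defaults (patch 32, head 64, depth 8, 200
epochs, dropout 0, train-set monitor) remain the dataclass defaults of
`VvitConfig`/`TrainConfig`; the desk configuration only shrinks the problem
so the full pipeline runs in tens of seconds per seed.

The planted-signal acceptance experiments use two arms: a *strong surgical
arm* (surgical_beta = 30, all other effect weights 0), under which the
label is nearly deterministic in the RN indicator plus ischemia time and a
correct pipeline should recover held-out patient-level AUC ≥ 0.8 and rank
the surgical sector first in permutation importance; and a *null arm* (all
effect weights 0, noise_sd 30 so the label mix stays near balance and the
balanced cohort keeps its size), under which every sector's mean importance
should be statistically indistinguishable from zero.  For the null arm the
standard error is taken across independent seeds (8), not across the 100
within-run repeats: for one fixed model and test set the unpermuted
accuracy is itself one draw from the permutation distribution, so the
within-run SE would be the wrong yardstick even for a perfect
implementation.

## Known limitations

- The 44-feature radiomics catalogue is a defined stand-in for a full
  IBSI-style set; no wavelet/LoG or 3-D features.
- No CNN baselines are trained; the comparison machinery (McNemar, DeLong)
  is fully implemented and tested against enumeration/bootstrap oracles.
- Reproducing the published real-data metrics requires the original cohort
  and long stochastic training; this package reproduces the *method* and
  verifies it on synthetic data plus the printed-metric arithmetic.
- The voted-BCE saturation effect described under Training is a property of
  the architecture; dropout mitigates but does not remove it.
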