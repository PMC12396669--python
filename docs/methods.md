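# Methods

## The normative model

The analysis treats anomaly detection as deviation from a healthy
reference distribution. An autoencoder with layer widths
20–15–10–4–8–10–13 (ReLU between layers, identity output) is trained on
healthy controls only. Inputs are 6 perfusion features (regional mean CBF
divided by 100), 7 diffusion features (regional mean ADC divided by
3,000) and 7 covariates (age, sex, cerebral volume, cerebellar volume,
age², age·sex, age²·sex) min-max scaled with bounds fitted **on the
training controls only**. The outputs reconstruct the 13 imaging features
only. Because the width-4 bottleneck cannot carry arbitrary detail, a
subject whose features violate the healthy covariate-conditional law is
reconstructed *toward* that law; the signed residual per feature
(reconstruction − observation, rescaled to physical units) localizes the
deviation, and the per-subject mean squared error over the 13 normalized
features aggregates it.

Covariate normalization is deliberately not clipped: patients older or
more atrophic than any training control map outside [0, 1], and that
out-of-range signal is part of the anomaly. The output layer is linear
for the same reason — a bounded activation would saturate exactly where
the signal lives.

Canonical feature order (fixed across all stages): perfusion (caudate,
hippocampus, pallidum, putamen, thalamus, CGM), diffusion (same + CWM),
covariates (age, sex, cerebral volume, cerebellar volume, age², age·sex,
age²·sex). Sex is coded 0 = male, 1 = female. Session selection keeps the
youngest session per subject for longitudinally scanned clinical-cohort
subjects and the oldest for the preschool reference dataset, which
narrows the age gap between sources; age ties break on the smallest
session id.

## Training

The per-subject MSE is the quantity of scientific interest, and its
median over a group is the evaluation and model-selection metric
throughout (group medians are what the loss reports show). As a
*training* objective two variants are implemented: the mean of
per-subject MSEs within a mini-batch (default) and the batch median
(subgradient taken at the median-defining subject; lower median for even
batches). The median objective propagates one subject's gradient per
step; at 80 training subjects it measurably underfits (validation
median-MSE ≈ 3.9 × 10⁻⁴ vs ≈ 3.1 × 10⁻⁴ for the mean objective under
otherwise default settings), so the mean objective is the default and the
median remains available via `Hyperparameters(loss="median")`.

Defaults: Adam, learning rate 5 × 10⁻³, batch size 16, up to 500 epochs,
early stopping on validation median-MSE with patience 50, weight decay
10⁻³. Weight decay is on by default for a reason specific to normative
modeling: the model is *always* evaluated out of distribution (patients
lie outside the healthy covariate range), and an unregularized ReLU
network behaves erratically there — on some seeds the entire A-T error
profile collapses to one sign. The L2 penalty keeps off-manifold
extrapolation tame at no cost on the in-distribution selection metric
(control validation loss 3.07 × 10⁻⁴ ± 0.11 × 10⁻⁴ across 15 generator
seeds, versus 3.09 × 10⁻⁴ unregularized). All defaults are configurable,
and a k-fold CV grid search (`grid_search`, default k = 5) ranks
user-supplied configurations by mean validation median-MSE, retaining the
top five for reporting; the single best is retrained for use.

Weight initialization is He-scaled from a seeded generator; batching,
splits and every other random choice derive from one master seed through
named sub-seeds, so training is bit-reproducible.

## Synthetic cohort generator

The generator emulates the study conditions the pipeline is designed for,
not real MRI physics. Controls (default n = 110) draw age from a scaled
Beta placing the median at ≈ 5.5 y in [2.9, 16.3]; cerebral and
cerebellar volumes are linear in age and sex with Gaussian noise
(medians ≈ 1,085 and ≈ 133 mL); each imaging feature is linear in (age,
sex, cerebellar volume) plus independent Gaussian noise, with
coefficients set so the covariates explain roughly 30–50 % of feature
variance, and values confined to plausible bands (ADC 300–2,000 × 10⁻⁶
mm²/s, CBF 10–100 mL/100 g/min under defaults). A-T-like subjects
(default n = 16) draw from an older age distribution (median ≈ 12 y in
[4.6, 17.8]) — deliberately stressing covariate extrapolation — and are
shifted along a disease direction scaled by a per-subject latent severity
(truncated normal, mean 1, SD 0.35): raised cerebellar-GM and -WM ADC,
mildly lowered hippocampal and caudate ADC, lowered caudate and putamen
CBF, raised pallidum CBF, reduced cerebral (≈ −105 mL) and cerebellar
(≈ −89 mL, median target ≈ 70 mL) volume. Under the normative model,
raised features are under-estimated and lowered features over-estimated,
which is the anomaly signature the statistics stage tests. Clinical
sub-scores are baseline − slope · severity + noise, truncated to bounds,
so lower scores mean more severe disease and severity is recoverable by
the association stage.

What the generator does **not** emulate: inter-feature noise correlation
(an equicorrelation knob exists but is unvalidated), scanner/site
effects, longitudinal structure, non-linear age trajectories, or any
spatial information. Passing tests on this cohort demonstrate that the
pipeline detects and localizes deviations of the constructed kind; they
are not evidence about real A-T data.

## Statistics

Group comparison uses a two-sided permutation test on the pooled-variance
t statistic of per-subject MSEs with the add-one estimator
p = (#{|t_perm| ≥ |t_obs|} + 1)/(B + 1), B = 1,000 by default, plus a
two-sided rank-sum test and both group medians. Degenerate edge: with
zero within-group variance and unequal means (maximal separation) the
permutation p is set to its floor 1/(B + 1) by convention. Per-feature
over/under-estimation within a group uses a one-sample sign-flip
permutation test of the mean signed error against zero (the test is not
named in the source analyses; sign-flipping is the natural one-sample
permutation scheme). No multiple-testing correction anywhere — the
analysis is exploratory by design.

The anomaly heatmap standardizes **signed errors** (not reconstructed
values — the reference wording is ambiguous; errors are what the rest of
the analysis interprets) against the control test set's mean and SD per
feature, and orders feature columns by agglomerative clustering with the
Lance-Williams maximum-linkage (complete) update on Euclidean distances,
leaf order from the dendrogram's canonical ordering. The latent-space
view embeds the width-4 codes to 2-D with UMAP (15 neighbors, shrunk with
a warning for tiny cohorts; min_dist 0.1; fixed seed). The embedding is
presentation-layer only.

## Shapley attribution

Attributions use a model-agnostic Kernel SHAP estimator written for this
package: coalitions are sampled from the Shapley kernel distribution over
subset sizes (default budget 2·20 + 2,048 coalitions), absent features
are filled from up to 50 seeded background controls, and the attribution
vector solves a least-squares system constrained so that
base + Σφ = f(x) holds exactly (local accuracy by construction). For
linear models the estimate equals the closed form wᵢ(xᵢ − E[xᵢ]), which
the tests exploit as an oracle. "Self-effect" exclusion masks the 13
identity pairings (caudate-CBF input on caudate-CBF output, etc.);
cross-modality same-region pairs (caudate-ADC input on caudate-CBF
output) are *not* masked, and covariate inputs are never masked. Stacked
summaries aggregate mean attributions per input, split by sign,
separately over the 6 perfusion and 7 diffusion outputs. Attributions are
on the normalized output scale; a helper rescales rows to physical units.

## Clinical association

One LASSO per NEST sub-score on A-T subjects only: outcome and all
predictors z-standardized, L1 penalty on the 13 signed error predictors,
penalty factor 0 on the 7 covariates (they are adjustments with a-priori
relevance, never selected away). Signed errors are used as predictors —
the reported coefficient signs are only interpretable with signed
residuals. λ comes from 5-fold CV minimizing validation MSE (no
one-standard-error rule at these sample sizes) unless given. Coefficients
with |β| > 0.1 are reported. A reduced covariate set (age, sex, cerebral
volume) is available via `covariates="reduced"`.

The solver is cyclic coordinate descent with per-coefficient penalty
factors. Unpenalized coordinates are concentrated out exactly by least
squares (partialling-out identity) before descent on the penalized block,
which avoids stalls on the degenerate free directions that arise when
covariates outnumber residual degrees of freedom. Correctness anchors:
λ = 0 reproduces OLS; an orthonormal design reproduces coordinate-wise
soft-thresholding; unpenalized coefficients survive any λ.

A note on power: with 16 subjects and 7 partialled-out covariates, ~9
effective observations remain for 13 correlated predictors — no method
recovers support reliably there, and at that size the analysis is
exploratory. The solver-verification simulations therefore run at
adequate sizes: planted-signal recovery on 60-subject generator cohorts
(recovery rate ≥ 0.9 required) and null false-report behavior on
200-subject cohorts (reported set empty in ≥ 80 % of null replicates).

## Numerical and reproducibility choices

- All randomness flows from one master seed; pipeline stages receive
  named sub-seeds (SHA-256 of `"{seed}:{stage}"`, reduced below 2³¹).
- The run manifest records the config hash (analysis parameters only, not
  the output path), stage seeds and artifact lists; wall-clock timings go
  to a separate file so reruns are byte-identical.
- Imaging normalization round-trips to within one ulp (division by 100
  and 3,000 is not exact in binary floating point).
- Permutation tests are vectorized (one index-matrix draw per call), so
  calibration studies with hundreds of replicates stay cheap.
- Default problem sizes used by the verification scripts: 110/16 cohort,
  1,000 permutation iterations, 500 calibration replicates at 200
  iterations each, 50 association replicates, 3 training seeds for the
  sign-recovery check.

## Known limitations

- The normative law and the generator share a linear-in-covariates form;
  real developmental trajectories are non-linear and the real feature
  covariance is unknown.
- Kernel SHAP with a sampled coalition budget is an estimator; its
  variance is negligible for near-linear trained models but grows with
  model curvature.
- No post-selection inference for the LASSO coefficients: reported
  coefficients carry sign and magnitude, not calibrated p-values.
- UMAP coordinates depend on the seed and neighbor count; only the
  qualitative group separation is meaningful.
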