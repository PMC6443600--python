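# Methods

This note documents the models, the parameter choices that matter, the
synthetic world the tests run in, and the numerical decisions taken where
the design was genuinely open. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic world

**Phantoms.** A tumor region of interest is emulated as a Gaussian random
field inside an ellipsoid (semi-axes at 40% of each volume extent). White
noise is convolved with a Gaussian kernel of σ = ℓ/√2, giving a
squared-exponential autocovariance with length scale ℓ
(`correlation_length`, voxels); the field is rescaled to marginal sd
`noise_sd`, multiplied by `contrast` and shifted by `mean_intensity`
(HU-like). Voxel spacing defaults to 2 mm isotropic, matching the
acquisition convention the pipeline emulates. Defaults use two texture
classes at contrast ratio 2 (1.0 vs 2.0) and correlation lengths 3 vs 1.5
voxels — chosen so that GLCM features separate the classes (verified as a
two-class AUC > 0.9 property), which is what lets texture carry hazard
information downstream. The phantoms do not attempt CT noise spectra,
contrast-phase effects or lesion-shape realism.

**Endpoints.** TTP follows a Weibull proportional-hazards model:
`T = scale · (−log U / exp(η))^{1/shape}` with
`η = β_sig · latent + β_AST · ast_flag`, centred. Defaults: shape 1
(exponential), scale 5.2 months — median `scale·ln 2 ≈ 3.6` months at
η = 0, the cohort-wide median the simulation emulates — and planted
log-hazards `β_sig = ln 2.45`, `β_AST = ln 3.66`, the multivariable
hazard-ratio magnitudes of the emulated analysis. The latent texture risk
is the z-scored class contrast plus N(0, 0.5²) within-class jitter. OS is
TTP plus an independent exponential post-progression survival (mean 7.9
months, the emulated OS−TTP median gap); the joint law is otherwise
unspecified in the source analysis, and independence is the simplest
choice that guarantees OS ≥ TTP. OS is administratively censored at the
empirical (1 − rate) quantile of the drawn OS times (default rate 19/96 ≈
0.198). TTP events are all observed by default; whether the emulated
cohort's non-progressed patients were censored is ambiguous, so a
`censor_ttp` switch exposes the alternative reading rather than guessing.

**Cohort tables.** The 24 clinical/blood variables are drawn to roughly
match the emulated cohort margins (86/96 aged < 65, 82/96 male, 78/96
smokers, 41/96 stage IV, …); blood values use normal/log-normal laws
around conventional reference ranges. AST is generated conditionally on
its ground-truth risk flag (prevalence 0.25 — a typical abnormal-AST
fraction in advanced disease; the source gives no count). All other
variables are independent of hazard by default (they were found
non-prognostic in the emulated analysis); `confound_demographics` ties age
into the hazard for robustness experiments. RECIST response is assigned
by rank-thresholding a noisy copy (sd 0.8) of the latent risk so the
marginal counts are PR/SD/PD = 27/56/13 per 96. The TKI validation arm
is generated at the hazard of the low-texture-class, normal-AST corner of
the chemotherapy cohort, on the same centred scale.

A green test on this world establishes that the pipeline's statistics
behave correctly under proportional hazards with texture-linked risk; it
does not establish radiological realism, non-PH robustness, or the
specific fitted numbers of any real cohort.

## Feature bank

Exactly 356 3-D + 236 2-D features per patient:

| family | features | grid |
|---|---|---|
| first-order | 12 (mean, sd, population variance, skewness, kurtosis, energy, entropy, min, max, range, median, MAD) | once per dim |
| GLCM | 9 (contrast, dissimilarity, homogeneity, energy, entropy, correlation, cluster shade, cluster prominence, max probability) | levels {8,16,32,64} × distances ({1,2,3,4} 3-D, {1,2} 2-D) × {mean, range} over directions |
| GLRLM | 7 (SRE, LRE, GLN, RLN, RP, LGRE, HGRE) | levels × {mean, range} |
| Gabor (2-D only) | 2 (response variance, response histogram entropy) | frequencies {0.1, 0.2, 0.4} cyc/voxel × orientations {0°, 45°, 90°, 135°} |

3-D co-occurrence/run-length statistics average 13 canonical directions;
2-D uses the 4 in-plane directions, computed per mask-intersecting axial
slice and aggregated by unweighted mean. Counts: 12 + 2·4·(9·4+7) = 356
and 12 + 2·4·(9·2+7) + 24 = 236. The full manifest (id → family/params)
is written alongside `features.csv` so the bank is auditable.

Numerical conventions: equal-width quantization on the masked range
(constant regions map to level 1); GLCM accumulation is symmetric, mask
aware (both voxels of a pair must be in the mask) and normalized after
accumulation; entropies use log2; GLCM correlation is NaN for degenerate
marginals; an offset with no valid pair yields an explicit missing value,
never zero; run-length runs break at the mask boundary. The Gabor even
kernel is DC-corrected so constant inputs give ~0 response, and a
numerically constant response is assigned zero histogram entropy.
Responses are computed by FFT convolution with symmetric (reflect)
padding; a kernel larger than the slice warns and proceeds.

The "GMTR variance" / "GPT rentropy" Gabor statistics named by the source
analysis are undefined there; they are implemented as the response
magnitude's variance and 64-bin histogram entropy, and flagged as an
interpretation. The bracketed parameter indices of the published
signature are unrecoverable and are not reproduced; the frozen reference
model uses descriptive ids instead.

## Signature

* **Screening:** one univariate Cox fit per feature (z-scored internally;
  the Wald p is invariant to affine rescaling), retained at raw p < 0.05.
  A Benjamini-Hochberg switch exists for sensitivity analysis. The fits
  run as one vectorized Newton-Raphson with Breslow tie handling —
  identical to Efron whenever event times are distinct, which holds
  almost surely in the continuous-time simulations; the multivariable
  fits use lifelines' Efron handling.
* **LASSO-Cox:** `scikit-survival` elastic-net path at l1_ratio 1,
  features z-scored before the shared penalty, weights rescaled back to
  the raw feature scale. The penalty is chosen by K-fold (default 10)
  cross-validated partial likelihood (Verweij–Van Houwelingen deviance),
  1-SE rule. If the 1-SE model is empty the fit falls back to the
  CV-optimal penalty, then to the smallest penalty with support, each
  with a warning; a path with no support at all raises. Folds are seeded;
  the whole fit is bit-reproducible.
* **Cut-point:** exhaustive scan of midpoints between consecutive
  distinct order statistics, subject to a 10% minimum group fraction;
  argmax of the two-group log-rank statistic, ties broken toward the more
  balanced split. Scores at or below the cut-off are "good-TTP". The
  naive p-value at the selected cut-point is anti-conservative because
  the cut-point is chosen to maximize the statistic; the acceptance suite
  measures this inflation under the null and the package deliberately
  reports it uncorrected, matching the emulated practice.

## Risk models

Dichotomization uses a cut-off registry (threshold, direction, source)
covering all 24 variables; risk requires strict exceedance, so boundary
values are normal. Only the smoking cut-off (cohort median, 9600
cigarettes) is anchored in the emulated analysis; the others (AST > 40
U/L, ALT > 40 U/L, CEA > 5 ng/mL, ALB < 35 g/L, …) are conventional
reference limits and are explicitly overridable stand-ins.

PIM indices are the candidates (signature status + univariately
significant clinical statuses) retained at p < 0.05 by multivariable Cox;
collinear candidates are dropped by a VIF filter with a warning. The PIM
score counts indices at risk; strata are 0 / 1 / ≥2. The clinical
comparison model applies the same counting rule to the significant
clinical indices alone. GPS uses the original Glasgow definition (2 iff
CRP > 10 mg/L and albumin < 35 g/L, 0 iff neither, else 1), restricted to
complete-case patients. In the orchestrated pipeline only, an empty
multivariable selection (possible in very small smoke-test cohorts) falls
back to a signature-only index with a warning; the library operation
itself raises, since a prognostic index with no significant index is
undefined.

## Evaluation

* C-index: Harrell's definition oriented as higher score = higher risk;
  ties in score credit 0.5; a pair is comparable when the earlier time is
  an event (or times tie with exactly one event). 95% CI by seeded
  patient-level bootstrap (default 2000 draws; 500 in the pipeline for
  runtime).
* NRI/IDI: continuous (category-free) variant at a 6-month horizon — the
  same horizon as the calibration curve, since no separate horizon is
  stated — with inverse-probability-of-censoring weights from the
  Kaplan-Meier estimate of the censoring distribution; p-values by seeded
  bootstrap SE and a normal approximation. Identical models return
  exactly 0 with p = 1.
* Decision curves: strata enter as risk probabilities via each stratum's
  observed KM event probability at the horizon; net benefit follows
  `TP/n − (FP/n)·Pt/(1−Pt)` with treat-all/treat-none references.
  Patients censored event-free before the horizon are excluded from the
  decision-curve 2×2 counts (in the default world TTP is uncensored, so
  this exclusion is empty).
* Calibration: a univariate Cox fit on the supplied linear predictor
  provides per-patient predicted survival at the horizon (Breslow
  baseline); quantile bins (default 5) are compared with per-bin KM
  estimates; empty/duplicate bins merge with a warning.
* Demographic balance: Kruskal-Wallis per variable across strata;
  constant variables report p = 1 with a note.
* All CIs are 95%, tests two-sided, significance at 0.05.

## Reproducibility

One master seed fans out to per-stage seeds through
`numpy.random.SeedSequence.spawn` (all below 2³¹), so stages are
independently rerunnable; reports carry the config hash, the seed list
and a content hash. Two runs from one config are byte-identical,
including the NIfTI phantoms — an acceptance property.

## Known limitations

* Proportional hazards everywhere; no time-varying effects or competing
  risks.
* The phantom generator produces stationary Gaussian textures; real
  tumors are neither stationary nor Gaussian, so feature values are not
  comparable to clinical CT magnitudes (the frozen reference signature is
  shipped for scoring, not validated against synthetic phantoms).
* The maximally selected cut-point's significance is not corrected
  (measured and documented instead).
* The TKI arm models only hazard equivalence, not treatment dynamics.
* 2-D Gabor only; no wavelet/LoG image variants; no shape features.
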