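# Methods

This note records the models implemented, the assumptions and defaults
behind them, the design choices that were genuinely open, and what the
synthetic data can and cannot establish.

## The scientific setting

Presence-only occurrence records are abundant but abundance data are
scarce, especially for wide-ranging carnivores in regions where field
access is limited. A practical workaround is to model environmental
suitability from occurrences alone and to ask whether suitability can
stand in for relative abundance. Theory and empirical work suggest the
relationship is *triangular* rather than linear: low suitability caps
abundance, while high suitability permits — but does not guarantee — high
abundance. The right statistical object is therefore the **upper
conditional quantile** of abundance given suitability, not the mean.

The pipeline implements that whole chain: two suitability algorithms
calibrated on presences within an accessible area, validated by replicate
AUC and cross-compared by weighted kappa, then confronted with camera-trap
capture rates through quantile regression.

## Synthetic virtual species

All stages are exercised on generated data with known truth.

- **Landscape.** Predictor layers are Gaussian white noise convolved with
  an isotropic Gaussian kernel (σ = `smoothness` cells, periodic
  boundaries), standardized to mean 0, sd 1. Designated layer pairs are
  made collinear by mixing a shared field: `L_j ← ρ L_i + √(1−ρ²) L_j`.
  This is the simplest controllable form of spatial autocorrelation and
  guarantees the collinearity filters have work to do when ρ ≥ 0.9.
- **Niche.** True suitability is a product Gaussian,
  `s(x) = exp(−Σ_k ((x_k − c_k)/w_k)²/2)`: exactly 1 when every predictor
  sits at the niche centre, monotonically decreasing along each axis.
- **Occurrences.** Cells are drawn without replacement with probability ∝
  `s × bias`, one presence per cell. The bias layer
  `exp(strength · smooth field)` emulates spatially uneven collection
  effort (a human-footprint surrogate); the same layer weights background
  sampling, mirroring the recommended bias-correction practice.
- **Abundance.** `N_i = U_i (a + b s_i)` with `U_i ~ Uniform(0,1)`
  i.i.d. — the multiplicative-uniform wedge. No cell exceeds its ceiling
  `a + b s`, and the conditional τ-quantile of N given s is exactly
  `τ(a + b s)`, so quantile regression at high τ should recover slope
  ≈ `τ b`, intercept ≈ `τ a`. This is precisely the structure the wedge
  analysis assumes; a truncated-count alternative was deliberately left
  out of scope.
- **Cameras.** Stations occupy distinct cells; detections follow a
  homogeneous Poisson process at `rate_scale × abundance` per day over
  `effort_days`, with a multi-animal photograph probability of 0.05
  (n_individuals = 2) to exercise the multi-animal clause of the
  independence filter. The proportionality constant between detection
  rate and abundance is a free scenario parameter (no field value exists
  for it); the default 0.25/day per abundance unit puts simulated capture
  rates in the 0.01–0.5 events/camera-day range reported for wild felids.

**Default study conditions.** 100 × 100 fine grid aggregated 2× to a
50 × 50 calibration grid (emulating the study's 1-km projection and 10-km
calibration resolutions); five layers, smoothness 3, collinearity 0.9 on
the first pair; 500 occurrence records; 240 stations × 110 days ≈ 26,400
camera-days (matching the scale of the motivating survey: 241 sites,
26,784 camera-days, per-species presence-cell counts 220–2268).

**What the generator does not emulate:** real geographic projections,
temporally varying climate, species interactions, imperfect detection
heterogeneity across stations, and observer-side record errors. Passing
tests therefore demonstrate internal correctness and recoverability under
the stated generative model, not performance on any real dataset.

## Accessible area (trend surface analysis)

A logistic regression of presence cells against all other cells of the
calibration grid on the nine cubic trend-surface terms (lat, long,
lat·long, long·lat², long²·lat, lat², long², lat³, long³; planar y = lat,
x = long). Terms are centred and scaled internally — this affects only
conditioning, not predictions. A small ridge penalty (1e−4 on the
standardized scale) keeps the fit defined under complete spatial
separation. The accessible area keeps every cell whose fitted probability
is **≥** the minimum fitted probability over presences; the closed
comparison means the defining presence always survives, so the mask
contains 100% of presences by construction.

## Predictor filters

- **Stepwise VIF** (threshold 10, the conventional default of the
  referenced stepwise procedure) on accessible-area cells: repeatedly
  drop the predictor with the largest `VIF = 1/(1−R²)` while any exceeds
  the threshold. Infinite VIFs (perfect collinearity) are dropped first;
  ties drop the later column.
- **Greedy Spearman filter** (|ρ| > 0.8) on presence-cell values, used
  for the DNC predictor set: while any retained pair exceeds the cut,
  drop the member of the worst pair with the larger mean |ρ| against the
  other retained predictors; ties drop the later column; constant
  predictors (undefined ρ) are dropped up front. The rule is a
  deterministic, reproducible stand-in for interactive tools that leave
  the choice to the analyst.

Whether the VIF sample should be the accessible area or the presences is
ambiguous in the emulated protocol; the accessible area was chosen
(matching the spatial domain the models are calibrated on) and the
correlation filter kept on presences, which is where redundancy matters
for the centroid covariance.

## Maxent-style model

The maximum-entropy density over background cells with feature set
`{x_k} ∪ {x_k²} ∪ {x_j x_k, j<k}` is fitted through its equivalence with
an L1-penalised presence-vs-background logistic regression. Details:

- Predictors are standardized by background mean/sd **before** products
  are formed; prediction-time values outside the training range are
  clamped to it (and the clamping logged).
- Per-feature penalty `reg_multiplier × sd_bg(feature) × √m / W`, where
  `m` is the presence count and `W` the total sample weight. The √m and
  sd scalings mirror the classic implementation's default regularization;
  the `m/W` factor converts it to the weighted-logistic objective (which
  is normalized by total weight rather than per presence). Default
  `reg_multiplier = 1.0`.
- Optimizer: monotone FISTA (accelerated proximal gradient with a
  fixed Lipschitz step, momentum restart, and a plain proximal fallback
  whenever acceleration would increase the objective), so the penalized
  objective is non-increasing by construction. The intercept is
  unpenalized. An independent solver (liblinear) reproduces the
  coefficients to ~1e−4 in the tests.
- Output: with `q(x) = e^η(x)/Z` normalized over the training background
  and `H` its entropy, the reported suitability is
  `cloglog(x) = 1 − exp(−e^H q(x))` — a strictly monotone map of η into
  [0,1] equal to `1 − 1/e` for a cell of entropy-average suitability, and
  invariant to additive shifts of η.
- Background: 10,000 cells drawn ∝ bias inside the accessible area (with
  replacement only if fewer cells exist). Replicates (10 by default, 70/30
  splits) are fitted independently; fine-grid replicate maps are averaged
  cell-wise.
- Diagnostics: leave-one-predictor-out refits reporting ΔAUC, and
  marginal response curves with the other predictors at background means.

## Distance to niche centroid

Centroid μ = presence column means; Σ = presence sample covariance
(denominator n−1). If Σ is ill-conditioned (condition number > 1e8) a
ridge `1e−6·diag(Σ)` is added. Distances use a Cholesky solve (verified
against explicit inversion to 1e−8, and against the χ²_p law of d² under
the fitted Gaussian). Suitability is `1 − d/d_max` with d_max taken over
the projection area — distances enter AUC only through ranks, so the
rescaling convention affects none of the validation, but it anchors the
intercepts of the wedge regressions near zero, matching how positively
oriented DNC outputs behave. DNC uses the same 10× replicate scheme as
the Maxent-style model, with covariance estimated per training split.

## Validation and agreement

- **AUC**: Mann–Whitney rank form, `P(score_presence > score_background)
  + ½ P(tie)`, computed per replicate on held-out presences against a
  fresh bias-weighted background draw of 10,000 (in presence-only
  validation the background is the only available contrast class);
  reported as mean (SD) over replicates.
- **Weighted kappa**: maps are cut into k = 4 quantile categories (ties
  at a break go to the lower class); disagreement weights
  `w_ij = |i−j|/(k−1)` (linear; quadratic available), κ_w = 1 − ΣwO/ΣwE.
  The 95% CI uses the large-sample (Fleiss–Cohen–Everitt) standard error,
  cross-checked against a bootstrap in the tests. Which weighting and CI
  method the emulated protocol used is unstated; linear weights and the
  analytic SE are declared defaults, not inferences.

## Capture rate and wedge regression

- **Independence filter**: per (species, station) stream in time order, a
  detection counts iff ≥ 24 h after the last *counted* detection, or it
  is a multi-animal photograph (counted once regardless of timing).
  Counted events — including multi-animal ones — reset the clock; this is
  the only convention under which the filter is idempotent, which it must
  be for the event table to be a fixed point of its own definition.
  The multi-animal clause contributes one extra event, not one per
  individual (the minimal reading of the rule).
- **Capture rate**: counted events per cell divided by pooled camera-days
  in that cell. Cells with effort and no events are genuine zeros; cells
  without effort are excluded from the regression entirely (no effort ≠
  zero abundance).
- **Quantile regression** at τ ∈ {0.60, 0.70, 0.80, 0.85, 0.90, 0.91,
  0.93, 0.95, 0.97, 0.99} of rate on replicate-averaged suitability,
  solved exactly as an LP (HiGHS, sparse constraints). Each fit records
  `R1(τ) = 1 − V_full/V_intercept-only` (pinball losses; the intercept-only
  optimum is itself solved as an LP so the two losses are exactly
  comparable) and the subgradient optimality bounds (≤ nτ points strictly
  below the line, ≤ n(1−τ) strictly above), which are asserted in tests
  on every fit.
- **Quantile selection**: among positive-slope fits, maximize R1; fits
  within ΔR1 < 0.005 of the best are tie-broken by larger slope, then
  smaller |intercept|. If no slope is positive the max-R1 fit is returned
  flagged "no positive wedge". The 0.005 tie width quantifies an
  otherwise qualitative "higher R1 and slope, intercept close to 0" rule.

## Numerical choices and degenerate inputs

- Cells are half-open squares `[x0, x0+w) × [y0, y0+h)`, 0-based
  row-major ids; edge points belong to the cell whose low corner they
  touch.
- Seed fan-out: `SeedSequence([master, crc32(stage_name)])`, so every
  stage is reproducible in isolation and end-to-end runs are bit-identical
  for a fixed config.
- Constant maps yield a single kappa category (with a warning); constant
  environments yield suitability ≡ 1 from DNC (with a warning); all-x-equal
  wedge inputs and sub-minimum sample sizes raise errors rather than
  guessing.
- Problem sizes in tests and the acceptance script (e.g. 1000-cell wedge
  recovery over 20 seeds, 10-seed flat-scenario AUC bands, 200 LP-oracle
  instances) are chosen to make the checks statistically decisive at desk
  scale; the defaults in `ScenarioConfig`/`PipelineParams` are the study
  conditions themselves.

## Known limitations

- The Maxent variant implements linear/quadratic/product features only —
  no hinge or threshold features and no automatic feature-class selection,
  so very sharp true response curves will be approximated smoothly.
- The TSA accessible area is a cubic in coordinates; it cannot represent
  disjoint or highly convoluted calibration regions.
- The analytic kappa CI is asymptotic; for very small maps prefer the
  bootstrap.
- Capture-rate indices assume detection rate ∝ abundance with a constant
  of proportionality shared across stations; the generator honours that
  assumption, real cameras often do not.
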