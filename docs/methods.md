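# Methods

## The prediction problem

After an intracerebral hemorrhage, the hematoma may keep growing during the
first day; growth beyond a clinical threshold ("hematoma expansion") is
strongly associated with neurological deterioration. `hemexpand` treats the
hematoma volume as a *non-stationary Gaussian process in its marginals*:

    V(t) ~ N(M(t), Sigma(t)),

with a time-varying expected volume `M(t)` (ml) and variance `Sigma(t)`
(ml²). The clinically relevant event is a threshold crossing inside a
prediction window `[t0, t0 + T]`:

    c = max(v0 + 12.5, 1.33 · v0),

i.e. an absolute increase of ≥ 12.5 ml or a relative increase of ≥ 33% over
the baseline volume `v0`, whichever bites first.

## Crossing probability

The instantaneous exceedance probability

    beta(t) = P(V(t) ≥ c) = Phi_bar((c − M(t)) / sqrt(Sigma(t)))

is treated as the hazard of a time-inhomogeneous Poisson process, giving

    P = 1 − exp( − Σ_i beta(t_i) · Δt )

on a uniform grid of left endpoints (left Riemann sum; a trapezoid variant
with a closing rectangle on the final half-open interval is available for
convergence studies). `beta` is a probability while the exponent treats it
as a rate — the identification only makes sense with a fixed time unit. We
fix **hours** as the canonical unit: all grids, horizons and hazards are per
hour, and the numbers would change under a different unit. The Gaussian
tail is evaluated through the complementary error function, not quadrature,
so extreme thresholds (z ≈ 30) remain accurate; quadrature survives only as
a test oracle.

Degenerate variances below 1e−12 ml² are rejected rather than clamped: a
collapsed variance head upstream should fail loudly, not silently produce a
step-function hazard.

A Monte-Carlo oracle draws, per path, one Bernoulli event per subinterval
with probability `beta(t_i)·Δt` — the locally stationary interval picture
behind the Poisson derivation — and estimates `P(any event)` with a binomial
standard error. The Poisson exponent and the Bernoulli product differ at
second order in `beta·Δt`, so oracle-agreement checks use fine grids
(Δt ≈ 0.01–0.02 h with hazards ≤ 0.05/h) where that bias is far below the
Monte-Carlo error. `beta·Δt > 1` raises an error instructing a finer grid.

## The sequence model

The personalized maps from a patient's clinical sequence to `M_j(t)` and
`Sigma_j(t)` are realized by one shared multi-scale kernel Transformer
(MSKT) trunk with two output heads (a configuration flag switches to fully
separate trunks):

1. **Embedding.** A per-time-step affine map from the d standardized
   features to d′ = 32 dimensions. The bias is initialized from N(0, 1)
   rather than zero: every kernel in the bank below is *even* under a global
   sign flip of centred embeddings (inner products and distances are), so a
   zero-bias model literally cannot distinguish a patient from their
   sign-mirrored twin, and linear (odd) feature effects would be
   unidentifiable.
2. **Multi-scale kernel bank.** Gram matrices of the embedded time steps
   under linear, polynomial (degree 2, offset 1), RBF and Matérn (ν = 1.5)
   kernels, stacked to N×T×T. RBF/Matérn lengthscales default to the median
   pairwise distance of the training embedding. The kernel families live on
   wildly different numeric ranges (polynomial entries can reach hundreds,
   Matérn stays in (0,1]); each Gram matrix is multiplied by a scalar fitted
   on the training embedding (1/SD of its entries) so the projection sees
   commensurate inputs. A per-sample normalization (e.g. LayerNorm over the
   profile) would instead subtract exactly the patient-level information the
   similarity profiles carry, so a *constant* rescaling is used.
3. **Sequence fusion.** For each time step, the N kernel rows indexed by
   that step (its multi-scale similarity profiles) are concatenated together
   with the embedded step itself and affinely projected to d″ = 64, then
   sinusoidal position codes are added. The skip path matters: a pure
   similarity-profile representation can express a *fixed* linear functional
   of the step only along the single direction bᵀW, which measurably
   bottlenecked parameter recovery.
4. **Transformer encoder.** Two blocks of multi-head self-attention
   (H = 4 heads, key dimension 16), a feed-forward net (width 128), dropout
   0.1, and `E = LayerNorm(F + A)`. The block input enters attention with a
   residual (`attended = x + MHA(x)`): without it, softmax weights near
   uniform at initialization average per-step identity away and the mean
   path cannot track step-level covariates.
5. **Heads.** An affine point-prediction head on the time-pooled encoding;
   a mean head producing `M(t)`; a variance head through
   `softplus(·) + 1e−6` for strict positivity. Targets are standardized
   internally (fitted location/scale on training volumes) and mapped back to
   ml on output.

## Training

The loss is the negative log-likelihood `−Σ log(L + δ)` of observed volumes
under `N(M(t), Sigma(t))` (δ = 1e−6 keeps underflowed densities finite; the
published likelihood formula contains an obvious exponent typo which we read
as the standard Gaussian density), averaged over observed grid points, plus
a small (weight 0.1) squared-error term tying the point head to each
patient's last observed volume. Optimization is minibatch gradient descent
— plain SGD by default, momentum and Adam behind config flags — with early
stopping on validation NLL (best weights restored), optional k-fold
cross-validation, and an optional plateau-triggered learning-rate decay
(×0.5 after 20 stale epochs).

Heteroscedastic NLL training has a well-known failure mode: the variance
head inflates early to explain residuals, which shrinks the mean gradients
(∝ residual/variance) and stalls the mean fit at an inflated-variance
equilibrium. The trainer therefore supports a *warm-up phase*
(`warmup_epochs`) during which the likelihood is evaluated at fixed unit
variance — squared-error fitting of the mean — before the full NLL takes
over. The desk-scale recovery run uses 150 warm-up epochs out of at most
450, Adam at 5e−3, batch 32; this configuration was frozen before being
used in acceptance checks.

All gradients come from a small reverse-mode automatic-differentiation core
(`hemexpand.autodiff`) written directly on NumPy arrays; analytic gradients
of the full model agree with central finite differences to ~1e−8 relative
error (tested).

## Synthetic cohort

The generator emulates the structure of a credentialed ICU database extract
so every stage is testable offline. Defaults are the package's study
conditions: 947 patients, 28 features, 72 h records at 1 h sampling, a
24 h prediction/labeling window, and expansion prevalence 0.32.

* **Features.** 6 demographic/admission variables (gender, age ~ N(62, 13),
  admission type, insurance, marital status, language), 8 vitals (AR(1)
  series with patient-random circadian phase), 10 labs including the
  coagulation panel PT/INR/aPTT, and 4 medication flags (one contiguous
  administration window when used). Hourly missingness rates span all three
  imputation tiers by design (vitals ~2–5%, most labs 4–15%, fibrinogen 30%
  so the drop path is exercised).
* **Truth.** Baseline volume v0 ~ LogNormal(2.9, 0.5) (median ≈ 18 ml).
  The mean path is driven by the standardized INR and systolic-pressure
  series — coagulopathy and hypertension being the canonical clinical
  drivers of hematoma growth. Two functional forms: `smooth` (default), a
  saturating growth trend `v0 + softplus(a0 + 0.9·z̄_INR + 0.6·z̄_SBP)·(1 −
  e^{−t/12}) + 2·z_INR(t) + 2·z_SBP(t)` with log-linear patient variance;
  and `linear`, `v0 + mu0 + 6·z_INR(t) + 5·z_SBP(t)` with known constant
  variance (4 ml², noise SD 2 ml) — the identifiable setting used for
  parameter recovery. The free intercept is calibrated by root finding so
  the analytic label probability averages to the requested prevalence.
* **Labels.** Realized volumes are independent Gaussian draws at each grid
  point; the label marks any draw in the 24 h window reaching the
  expansion threshold. Everything is bitwise reproducible under the seed.
* **Noise injection** perturbs continuous feature values only (truth,
  labels and missingness masks untouched), rebuilding the event table under
  the same masks — the input for the robustness (RNH) evaluation.

What the generator does *not* emulate: correlated volume increments (draws
are independent across hours), real lab panel cadences (labs here are
near-hourly with thinning; real coagulation panels are far sparser),
imaging features, medication pharmacology, and coded-diagnosis semantics.
Passing tests therefore demonstrate that the machinery recovers known
structure under realistic dimensionality, missingness and outliers — not
clinical validity on real ICU data, which requires the credentialed source.

## Preprocessing

Order of operations: hourly resampling (last observation per half-open bin,
presence flags for medications) → one-hot encoding → hard physiologic-range
removal (e.g. systolic BP > 300 mmHg) → winsorization (values beyond 3
training SDs pulled to the training 2.5th/97.5th percentiles) →
missing-rate-tiered imputation. Missing rates are computed *after* removal,
since removal creates missingness. Tiers: < 5% median (continuous) or mode
(categorical, imputed as a whole category so one-indicator-per-row
survives); 5–20% patient-level KNN; > 20% dropped unless whitelisted
(empty default — clinical importance is a user judgement; whitelisted
features go through the KNN path).

KNN semantics: patient vectors are per-patient means of standardized
complete (< 5%-missing) continuous features; the K = 5 nearest *training*
patients supply the value — nanmean of their same-hour observations,
falling back to their overall means, then the training median. All
statistics are fitted on the training split and frozen; the fitted
transform is idempotent and fully audited (CSV log, JSON state).

The model additionally receives the baseline volume v0 as a static input
column: the admission CT volume is a known clinical predictor, and the
growth target is not identifiable without it.

## Evaluation

95% intervals use the multiplier 1.96 exactly (not the 0.975 quantile
1.959964...) for bit-agreement with the conventional interval formulas:
coverage is the fraction of realized values inside `ŷ ± 1.96σ`, width the
mean of `2·1.96·σ`. RNH (rate of noise-induced error change) is the mean
relative change of signed prediction errors after feature-noise injection;
pairs with baseline error below 1e−8 are excluded and counted. The ROC AUC
is the rank-based Mann-Whitney statistic with average ranks (ties at half
weight); `sklearn` serves only as a cross-check oracle in tests.
Confusion-matrix rates with zero denominators are reported as `None`,
never as zero. Classification uses `P_j ≥ 0.5` by default (configurable).

## Parameter recovery: what is checked and why

On the identifiable 500-patient cohort (fixed seeds), training must (i)
reduce the training NLL from initialization, (ii) recover the true mean
path with RMSE ≤ 1.5× the noise SD, and (iii) discriminate expansion labels
with AUC ≥ 0.80 using the crossing probability. The frozen run measures
RMSE ≈ 2.6 ml (budget 3.0) and AUC ≈ 0.97.

Predictive *variance* is checked as calibration, not as recovery of the
generator constant: an honest predictive variance equals the noise variance
plus the model's own mean error (≈ 4 + RMSE² ml²), so at any mean RMSE
above ~1 ml it must exceed the generator value — even an ordinary ridge
regression on the same imputed inputs lands ~90% above it. The suite
asserts that the median predicted variance is within 30% of the achievable
target (true variance + realized mean-path MSE) and never undercuts the
true noise floor.

## Numerical choices and limitations

* Everything is float64; forward/backward passes are deterministic given
  seeds (dropout streams re-seeded from the training seed).
* `P = 1 − exp(−cumhaz)` uses `expm1` for small hazards.
* The fitted kernel scales and lengthscales are constants of the fitted
  model and are stored in checkpoints.
* Sequence length is fixed at construction (the kernel-profile projection
  ties weights to T); variable-length stays are handled upstream by the
  resampling window.
* Training cost is CPU-bound Python/NumPy; desk-scale (500 patients × 24
  steps, ~450 epochs) fits in a few minutes. The problem sizes used in the
  tests — 500-patient recovery, 60-patient pipeline fixtures, 100k-draw
  calibration and Monte-Carlo checks — were chosen so the whole suite runs
  comfortably on one CPU.
* The per-interval independence assumption means the crossing probability
  ignores serial correlation of volume draws; with positively correlated
  increments the same marginals would imply a lower crossing probability.
  This is intrinsic to the hazard formulation, not an implementation choice.
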