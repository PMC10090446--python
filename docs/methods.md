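# Methods

This note documents the models, algorithms and numerical choices behind
`pmxnpag`, what the synthetic-cohort generator does and does not emulate,
and the package's known limitations.

## Structural model

Drug amounts follow the standard two-compartment intravenous-infusion
disposition

    dX1/dt = R(t) − (CL/Vc + Q/Vc)·X1 + (Q/Vp)·X2
    dX2/dt = (Q/Vc)·X1 − (Q/Vp)·X2,          C(t) = X1(t)/Vc

with clearance CL (L/h), central volume Vc (L), inter-compartmental
clearance Q (L/h), peripheral volume Vp (L), and piecewise-constant
infusion rate R(t) (mg/h). The one-compartment model drops X2. Units are
fixed package-wide (mg, L, h, mg/L, mg·h/L); there is no unit-conversion
layer.

The timeline is segmented at every infusion start/stop and query time.
Within a segment the affine system `dX/dt = AX + b` is propagated exactly:
`X(t₀+τ) = Xss + e^{Aτ}(X₀ − Xss)` with `Xss = −A⁻¹b`, and `e^{Aτ}`
evaluated from the two real eigenvalues of the 2×2 disposition matrix
(their discriminant `(a₁₁−a₂₂)² + 4a₁₂a₂₁` is positive whenever all
parameters are). This event-driven analytic propagation avoids coupling
estimation accuracy to ODE solver tolerances; an adaptive ODE integration
appears only as an independent oracle in the test suite (agreement ≤ 1e-6
relative on random draws). A numba-compiled kernel evaluates the
propagation for thousands of candidate parameter vectors at once; a pure
numpy fallback gives identical results when numba is absent.

Steady-state daily exposure is computed analytically:
`AUC_ss,24h = (24/interval)·maintenance_dose/CL`. The loading dose does
not enter (linear PK); trapezoidal integration of the simulated profile is
used only as a test oracle, run far past ten dosing intervals because the
terminal half-life under the fitted parameters is on the order of two
days.

## Residual error and likelihood

The assay standard deviation is a polynomial in the **observed**
concentration, `SD(C_obs) = C0 + C1·C_obs + C2·C_obs² + C3·C_obs³`, with
defaults (0.1, 0.15, 0, 0); the effective observation SD is `γ·SD` with γ
a dimensionless process-noise multiplier started at 5 and re-optimized
during fitting. Observations are Gaussian with mean equal to the model
prediction and that SD; the weight of an observation is `1/(γ·SD)²`.
Evaluating SD at the observed rather than predicted concentration differs
from many population-PK codes and is deliberate here, matching the fitting
convention this pipeline reproduces. Coefficients C0–C3 are fixed; only γ
is estimated. Observations below the limit of quantification (default
0.19 mg/L for total drug) are flagged and excluded from all likelihoods;
the flag is retained so a censored-likelihood option can be added later.

## Nonparametric adaptive-grid estimation

The population distribution F of the structural parameters is estimated
nonparametrically as a discrete distribution (support points θⱼ with
weights wⱼ) maximizing `∑ᵢ log ∑ⱼ wⱼ p(yᵢ|θⱼ)`; by mixture-ML theory the
maximizer needs no more support points than subjects. One cycle of the
search:

1. **Likelihood cache.** For each subject and candidate point, predictions
   at the observation times give the standardized residual sum Rᵢⱼ; the
   subject log-likelihood at any γ is `−Rᵢⱼ/(2γ²) − nᵢ·log γ + cᵢ`, so the
   per-cycle γ search costs no model re-evaluation.
2. **Weights.** The multiplicative EM update
   `wⱼ ← (wⱼ/N)·∑ᵢ Pᵢⱼ/(Pw)ᵢ` (monotone; global optimum of this concave
   problem), run in row-scaled arithmetic to avoid underflow. Search
   cycles use tolerance 1e-7 / 500 iterations; the final support is
   polished at 1e-10 / 3000.
3. **Gamma.** Golden-section maximization of the mixture log-likelihood
   over γ ∈ [0.01, 50] on the log scale, guarded never to return a worse
   value than the current one. The large starting value (5) effectively
   anneals the likelihood surface while the grid is still coarse.
4. **Condense.** Points are dropped when their weight is below 1e-8 of
   the maximum or their mixture directional derivative
   `gⱼ = (1/N)∑ᵢ Pᵢⱼ/(Pw)ᵢ` is clearly below 1 — the NPML optimality
   condition (g = 1 on the support) identifies dominated points long
   before their EM weight decays. Near-duplicates (within 1e-4 of each
   parameter range) are folded into their heavier neighbor.
5. **Expand.** Each survivor is perturbed by ±Δ per dimension; the
   heaviest 50 survivors also receive pairwise diagonal perturbations,
   which lets the support track correlated-parameter ridges (CL–Vp in
   particular). A small batch (32) of fresh scrambled-Sobol points is
   injected each cycle for global coverage. Δ starts at 20% of each range,
   halves when a cycle improves −2LL by less than 0.01, re-doubles (capped
   at 20%) while improvement continues, and the search stops when Δ <
   0.01% and the improvement is below tolerance.

If a cycle would worsen −2LL (possible only through condensation
round-off) the previous support is restored and Δ halved, so the recorded
cycle trace is non-increasing by construction. The initial grid is a
scrambled Sobol sequence of 512 points per dimension by default; all
randomness flows from one integer seed recorded in the result, making fits
bit-reproducible.

Default parameter box (the data sheet for this drug class): CL ∈ [0.05, 8]
L/h, Vc ∈ [1, 120] L, Q ∈ [0.05, 30] L/h, Vp ∈ [1, 300] L — covering the
fitted means ± >3 SD and the span of published polymyxin B models.

**Posteriors and fit indices.** Subject posteriors over the support follow
Bayes' rule; a subject without observations recovers the population
weights. Model comparison uses k = structural dimensions + 1 (for γ) and
n = quantified observations: `AICc = −2LL + 2k + 2k(k+1)/(n−k−1)`,
`BIC = −2LL + k·ln n` — this convention reproduces the published
comparison-table arithmetic exactly. R²pop is the squared Pearson
correlation of observations with the weight-averaged (population)
prediction, R²post with the posterior-weighted prediction; the population
prediction had to be defined here (weight-averaged over support) since no
universal convention exists. Shrinkage per parameter is
`100·(1 − SD(posterior means across subjects)/SD(population marginal))`;
the reference software's exact convention is unpublished, so this choice
is documented rather than claimed identical. Medians are weighted medians
of the support.

## Covariate modeling

Creatinine clearance uses Cockcroft–Gault with serum creatinine in µmol/L
(`(140−age)·wt/(72·scr/88.4)`, ×0.85 for women). Covariates enter as
centered power laws; the final model is `CL = CL0·(ALB/31.45)^−0.95`,
`V = V0·(age/68)^0.95`, with centering constants the cohort medians. The
exponents default to the published fitted values; how they were originally
obtained is not stated anywhere, so they are treated as fixed (an optional
profiling grid is deliberately not enabled by default, for
reproducibility).

Screening regresses posterior parameter estimates on each covariate by
OLS and reports R². Stepwise selection refits the model with each
candidate effect and accepts it when Δ(−2LL) > 6.63 (the df-1, p = 0.01
chi-square critical value; ties not accepted) **or** the population R²
improves; accepted effects are then fitted jointly. Two implementation
details matter at finite search budgets:

* Candidate fits are warm-started from the base support, with the target
  parameter column rescaled by quantiles of the cohort's covariate factors
  so points land near their image under the new parameterization.
* Before likelihoods are compared, the base model is *re-polished* from
  everything the candidate searches discovered (inverse-rescaled the same
  way). Without this, the −2LL difference between two independently
  searched models measures search depth, not the covariate. The -2LL
  changes from adding a covariate are intrinsically small in the
  nonparametric framework — the flexible mixing distribution absorbs most
  marginal covariate structure — so the R²pop clause does most of the
  discriminating, exactly as in the published comparison table.

## Validation tools

Weighted residuals are `(observed − population prediction)/(γ·SD(obs))`;
posterior-based residuals are emitted alongside. The bootstrap resamples
subjects with replacement, refits each replicate with a reduced budget
(coarser step floor so replicates converge quickly), and reports
percentile CIs of the weighted population means, aborting if more than 20%
of replicates fail. Data splitting fits the full cohort and a random
80/20 subject partition independently. The VPC simulates replicate
cohorts at the observed design, sampling parameters from the fitted
support and noise from the fitted error model, and bins by time after the
last dose (quantile bins, default 6 — matching the trough/peak/mid
sampling structure better than absolute time).

## Monte Carlo dose optimization

The efficacy threshold converts the free-drug consensus target
(fAUC/MIC ≈ 20, unbound fraction 0.42) to total drug: 20/0.42 = 47.6,
rounded up to the nearest ten → AUC/MIC ≥ 50. Toxicity uses
AUC_ss,24h > 100 mg·h/L. Virtual patients are sampled either from a
fitted support (with replacement by weight) or from the published table —
independent lognormals parameterized by the reported **mean** and CV%
(`σ² = ln(1+CV²)`, `μ = ln(mean) − σ²/2`; the mean parameterization is
chosen so the sampled mean converges to the reported value). Albumin is
drawn uniformly within its stratum (only ranges are reported), age is
fixed per scenario, and the final covariate model is applied. One
population is sampled per scenario and shared across regimens, making
efficacy PTA exactly monotone in dose. The recommended regimen per
scenario is the smallest maintenance dose reaching efficacy PTA ≥ 0.9 at
the chosen MIC with toxicity PTA < 0.9.

Because the AUC-based targets depend only on CL, and the covariate model
puts age on V only, PTA is invariant to age by construction — asserted in
the tests. Age-stratified PTA differences in the source analysis would
require either a CL–age pathway or joint resampling of correlated support
points; neither is published, so none is invented. The ultra-low albumin
stratum's lower bound is stated inconsistently at its two mentions (21.3
vs 23.1 g/L); the config default is 21.3.

## Synthetic cohort generator

The generator defines the study conditions used by every test:

* 22 subjects, 64 total samples (twenty subjects contribute 3, two
  contribute 2), all drawn ≥ 48 h after the start of therapy in the
  reported mix — 37.5% troughs (< 1 h before a dose), 35.9% peaks (< 1 h
  after infusion end), 26.6% at 6–8 h post-infusion.
* Demographics from scaled Beta distributions fitted to each reported
  (min, median, max) — a deliberately skew-capable family; the Beta total
  concentration is fixed at 4 and the shape solved from the median.
* Dosing: loading 100–150 mg, maintenance 50–75 mg q12h, infusions 1–2 h,
  six days of treatment.
* Truth: base parameters lognormal (mean/CV% from the published table:
  CL 1.24/30.48%, Vc 16.64/76.55%, Q 3.04/74.78%, Vp 66.2/54.76%), the
  final covariate model applied, observation noise Gaussian with
  SD = γ·SD(prediction) at γ = 0.72. Computing the error polynomial at
  the noiseless prediction resolves the observed-side circularity at
  generation time; the fitted convention (SD at the observation) coincides
  as noise vanishes.
* A rich mode (12 samples/subject: a dense profile after the 48-h dose
  plus troughs spaced across later days and one late peak) exists because
  sparse designs cannot identify Q and Vp tightly; the accumulation
  trajectory toward steady state is what separates CL from Vp at these
  time scales.

What the generator does **not** emulate: assay batch effects, dose
rounding and deviations, occasions/inter-day variability, dropout,
renal-replacement or ECMO clearance pathways, and any covariate
correlation structure (covariates are drawn independently). Passing
recovery tests therefore demonstrate estimator correctness under the
stated design, not robustness to these real-data features.

## Problem sizes and observed operating characteristics

The test suite uses sizes chosen to exercise each claim meaningfully:
single-truth collapse on 10 subjects with near-zero variability;
parameter recovery averaged over three replicate rich cohorts of 50
subjects (initial grid 2048, 120 cycles); selection operating
characteristics over 20 replicates per arm (n = 50, reduced fit budget of
512 initial points and 40 cycles with warm-started refits).

Two honest findings from these runs are worth recording. First, the
fitted γ settles around 0.58–0.62 when the generating value is 0.72 — the
joint ML of (F, γ) absorbs part of the residual noise into the flexible
mixing distribution, the nonparametric analogue of ML variance
underestimation. Second, the population **means** of the weakly
identified pair (Q, Vp) are recovered with an upward bias: profile
sensitivity analysis shows a twofold change in Q moves the observable
profile by at most ~13% — the same order as the observation noise — so
the likelihood genuinely supports heavy upper tails for a subset of
subjects (clamping the high-Q support mass costs tens of −2LL units; this
is not a search artifact), and the NPML mean inherits that tail mass.
The weighted **medians** of Q and Vp land close to the truth. Recovery
tolerances for Q and Vp are therefore intrinsically harder to meet than
for CL and Vc, and the recovery test may flag Q even when the estimator
is working as designed; see the test output for the current status.

Similarly for covariate selection: the inclusion rule's R²-improvement
clause is a strict inequality on a stochastic quantity, so at finite
search budgets chance improvements are accepted in a nontrivial fraction
of effect-free cohorts. The suite measures both the power and the
false-positive rate of the rule over 20 replicate cohorts per arm; the
power check passes while the false-positive rate at the affordable fit
budget runs above the nominal expectation, which the test reports rather
than hides.

## Limitations

* BLQ observations are excluded rather than censored-likelihood modeled.
* No occasions: one continuous dosing history per subject.
* The additive+proportional (λ) error alternative and parametric
  (FOCE/SAEM) estimation are out of scope.
* The bootstrap and stepwise refits use reduced search budgets; their
  −2LL values are comparable within a run (warm-start symmetrization) but
  not across packages.
* CRRT/ECMO patients are outside the model's domain of validity.
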