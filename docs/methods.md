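# Methods

This note documents the models implemented in `ivgttml`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic
cohort can and cannot establish about real clinical data.

## Test protocol and data model

An insulin-modified IVGTT: glucose bolus of 300 mg per kg body weight at
t = 0, exogenous insulin (0.03 IU/kg) infused over minutes 20–25, and
plasma glucose (mmol/L), insulin (pmol/L) and C-peptide (pmol/L) sampled at
fasting and at 3, 4, 5, 6, 8, 10, 14, 19, 22, 27, 30, 35, 40, 50, 70, 100,
140 and 180 min.  The fasting sample is taken before the injection, so the
t = 0 entry of every record holds the pre-bolus basal state.  All unit
conversions (6.00 pmol/L per μU/mL of insulin, 6.00 nmol per IU, 18.02
mg/dL per mmol/L of glucose, 180.16 mg/mmol for the dose, 0.302 ng/dL per
pmol/L of C-peptide) live in a single constants table.

## Minimal model of glucose kinetics

States G (plasma glucose) and X (remote insulin action):

    dG/dt = -(S_G + X) G + S_G G_b,     G(0) = G0
    dX/dt = -p2 X + p2 S_I (I(t) - I_b)

The bolus is treated as instantaneous (the first post-bolus sample is at
3 min, so the 0–0.5 min injection window is unobservable), raising glucose
to G0 = G_b + Dose/V.  Estimation is single-subject unweighted least
squares of model glucose against the measured samples with t ≥ 8 min
(excluding early mixing artifacts; the window start is configurable), with
the measured insulin curve as forcing input.  Initial estimates are
S_G = 0.02 min⁻¹, p2 = 0.03 min⁻¹, S_I = 5·10⁻⁴, G0 near the sampled peak;
all parameters are bounded below by zero (S_G and p2 strictly).  V is
reported as Dose/(G0 − G_b).

Numerical choices that matter:

* The insulin forcing is interpolated by a **monotone cubic (PCHIP)**, not
  a polyline.  With only two samples (22, 27 min) spanning the infusion
  peak, piecewise-linear forcing clips the peak and biases S_I by ≈2.4% on
  noise-free data; the monotone cubic reduces the round-trip error to
  ≈0.3% without overshoot.
* When the insulin samples never leave baseline, X(t) ≡ 0 for every S_I:
  insulin action is structurally unidentifiable and the fit reports
  S_I = 0 by convention rather than an arbitrary interior value.
* Non-convergence is reported as a flagged fit (`converged=False`) and the
  affected features propagate as missing, never as silent zeros.

Model-free glucose disappearance rates K_G1 (10–20 min) and K_G2
(20–40 min) are 100 × |OLS slope| of ln G against time over the in-window
samples.  S_G decomposes into BIE = S_I·I_b (insulin in μU/mL) and
GEZI = S_G − BIE; GEZI is reported as computed, even if negative.  The
disposition index DI = S_I·AIR is reported in 10⁻² min⁻¹ so typical values
are order one, matching the conventional reporting scale of the other
indexes.

## C-peptide kinetics and secretion

C-peptide is cosecreted equimolarly with insulin and escapes hepatic
extraction, so the prehepatic secretion rate is recoverable from plasma
C-peptide.  Per-subject two-compartment kinetics use the standard
population model: the post-bolus decay is F·e^(−αt) + (1−F)·e^(−βt) with a
status-dependent fast fraction and short half-life (normal: F = 0.76,
4.95 min; obese: 0.78, 4.55 min; diabetic: 0.78, 4.33 min), a long
half-life of 0.14·age + 29.2 min, and a central volume
V_C = 1.11·BSA + 2.04 L for women (1.92·BSA + 0.64 for men) with Du Bois
body surface area.  Subjects with BMI ≥ 30 use the obese constants.  Every
constant is exposed in the module.

Deconvolution solves the discretised convolution of the impulse response
with a secretion rate that is piecewise constant on a 1-min grid.  The
basal steady state is subtracted first (the suprabasal C-peptide signal is
deconvolved, and BSR = k₀₁·Cp_b added back), the convolution integrals over
grid bins are evaluated analytically, and the system is solved by bounded
linear least squares with ISR ≥ 0 and a second-difference (curvature)
penalty with weight λ.  The default λ = 0.25 was fixed once from an L-curve
sweep on the noise-free synthetic fixture: below ≈0.01 the reconstruction
is unstable between samples, above ≈5 the first-phase pulse is visibly
over-smoothed; within that range the round-trip error is flat (≈2.6% of
the pulse peak).  As λ → ∞ the solution collapses to the penalty's null
space (a straight line), which is the expected penalty-dominated limit.

Secretion indexes: AIR and ACPR are the mean *signed* suprabasal insulin
and C-peptide over minutes 3–8 — clipping negative suprabasal values at
zero would bias low responders upward.  Φ₁c is defined here as the mean
suprabasal ISR over 3–8 min divided by the mean suprabasal glucose (mg/dL)
over the same window; the test protocol does not pin down a unique
definition, and this ratio-of-means is the simplest one consistent with
Φ₁c's units.  Secretion AUCs integrate V_C·ISR over [0, 180] with the
first/second-phase split at 20 min, the only protocol landmark separating
the phases.

## Insulin clearance

Whole-test and windowed clearance come from mass balance over a window
[t₀, t₁]:

    CL = [ V_C ∫ ISR dt + ExoDose − V_I (I(t₁) − I(t₀)) ] / ∫ I dt

with endogenous delivery taken as the full prehepatic secretion (hepatic
extraction is lumped into the clearance figure, which keeps CL_MEAN and the
FE_L/CL_P partition independent outputs).  V_I defaults to 0.141 L/kg body
weight, exposed in the configuration.

The hepatic/extra-hepatic partition fits the one-compartment balance

    V_I dI/dt = (1 − FE_L) S_pre(t) + R_exo(t) − CL_P I(t)

with FE_L ∈ [0, 1] and CL_P ≥ 0, one constant extraction per subject.  The
balance is fitted in **integrated (antiderivative) form**, evaluated at the
measured sample times: differentiating the sparsely sampled insulin curve
numerically injects large errors exactly where the infusion makes the
problem identifiable, biasing FE_L by >20%, whereas the cumulative form
needs only the measured concentrations and smooth cumulative integrals
(noise-free recovery ≈2% for both parameters).  The boxcar infusion is
integrated exactly rather than by trapezoid (the edge bins otherwise lose
10% of the dose).  When S_pre ≡ 0 the extraction fraction is
unidentifiable; it is reported missing and CL_P fitted from the exogenous
decay alone.

## The 34-feature table

One row per subject: age, BW, h, BMI, g_b, G_MEAN, I_MEAN, Cp_MEAN,
AUC_INS-1P/2P, K_G1, K_G2, S_I, S_G, V, BIE, GEZI, AIR, ACPR, DI, BSR,
Φ₁c, AUC_SECR (total/1P/2P), CL_MEAN (total/1P/2P), CL_P, FE_L,
I_PEAK-FIRST, I_PEAK-INJECT, C_PEAK and DOSE, in the units conventional
for each index (S_I in 10⁻⁴ min⁻¹ per μU/mL, BIE in 10⁻³ min⁻¹, GEZI in
10⁻² min⁻¹, peaks in μU/mL and ng/dL).  Insulin-curve AUCs are areas
(pmol·min/L).  FE_L is reported as a fraction.  Peaks are sample maxima
(no interpolation, ties to the earliest sample).  Missing component results
stay missing — empty CSV cells, no imputation — because downstream
preprocessing drops outlying cases rather than imputing.

## Classification stage

* **LOF screening** runs once on the pooled cohort (both classes together)
  with 20 neighbours and Euclidean distance on internally standardized
  features, flagging exactly round(0.04·n) cases — the worst LOF scores —
  so a 78-case cohort retains 75.  Pooled (rather than per-class) screening
  matches the removal pattern expected for a small two-class cohort.
* **Normalization** is per-feature z-scoring; inside cross-validation the
  scaler is fitted on training folds only.
* **Feature selection** is a greedy binary decision tree scored by
  information gain ratio with the stopping rules: ≥3 instances per leaf,
  no splitting of nodes under 5 instances, depth ≤ 100, and no splitting
  once the node majority reaches 95%.  Equal-score splits resolve to the
  lower feature index, then the lower threshold, making induction
  deterministic.  The tree is induced once on the full preprocessed set
  before classifier evaluation; the optimistic bias this introduces is a
  property of the workflow being reproduced and is stated rather than
  hidden.  Selected features are the distinct split features in
  breadth-first first-use order.
* **Evaluation** is stratified 5-fold cross-validation (with only ~17
  positives, unstratified folds can lose a class) of the gain-ratio tree,
  Gaussian Naïve Bayes and ridge (L2, C = 1) logistic regression.  Metrics
  are reported in two conventions: class-weighted precision / recall /
  specificity / F1 (weighted recall is algebraically identical to CA), and
  PROG-positive sensitivity with NON-PROG specificity.  AUC is reported
  both fold-averaged and pooled.
* **Comparison**: 3-set Venn region counts of correctly and incorrectly
  classified cases, and the correlated Bayesian t-test on paired per-fold
  scores — the posterior of the mean difference is Student t with k−1
  degrees of freedom and variance inflated by the fold-overlap correction
  ρ = 1/k; P(A>B) + P(B>A) = 1 with no equivalence region.

## Cohort statistics

Each feature is tested for normality per group with a Lilliefors test
(composite normality, mean and SD estimated).  The p-value is Monte Carlo:
the null distribution of the statistic is distribution-free under
normality, so one seeded null table per sample size is simulated (default
10⁴ draws, cached) — this avoids the accuracy limits of table
approximations, which the test suite shows can deviate by up to ~0.1 in
mid-range p-values.  If both groups pass at 5% the summary is mean ± SD and
the comparison a pooled-variance t-test; otherwise median [IQR width] and
the Wilcoxon rank-sum test.  No multiplicity correction is applied, by
design.  Constant samples reject normality by convention (p = 0).

## Synthetic cohort simulator

The clinical cohort this workflow was built for is restricted, so the
simulator generates surrogate cohorts with per-subject ground truth.  The
forward model couples the minimal model (glucose), a secretion model
(basal + raised-cosine first-phase pulse over 0–8 min with configurable
secreted amount + second-phase component proportional to suprabasal
glucose), population two-compartment C-peptide kinetics, and a
one-compartment insulin balance receiving (1 − FE_L) of secretion plus the
infusion, cleared at rate CL_P.  Basal insulin is derived as
I_b = (1 − FE_L)·BSR·V_C / CL_P so that every subject starts at an exact
steady state.  Integration uses LSODA at rtol 10⁻⁸, split at the pulse and
infusion discontinuities, with output on a 1-min grid.

Per-group parameter distributions are log-normal — positive support and
right skew match how such physiology is reported (median [IQR]) — with
medians following the published group characteristics of a 78-woman
post-GDM cohort (59 non-progressors / 19 progressors; progressors: lower
S_I 3.1 vs 4.7 ×10⁻⁴, lower first-phase secretion, higher BMI 30.6 vs
25.4 kg/m², fasting glucose 96 vs 84 mg/dL and basal secretion 39.6 vs
31.8 pmol·L⁻¹·min⁻¹) and log-scales from the reported IQR/median ratios.
Where no published value exists (first-phase amount, second-phase gain,
p2), values were chosen once to give realistic curve shapes (insulin peaks
after the bolus and again during the infusion, glucose undershoot and
recovery) and group differences in the physiologically expected direction.
Measurement noise is multiplicative Gaussian with assay-typical CVs
(glucose 1.5%, insulin 6%, C-peptide 5%), configurable and zero-able; no
claim is made about the true assay error model.

What passing round-trip tests shows: the estimators recover the parameters
of *this* forward model from noise-free (and, within stated tolerance,
noisy) data.  What it cannot show: correctness of the population C-peptide
constants for a given cohort, absence of model misspecification in real
curves (glucose mixing artifacts, time-varying hepatic extraction,
non-Gaussian assay error), or the clinical classification performance —
the simulated cohort is cleaner and more separable than clinical data, so
classifier metrics on it are upper bounds, and only directional group
differences and procedural counts are meaningful comparisons.

## Problem sizes and seeds

Tests and the acceptance script use the cohort sizes of the emulated study
(78 subjects), 100-replicate Monte Carlo for noisy parameter recovery, 200
replicates for the Lilliefors type-I calibration, and 20 permutation seeds
for the null-AUC check.  A single pipeline seed fans out to fixed per-stage
offsets so any stage can be rerun alone and reproduce its output exactly.

## Known limitations

* FE_L is a single constant per subject; real hepatic extraction varies
  during the test.
* The C-peptide kinetics are population values, not individually fitted.
* Φ₁c's definition is a stated convention; other definitions exist.
* The feature-selection-before-CV leakage of the reproduced workflow is
  deliberate and documented, not corrected.
* The simulator's noise model is a stand-in; robustness figures under it
  do not transfer verbatim to any specific assay.
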