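# ivgttml

Kinetic feature extraction from insulin-modified intravenous glucose
tolerance tests (IM-IVGTT) and machine-learning classification of
progression from gestational diabetes (GDM) to type 2 diabetes (T2DM).

Women with prior GDM carry a markedly elevated risk of developing T2DM.
A frequently sampled IM-IVGTT — a 300 mg/kg glucose bolus at t = 0, a
0.03 IU/kg insulin infusion over minutes 20–25, and plasma glucose, insulin
and C-peptide sampled at fasting and 18 times out to 180 min — contains far
more physiological information than any single biomarker, but that
information has to be extracted by mechanistic modelling.  This package
implements the full analysis chain for researchers in metabolic physiology
and biostatistics:

1. **Minimal model of glucose kinetics** — insulin sensitivity *S*_I,
   glucose effectiveness *S*_G and distribution volume *V* from

   d*G*/dt = −(*S*_G + *X*)·*G* + *S*_G·*G*_b,  
   d*X*/dt = −p₂·*X* + p₂·*S*_I·(*I*(t) − *I*_b),

   with the measured insulin curve as forcing input, plus the model-free
   disappearance rates *K*_G1/*K*_G2 and the *S*_G split into the basal
   insulin effect (BIE = *S*_I·*I*_b) and glucose effectiveness at zero
   insulin (GEZI = *S*_G − BIE).
2. **Insulin secretion by C-peptide deconvolution** — ISR(t) reconstructed
   through population two-compartment C-peptide kinetics by regularised
   non-negative deconvolution; yields the basal secretion rate
   BSR = k₀₁·Cp_b, β-cell responsivity Φ₁c, the acute insulin/C-peptide
   responses (AIR/ACPR, mean suprabasal concentration over 3–8 min), the
   disposition index DI = *S*_I·AIR and phase-resolved secretion AUCs.
3. **Insulin clearance** — windowed mass-balance clearance (CL_MEAN and its
   first/second-phase components) and the partition of insulin removal into
   hepatic fractional extraction FE_L and extra-hepatic clearance CL_P from
   the one-compartment balance
   *V*_I·d*I*/dt = (1 − FE_L)·S_pre(t) + R_exo(t) − CL_P·*I*(t).
4. **A 34-feature table per subject** (anthropometrics, curve statistics and
   all model indexes, in conventional units) and the downstream analysis:
   local-outlier-factor screening (20 neighbours, Euclidean, 4%
   contamination), z-score normalisation, feature selection by a binary
   gain-ratio decision tree, and stratified 5-fold cross-validation of the
   tree, Gaussian Naïve Bayes and L2 logistic regression with AUC, CA,
   precision, sensitivity, specificity and F1, Venn comparisons and the
   correlated Bayesian t-test.
5. **A mechanistic cohort simulator** that generates IM-IVGTT cohorts with
   known per-subject physiology (progressors drawn with lower insulin
   sensitivity and first-phase secretion, higher BMI, fasting glucose and
   basal secretion), so every estimator can be validated by round-trip
   against ground truth.

## Worked example

```python
from ivgttml import SimulationConfig, sample_cohort, simulate_ivgtt, extract_features

config = SimulationConfig(
    noise_cv={"glucose": 0.0, "insulin": 0.0, "cpeptide": 0.0}, seed=1
)
subject = sample_cohort(config)[0]          # known ground-truth physiology
record = simulate_ivgtt(subject, config)    # noise-free IM-IVGTT curves
features = extract_features(record)         # the 34-feature vector
for name in ("S_I", "S_G", "V", "AIR", "DI", "BSR", "FE_L", "CL_P", "DOSE"):
    print(f"{name:6s} {features[name]:8.3f}")
```

prints

```
S_I       6.953
S_G       0.024
V        12.877
AIR     129.568
DI        1.501
BSR      34.542
FE_L      0.598
CL_P      0.269
DOSE     22.699
```

i.e. an insulin sensitivity of 6.95 × 10⁻⁴ min⁻¹ per μU·mL⁻¹ (this
subject's true value is 6.94), a glucose distribution volume of 12.9 L, a
basal secretion rate of 34.5 pmol·L⁻¹·min⁻¹, a hepatic extraction of 0.60
(true 0.59) and an extra-hepatic clearance of 0.27 L/min (true 0.27) — the
noise-free extraction recovers the simulator's ground truth.

The full pipeline (simulate → extract → outlier filter → feature selection →
cross-validated classification → group statistics) runs from the shell:

```bash
ivgttml run-all --seed 3 --out run/
```

and writes `features.csv`, `flagged_outliers.csv`, `selected_features.json`,
`metrics.csv`, `pairwise.csv`, `venn.json` and `summary.csv` into `run/`.

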