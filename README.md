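# pmxnpag

Nonparametric population pharmacokinetics and Monte Carlo dose
optimization for intravenous **polymyxin B** in critically ill patients.

Polymyxin B is a last-line antibiotic against carbapenem-resistant
Gram-negative bacteria. In intensive-care patients its clearance (CL) and
volume of distribution (V) are altered — hypoalbuminemia raises the free
fraction of this highly protein-bound drug and with it the clearance of
total drug, while age shifts the central volume — so fixed label dosing
misses the therapeutic window in both directions. This package implements
the full analysis pipeline such a study needs:

* **Structural model** — one- and two-compartment intravenous-infusion
  models, `dX1/dt = R(t) − (CL/Vc + Q/Vc)X1 + (Q/Vp)X2`,
  `dX2/dt = (Q/Vc)X1 − (Q/Vp)X2`, solved analytically segment-by-segment
  (matrix-exponential eigendecomposition per infusion interval, no ODE
  solver).
* **Residual error** — multiplicative polynomial model
  `SD(C_obs) = C0 + C1·C_obs + C2·C_obs² + C3·C_obs³`, scaled by a fitted
  process-noise multiplier γ.
* **Population estimation** — nonparametric adaptive-grid (NPAG) maximum
  likelihood: the population distribution is a discrete set of support
  points with weights, found by alternating EM weight optimization,
  gradient-based support condensation, and local/diagonal grid expansion,
  with γ re-optimized each cycle by golden-section search.
* **Covariate models** — centered power laws
  `CL = CL0·(ALB/31.45)^−0.95`, `V = V0·(age/68)^0.95`, screened by OLS
  regression on posterior estimates and selected stepwise by the
  Δ(−2LL) > 6.63 (χ², df 1, p < 0.01) **or** R²pop-improvement rule.
* **Validation** — goodness-of-fit tables with weighted residuals,
  nonparametric bootstrap, random 80/20 data splitting, and a visual
  predictive check.
* **Dosing simulation** — Monte Carlo probability of target attainment
  (PTA) over maintenance regimens 100/75/60/50/40 mg q12h, MICs
  0.25–4 mg/L, albumin strata and patient ages, with efficacy target
  AUC<sub>ss,24h</sub>/MIC ≥ 50 (from fAUC/MIC ≈ 20 at 42% unbound) and
  toxicity limit AUC<sub>ss,24h</sub> > 100 mg·h/L. For linear PK,
  AUC<sub>ss,24h</sub> = daily dose / CL.
* **Synthetic cohorts** — a generator emulating the sparse steady-state
  ICU sampling design (22 subjects, 64 samples: 37.5% troughs, 35.9%
  peaks, 26.6% samples 6–8 h post-infusion) with known ground truth, so
  every stage of the pipeline is testable end to end.

## Worked example

```python
from pmxnpag import (PublishedModel, Scenario, Regimen, PdTargets,
                     sample_virtual_population, pta_efficacy, pta_toxicity)

model = PublishedModel()          # fitted population table + covariate model
scen = Scenario(35.0, 41.5, 68.0) # normal albumin, median age
pop = sample_virtual_population(model, scen, n=1000, seed=20230329)
print(pta_efficacy(pop, Regimen(60.0), PdTargets(), [0.25, 0.5, 1, 2, 4]))
print(pta_toxicity(pop, Regimen(100.0), PdTargets()))
```

prints

```
0.25    1.000
0.50    1.000
1.00    0.997
2.00    0.749
4.00    0.060
Name: pta_efficacy, dtype: float64
0.993
```

— at 60 mg q12h a patient with normal albumin and median age attains the
efficacy exposure target with probability ≥ 0.9 for MICs up to 1 mg/L but
not at 2 mg/L, while 100 mg q12h pushes ~99% of such patients past the
nephrotoxicity exposure limit.

The full study workflow runs from the command line on synthetic data:

```bash
pmxnpag simulate --out-dir out        # cohort.csv + ground truth
pmxnpag fit --out-dir out             # NPAG base fit
pmxnpag covariates --out-dir out      # stepwise selection + final fit
pmxnpag validate --out-dir out        # GOF, bootstrap, 80/20 split, VPC
pmxnpag pta --out-dir out             # PTA table + dose recommendations
```

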