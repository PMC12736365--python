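# fludapk — population pharmacokinetics of fludarabine lymphodepletion

Fludarabine + cyclophosphamide lymphodepletion conditions patients for CAR
T-cell therapy, and fludarabine exposure (cumulative AUC) is linked to both
CAR-T expansion and toxicity. `fludapk` reimplements a population
pharmacokinetic analysis of fludarabine in adults receiving axi-cel or
tisa-cel as a reusable, tested pipeline: structural model, covariate
equations, population simulation, nonlinear mixed-effects estimation,
diagnostics, and AUC-targeted dose individualization. It is aimed at
pharmacometricians and clinical-pharmacy researchers who want to simulate,
re-estimate or extend the model without NONMEM.

The study data are not public, so a synthetic-cohort generator reproduces the
published study design (56 adults, three daily 30-min infusions, limited
sampling at 1.5/2/(7)/24 h on days 1 and 3 plus a pre-infusion sample,
LLOQ 1 ng/mL) and every pipeline stage is validated against it.

## Model

Serum F-ara-A follows a three-compartment model with zero-order infusion
input and first-order elimination. The final covariate model is

    CL   = [θ_CART + θ_CRCL · CRCL/96] · (WGT/70)^¾ · exp(η_CL)
    V1   = θ_V1 · (WGT/70) · exp(η_V1)      V2, V3 ∝ WGT/70
    CLD2, CLD3 ∝ (WGT/70)^¾

with θ_CART = 4.4 L/h (axi-cel) or 3.9 L/h (tisa-cel), θ_CRCL = 1.7 L/h at
the 96 mL/min reference creatinine clearance, volumes 41.2/14.5/10.8 L and
distributional clearances 4.8/3.6 L/h at 70 kg. Between-subject variability
is bivariate log-normal on (CL, V1) (CV 29.8%/34.8%, correlation 0.9);
residual error is additive on log-concentration (SD 0.29). See
`docs/methods.md` for assumptions, numerics and limitations.

## Worked example

```python
from fludapk import (ThetaVector, Covariates, RegimenSpec, individual_params,
                     bsa, build_regimen, concentration, auc)

theta = ThetaVector()                       # published estimates
cov = Covariates(wgt=70, crcl=96, cart="axi-cel")
p = individual_params(theta, cov)           # typical patient
print(p.cl, p.v1)                           # 6.1 L/h, 41.2 L

regimen = build_regimen(RegimenSpec(product="axi-cel"), bsa(175, 70), egfr=96)
print(round(regimen[0].amount, 2))          # 43.25 mg F-ara-A per day
print(round(concentration(p, regimen, 1.5), 1))   # 713.5 ng/mL at 1.5 h
print(round(auc(p, regimen, 0, float("inf")), 2)) # 21.27 mg·h/L cumulative
```

The typical reference patient clears 6.1 L/h (axi-cel; 5.6 with tisa-cel,
whose lower non-renal clearance reflects its lower-dose regimen population);
three BSA-dosed infusions yield a cumulative AUC of about 21.3 mg·h/L, and
concentrations at the first sampling time sit around 700 ng/mL, well inside
the 1–1000 ng/mL assay range.

## Analysis pipeline

Numbered drivers under `analysis/` run the full study replica and write
tables under `results/`:

| script | what it does |
|---|---|
| `01_simulate_cohort.py` | virtual cohort + limited-sampling study dataset (CSV) |
| `02_fit_model.py` | re-estimate the model (Laplace/FOCE) from perturbed starts |
| `03_diagnostics.py` | GOF table (PRED/IPRED/IWRES/CWRES) and 1000-replicate pcVPC |
| `04_covariate_impact.py` | typical profiles across weight/CRCL percentiles and products |
| `05_dose_individualization.py` | closed-loop MAP-guided dosing vs fixed BSA dosing |

For example, `python analysis/05_dose_individualization.py` prints

    n=200, target cumulative AUC 20.0 mg*h/L
    fixed BSA dosing : mean AUC 19.2, CV 32%
    MAP-guided dosing: mean AUC 20.1, CV 8%

i.e. estimating each subject's clearance from day-1 samples and re-dosing
days 2–3 toward the target cuts the between-patient exposure spread about
four-fold, and `04_covariate_impact.py` shows pre-infusion troughs rising
~3.5-fold from the 90th to the 10th creatinine-clearance percentile under
fixed dosing — the accumulation pattern that motivates renal dose
adjustment.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch: the typical clearances implied by the covariate
model; the median V1/V2/V3 and η-correlation recovered by the implemented
estimator from three replicate 56-subject cohorts simulated under the
published design; and the objective-function penalty for dropping the renal
clearance covariate on one of those cohorts. Runtime is dominated by the
four population fits (several minutes on one CPU).
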