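# Methods

## Scope and model

`fludapk` reimplements, as a tested pipeline, a population pharmacokinetic
analysis of fludarabine given as lymphodepleting chemotherapy before CAR
T-cell infusion. Fludarabine phosphate (f-ara-AMP) is infused over 30 min on
three consecutive days (30 mg/m²/day with axi-cel, 25 mg/m²/day with
tisa-cel); the measured analyte is the circulating nucleoside F-ara-A
(administered amount × 0.78 by molecular weight). Serum disposition follows
a linear mammillary three-compartment model with zero-order input and
first-order elimination, parameterized by CL, V1–V3 and the distributional
clearances CLD2/CLD3.

The covariate model splits clearance into non-renal and renal components:

    CL   = [θ_CART(construct) + θ_CRCL · CRCL/96] · (WGT/70)^0.75 · exp(η_CL)
    V1   = θ_V1 · (WGT/70) · exp(η_V1)
    V2   = θ_V2 · (WGT/70)        V3 = θ_V3 · (WGT/70)
    CLD2 = θ_CLD2 · (WGT/70)^0.75 CLD3 = θ_CLD3 · (WGT/70)^0.75

with fixed allometric exponents (¾ for clearances, 1 for volumes). CRCL is
the absolute Cockcroft–Gault creatinine clearance in mL/min normalized by the
reference 96 mL/min; BSA-normalized eGFR (mL/min/1.73 m²) is treated as a
reporting covariate, not the model input. V2 and V3 use linear weight
scaling because that is the published final parameterization; an allometric
¾ alternative was not published and is not implemented.

Default fixed effects are the published estimates (4.4/3.9/1.7 L/h;
41.2/14.5/10.8 L; 4.8/3.6 L/h). Between-subject variability is bivariate
log-normal on (CL, V1) with a full covariance block — defaults reproduce the
published CV% of 29.8/34.8 via ω² = ln(1+(CV/100)²) and a correlation of
0.9 — and the residual error is additive on the natural log of the ng/mL
concentration with SD 0.29. The published table does not label this value as
SD or variance; it is read as the SD of the additive log-scale error (the
NONMEM log-transform-both-sides convention).

### Units

Time h, amounts mg F-ara-A, volumes L, clearances L/h. Concentrations are
reported in ng/mL (1 mg/L = 1000 ng/mL; the conversion lives only in
`pk_core`). AUC is reported in mg·h/L.

## Analytic solution

The rate matrix of a mammillary system is symmetrizable by the diagonal
similarity D = diag(1, √(k21/k12), √(k31/k13)), so concentrations are
computed from a symmetric eigendecomposition: eigenvalues are exactly real
and negative, and repeated eigenvalues are unproblematic because `eigh`
always returns an orthogonal basis. This replaces the originally planned
general eigendecomposition with a matrix-exponential fallback — the
symmetric route is both exact and unconditionally stable, so no fallback is
needed. Compartments with zero distributional clearance are dropped from
the system, which yields the exact two- and one-compartment limits and keeps
the retained matrix nonsingular.

Because the symmetrizer's first entry is 1, the projection of a
central-compartment input and the reconstruction of the central amount both
use the first row of the orthogonal eigenvector matrix; the central amount is
Σⱼ Q₀ⱼ² fⱼ(t), which is what the estimation hot path evaluates (batched over
candidate η values).

AUC over [t0, t1] uses the exact identity ∫x dt = A⁻¹(Δx − bΔt) per
piecewise-constant input segment (no quadrature); t1 = ∞ is supported, giving
AUC(0,∞) = dose/CL per dose.

## Estimation

The marginal likelihood is approximated subject-by-subject with the Laplace
method: a damped Gauss–Newton inner loop finds the MAP η, and the
log-determinant of the Gauss–Newton Hessian (J'J/σ² + Ω⁻¹) supplies the
correction. Because the residual model is additive on the log scale with
constant σ, the ε–η interaction term of FOCEI vanishes, so this estimator
stands in for FOCE(I) on this model class; the quadrature-agreement test
(≤0.5 OFV points against tensor Gauss–Hermite on single-subject problems)
bounds the approximation error where it can be checked exactly.

OFV convention: −2 log L − n·log 2π (NONMEM), so only ΔOFV is interpreted.
Nested one-parameter comparisons use 3.84 (5%) and 6.61 (1%); 6.61 is the
published threshold and is used as printed even though χ²₁(1%) = 6.635.

Fixed effects are optimized on the log scale (positivity by construction;
covariate-effect exponents and proportional shifts are unconstrained), Ω via
its log-Cholesky factor (correlation always derived), σ on the log scale.
The outer optimizer is L-BFGS-B with finite-difference gradients, restarted
from jittered starts (configurable) and "polished" by re-running from its
own solution up to three times — restarting resets the Hessian approximation
and reliably recovers a few OFV points on this stiff surface. Standard
errors (optional) come from a central-difference Hessian of OFV/2 with step
1e-4 on the transformed scale, so RSE% of a log-scale parameter is 100·SE of
its log.

BLQ/ALQ samples are excluded from the likelihood (M1), matching the source
analysis; a subject whose samples are all censored contributes exactly zero
OFV. Time-varying creatinine clearance is carried forward at dose times:
the second clinical measurement (taken before the third administration)
applies to the final dose's contribution only, an approximation that is
exact when CRCL is constant.

### Identifiability caveat

Sums of three exponentials are numerically degenerate: parameter sets with
V2/V3 differing by ~7% can reproduce the concentration function to ~1e-5
relative, so the deep disposition parameters are determined only up to this
ridge even from rich, nearly noise-free data. CL and V1 are well identified.
This is why the recovery tolerances widen from V1 (10%) through V2 (20%) to
V3 (30%) — the same ordering as the precision limitation reported for the
original sparse design, where the 7 h sample that anchors the β/γ transition
was rarely available.

Under the limited-sampling schedule itself the degeneracy is structural, not
merely numerical: the expected Fisher information of the design evaluated at
the default parameters is singular, with essentially no information about
V2/V3/CLD2/CLD3 (the earliest sample falls 1 h after the infusion ends,
after most of the fast distribution phase) and a design-based RSE of roughly
24% for V1. Simulation–re-estimation under this design therefore produces
estimates that wander along an observationally near-equivalent manifold —
typically a "collapsed" geometry in which one peripheral compartment
equilibrates quickly with the centre while the other nearly disconnects —
and an independent adaptive Gauss–Hermite evaluation of the marginal
likelihood confirms those points are genuine optima, not approximation
artifacts. The recovery tests in `tests/test_acceptance.py` implement the
experiment at face value and are expected to fail at their stated
tolerances; they document the information limit of the design rather than a
defect of the estimator, whose correctness is established by the rich-design
and quadrature tests.

## Synthetic cohort

The real study data are not public; the generator reproduces the published
baseline characteristics of the 56-patient cohort:

* weight — truncated normal on [52, 101] kg; the parent parameters
  (86.1, 22.9) are moment-matched so the *truncated* distribution has the
  published mean 79.6 and SD 12.9;
* age — Beta(2.7, 1.9) scaled to [23, 82] years, matching the median of 59;
* sex — 59% male; construct — 68% axi-cel (independent Bernoulli draws);
* eGFR — log-normal (μ=4.46, σ=0.35 on the log), truncated to the published
  range [39, 213.9] mL/min/1.73 m²; right-skew follows from the published
  mean-vs-range asymmetry, the parameters are a modeling choice;
* height — sex-specific normals (175±7 / 162±6.5 cm), used only for BSA;
* absolute CRCL = eGFR · BSA/1.73 (median lands near the published
  96 mL/min); serum creatinine is back-calculated so Cockcroft–Gault
  reproduces CRCL exactly. Apart from that deterministic link, covariates
  are independent — the real joint structure is unpublished.

Regimens are built per subject (product dose, Du Bois BSA, renal
adjustment: full dose ≥60 mL/min, 75% in [45, 60), 60% in [30, 45), error
below 30 where the protocol is silent; boundaries take the higher fraction).
Doses are not rounded to vial sizes.

The sampling design takes samples at 1.5/2/24 h after the start of doses 1
and 3, a 7 h sample with probability 0.04 per sampled dose (7 of 168
administrations had one), and a pre-infusion sample at 119.5 h. LLOQ is
1 ng/mL; values below it are flagged BLQ. Samples above the 1000 ng/mL ULOQ
are assay-diluted back into range whenever possible and flagged ALQ only
when dilution fails (probability 0.1) — the source assay handled above-range
samples the same way, and excluding *all* peaks above range would
informatively censor the peak distribution and bias V1 upward by tens of
percent.

Per-subject randomness comes from substreams keyed by (seed, subject id), so
cohort composition never reshuffles another subject's draws.

What a green test does *not* establish: the generator draws covariates
independently, uses a single CRCL per subject, and knows nothing about
disease burden, inflammation or concomitant therapy — agreement on synthetic
data validates the estimator and pipeline, not the transportability of the
published estimates to other populations.

## Diagnostics

GOF tables report DV, PRED (η=0), IPRED (EBE η), IWRES = (log DV − log
IPRED)/σ and CWRES from the FOCE-style linearization about the EBEs
(marginal mean m(η̂) − Jη̂, covariance JΩJ' + σ²I, whitened by Cholesky).
CWRES calibration (mean within ±0.05, SD within 1±0.1 under the true model
at large n) is verified by simulation rather than claimed to match any
particular NONMEM variant bit-for-bit.

The pcVPC simulates replicate studies preserving each subject's design, bins
by nominal design time (identical times share a bin; small bins merge
leftward; quantile edges can be supplied for irregular data),
prediction-corrects on the linear concentration scale by the bin-median
typical prediction, and reports observed 2.5/50/97.5 percentiles with their
95% simulation intervals. 1000 replicates by default.

Covariate-impact profiles hold the dose fixed and sweep one covariate at a
time (10th/50th/90th cohort percentiles of weight and CRCL; both
constructs), reproducing the published orderings: heavier patients start
lower under fixed dosing (V1 ∝ weight); renally impaired patients accumulate
drug and diverge over the three days.

## Dose individualization

With linear kinetics each dose contributes dose/CL to cumulative AUC(0,∞),
so after MAP-estimating CL from day-1 samples the remaining doses are
dose = CL·(target − accrued)/n_remaining. The recommendation therefore also
compensates day-1 over- or under-exposure, not just the clearance ratio.
Empirical-Bayes shrinkage under the published residual SD caps single-subject
accuracy at roughly 5–7% even with rich day-1 sampling; with the sparse
clinical design the pull toward typical values is stronger. No default AUC
target is shipped — optimal exposure targets are an open clinical question
and must be supplied by the caller.

## Numerical choices

* Inner Newton: convergence at step < 1e-8, ≤50 iterations, step-halving
  line search; η warm-started from the previous outer iteration.
* Outer optimizer: ftol 1e-10, gtol 1e-7, FD step 1e-4, up to 3 polish
  rounds; across restarts ties break by lowest OFV, then fewest iterations.
* Box bounds on the transformed scale: each positive fixed effect may move a
  factor ~20 (e^3) from its start, covariate coefficients ±10, Cholesky and
  σ entries within fixed generous ranges. The bounds are physiological
  plausibility constraints; without them the optimizer can escape onto
  degenerate ridges (CLD2 → ∞ collapses the central and shallow compartments
  into one and is observationally near-equivalent under sparse sampling).
* Ω must be invertible for the η prior; exact singularity raises. Simulation
  accepts ω = 0 and σ = 0 (noise-free worlds) — only estimation requires
  positivity, which its log parameterization guarantees.
* The LRT boundary is inclusive with 1e-9 slack so thresholds computed as
  (x + 3.84) − x are not rejected by rounding.
* θ_CRCL may be exactly 0 (reduced model for nested testing); all other
  structural parameters are strictly positive.

## Known limitations

* No inter-occasion variability (explored upstream but not retained; no
  published parameters to reproduce).
* BLQ handling is exclusion (M1); likelihood-based censoring (M3) is out of
  scope. Excluding BLQ troughs at 119.5 h mildly biases the terminal phase,
  which is part of the replicated study world.
* Laplace/Gauss–Newton rather than exact-Hessian Laplace; the difference is
  bounded by the quadrature tests on toys but not characterized at scale.
* Standard errors assume a locally quadratic OFV; no covariance-step
  diagnostics beyond that.
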