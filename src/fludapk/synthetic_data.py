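"""Virtual cohorts and study-design replicas.

The real study data (56 adults with relapsed/refractory large B-cell
lymphoma, sampled under a limited-sampling design during three-day
fludarabine lymphodepletion) are not public, so every pipeline stage is
exercised against synthetic cohorts that reproduce the published baseline
characteristics:

* weight: truncated normal, mean 79.6 kg, SD 12.9, range 52-101;
* age: scaled Beta on [23, 82] matched to the median of 59 years;
* sex: 59% male; CAR-T construct: 68% axi-cel;
* eGFR: log-normal (right-skewed, matching the published mean 90 and range
  39-213.9 mL/min/1.73 m2), truncated to that range;
* height: sex-specific normals, solely to exercise BSA dosing;
* serum creatinine: back-calculated so that the Cockcroft-Gault formula
  reproduces each subject's absolute creatinine clearance exactly.

Absolute creatinine clearance (the model covariate, median anchored near
96 mL/min) is the BSA-denormalized eGFR: CRCL = eGFR * BSA/1.73.  Covariates
are drawn independently apart from that deterministic link; the real joint
covariate structure is unpublished.

The sampling design takes samples at 1.5, 2 and 24 h after the start of
doses 1 and 3, an uncommonly available 7 h sample (inclusion probability
0.04 per sampled dose, matching 7 of 168 administrations), and one sample
30 min before the CAR-T infusion (119.5 h).  Assay limits: LLOQ 1 ng/mL,
ULOQ 1000 ng/mL.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .pk_core import AXI_CEL, TISA_CEL, Covariates, ThetaVector
from .population import (
    Dataset,
    RandomEffectsSpec,
    SubjectRecord,
    simulate_subject,
    subject_rng,
)
from .regimen import RegimenSpec, bsa, build_regimen

__all__ = ["CohortSpec", "DesignSpec", "generate_cohort", "generate_study"]


@dataclass(frozen=True)
class CohortSpec:
    """Marginal covariate distributions of the study population."""

    n: int = 56
    # parent-normal parameters moment-matched so that after truncation to the
    # published range the cohort reproduces the published mean 79.6 / SD 12.9
    weight_mean: float = 86.10
    weight_sd: float = 22.93
    weight_range: tuple[float, float] = (52.0, 101.0)
    age_range: tuple[float, float] = (23.0, 82.0)
    # Beta(2.7, 1.9) on the age range puts the median at ~59 years
    age_beta: tuple[float, float] = (2.7, 1.9)
    male_fraction: float = 0.59
    axicel_fraction: float = 0.68
    # log-normal eGFR: mu chosen so the truncated mean lands near 90
    egfr_mu: float = 4.46
    egfr_sigma: float = 0.35
    egfr_range: tuple[float, float] = (39.0, 213.9)
    height_male: tuple[float, float] = (175.0, 7.0)   # mean, SD cm
    height_female: tuple[float, float] = (162.0, 6.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        for name in ("weight_range", "age_range", "egfr_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} bounds must satisfy lo < hi, got ({lo}, {hi})")


@dataclass(frozen=True)
class DesignSpec:
    """Limited-sampling design replicated for each simulated subject."""

    dose_days: tuple[float, ...] = (0.0, 24.0, 48.0)
    sample_offsets: tuple[float, ...] = (1.5, 2.0, 24.0)
    sampled_doses: tuple[int, ...] = (0, 2)  # doses 1 and 3
    seven_hour_probability: float = 0.04
    pre_infusion_time: float = 119.5  # 30 min before CAR-T infusion at 120 h
    lloq: float = 1.0
    uloq: float = 1000.0
    # above-range samples are diluted back into range whenever possible and
    # excluded only when dilution is not; this is the fraction lost
    dilution_failure_probability: float = 0.1

    def __post_init__(self) -> None:
        if not all(t >= 0 for t in self.sample_offsets):
            raise ValueError("sample offsets must be non-negative")
        if not 0 <= self.seven_hour_probability <= 1:
            raise ValueError("seven_hour_probability must be in [0, 1]")
        if not 0 < self.lloq < self.uloq:
            raise ValueError("need 0 < LLOQ < ULOQ")

    def sampling_times(self, rng: np.random.Generator) -> np.ndarray:
        """Design sampling times for one subject (h after first dose start)."""
        times = []
        for d in self.sampled_doses:
            start = self.dose_days[d]
            times.extend(start + off for off in self.sample_offsets)
            if rng.random() < self.seven_hour_probability:
                times.append(start + 7.0)
        times.append(self.pre_infusion_time)
        return np.array(sorted(times))


def _truncated_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Draw a reproducible virtual cohort with regimens, no observations.

    Each subject's regimen comes from the regimen module using the drawn
    construct, Du Bois BSA and absolute creatinine clearance, so renal dose
    reductions arise naturally for low-clearance draws.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    weight = _truncated_normal(rng, spec.weight_mean, spec.weight_sd, *spec.weight_range, size=n)
    lo, hi = spec.age_range
    age = lo + (hi - lo) * rng.beta(*spec.age_beta, size=n)
    male = rng.random(n) < spec.male_fraction
    axicel = rng.random(n) < spec.axicel_fraction
    # log-normal eGFR truncated to the published range, via inverse-CDF
    log_lo = (np.log(spec.egfr_range[0]) - spec.egfr_mu) / spec.egfr_sigma
    log_hi = (np.log(spec.egfr_range[1]) - spec.egfr_mu) / spec.egfr_sigma
    u = rng.uniform(stats.norm.cdf(log_lo), stats.norm.cdf(log_hi), size=n)
    egfr = np.exp(spec.egfr_mu + spec.egfr_sigma * stats.norm.ppf(u))
    hm, hf = spec.height_male, spec.height_female
    height = np.where(male, rng.normal(hm[0], hm[1], n), rng.normal(hf[0], hf[1], n))

    subjects = []
    for i in range(n):
        sex = "male" if male[i] else "female"
        cart = AXI_CEL if axicel[i] else TISA_CEL
        bsa_i = bsa(float(height[i]), float(weight[i]))
        crcl = float(egfr[i] * bsa_i / 1.73)  # absolute mL/min
        # serum creatinine consistent with Cockcroft-Gault at this CRCL
        scr = (140.0 - age[i]) * weight[i] / (72.0 * crcl)
        if sex == "female":
            scr *= 0.85
        cov = Covariates(
            wgt=float(weight[i]),
            crcl=crcl,
            cart=cart,
            age=float(age[i]),
            sex=sex,
            height=float(height[i]),
            scr=float(scr),
        )
        regimen = build_regimen(RegimenSpec(product=cart), bsa_i, crcl)
        subjects.append(SubjectRecord(id=f"S{i + 1:03d}", covariates=cov, regimen=tuple(regimen)))
    return subjects


def generate_study(
    cohort: Sequence[SubjectRecord],
    design: DesignSpec,
    theta: ThetaVector,
    spec: RandomEffectsSpec,
    seed: int,
) -> Dataset:
    """Simulate the full study: design times, IIV, residual error, censoring.

    Per-subject randomness (sampling-time inclusion, etas, residuals) comes
    from a substream keyed by (seed, subject id), so the draws for one
    subject are independent of cohort composition.  Values below the LLOQ are
    kept but flagged; above-range samples are assay-diluted back into range
    whenever possible and flagged ALQ only when dilution fails.  Exclusion of
    flagged samples happens at estimation, mirroring the study's handling.
    """
    simulated = []
    for subject in cohort:
        rng = subject_rng(seed, subject.id)
        times = design.sampling_times(rng)
        sim = simulate_subject(theta, spec, subject, times, rng)
        flagged = []
        for o in sim.observations:
            blq = bool(o.blq or (np.isfinite(o.conc) and o.conc < design.lloq))
            alq = bool(
                np.isfinite(o.conc)
                and o.conc > design.uloq
                and rng.random() < design.dilution_failure_probability
            )
            flagged.append(replace(o, blq=blq, alq=alq))
        simulated.append(replace(sim, observations=tuple(flagged)))
    return Dataset(subjects=tuple(simulated))
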