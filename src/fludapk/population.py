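"""Between-subject variability model and forward simulation.

Interindividual variability (IIV) is log-normal on clearance and central
volume: the individual parameter is the typical value times exp(eta), with
(eta_CL, eta_V1) jointly normal with a full 2x2 covariance.  The published
model reports IIV as CV% = sqrt(exp(omega^2) - 1) * 100 with an eta_CL-eta_V1
correlation of 0.9, and an additive residual error of SD 0.29 on the natural
log of the ng/mL concentration (the log-transform-both-sides convention; the
published table does not label SD vs variance and SD is the NONMEM reading).

Reproducibility: each simulated subject draws from an independent substream
keyed by (seed, subject id), so adding or removing subjects never reshuffles
another subject's residuals.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .pk_core import Covariates, DoseEvent, ThetaVector, concentration, individual_params

__all__ = [
    "RandomEffectsSpec",
    "Observation",
    "SubjectRecord",
    "Dataset",
    "cv_percent",
    "sample_etas",
    "simulate_subject",
    "subject_rng",
]


def _default_omega() -> np.ndarray:
    # variances matching the published 29.8% / 34.8% CV and correlation 0.9
    w_cl = cv_percent(29.8, inverse=True)
    w_v1 = cv_percent(34.8, inverse=True)
    off = 0.9 * np.sqrt(w_cl * w_v1)
    return np.array([[w_cl, off], [off, w_v1]])


@dataclass(frozen=True)
class RandomEffectsSpec:
    """Covariance of (eta_CL, eta_V1) and the log-scale residual SD."""

    omega: np.ndarray = field(default_factory=_default_omega)
    sigma: float = 0.29  # SD of additive error on log(ng/mL)

    def __post_init__(self) -> None:
        om = np.asarray(self.omega, dtype=float)
        if om.shape != (2, 2):
            raise ValueError(f"omega must be 2x2, got shape {om.shape}")
        if not np.allclose(om, om.T):
            raise ValueError("omega must be symmetric")
        eigvals = np.linalg.eigvalsh(om)
        if eigvals.min() < -1e-10 * max(1.0, eigvals.max()):
            raise ValueError("omega must be positive semi-definite")
        object.__setattr__(self, "omega", om)
        # sigma = 0 is allowed for noise-free simulation; estimation keeps it
        # strictly positive through its log parameterization
        if not self.sigma >= 0:
            raise ValueError(f"sigma must be non-negative, got {self.sigma}")

    @property
    def correlation(self) -> float:
        denom = np.sqrt(self.omega[0, 0] * self.omega[1, 1])
        return float(self.omega[0, 1] / denom) if denom > 0 else 0.0


@dataclass(frozen=True)
class Observation:
    """One serum concentration sample; censored values keep the drawn value
    but are flagged so estimation can exclude them."""

    time: float
    conc: float  # ng/mL; nan when nothing is quantifiable
    blq: bool = False
    alq: bool = False

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"observation time must be >= 0, got {self.time}")
        if not (self.blq or self.alq) and not self.conc > 0:
            raise ValueError("non-censored observations need a positive concentration")

    @property
    def usable(self) -> bool:
        return not (self.blq or self.alq) and np.isfinite(self.conc)


@dataclass(frozen=True)
class SubjectRecord:
    """Covariates, dosing history and observations for one patient.

    ``crcl_day3`` optionally carries the second clinical creatinine-clearance
    measurement (taken before the third infusion); covariate time variation
    is handled as last-observation-carried-forward at dose times.
    """

    id: str
    covariates: Covariates
    regimen: tuple[DoseEvent, ...] = ()
    observations: tuple[Observation, ...] = ()
    crcl_day3: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "regimen", tuple(self.regimen))
        object.__setattr__(self, "observations", tuple(self.observations))

    def usable_observations(self) -> list[Observation]:
        return [o for o in self.observations if o.usable]


@dataclass(frozen=True)
class Dataset:
    """A study dataset: subjects with unique ids."""

    subjects: tuple[SubjectRecord, ...]

    def __post_init__(self) -> None:
        subjects = tuple(self.subjects)
        ids = [s.id for s in subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique within a dataset")
        object.__setattr__(self, "subjects", subjects)

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)


def cv_percent(value: float, inverse: bool = False) -> float:
    """Log-normal CV% from a variance omega^2, or (inverse) back again.

    forward: sqrt(exp(omega2) - 1) * 100; inverse: log(1 + (CV/100)^2).
    """
    if value < 0:
        raise ValueError(f"need a non-negative value, got {value}")
    if inverse:
        return float(np.log1p((value / 100.0) ** 2))
    return float(np.sqrt(np.expm1(value)) * 100.0)


def sample_etas(spec: RandomEffectsSpec, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """n mean-zero (eta_CL, eta_V1) pairs with covariance spec.omega."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not np.any(spec.omega):
        return np.zeros((n, 2))
    return rng.multivariate_normal(np.zeros(2), spec.omega, size=n, method="cholesky")


def subject_rng(seed: int, subject_id: str) -> np.random.Generator:
    """Independent, reproducible substream for one subject.

    Keyed by (seed, crc32(id)) so a subject's draws do not depend on cohort
    composition or ordering.
    """
    return np.random.default_rng([seed, zlib.crc32(subject_id.encode())])


def simulate_subject(
    theta: ThetaVector,
    spec: RandomEffectsSpec,
    subject: SubjectRecord,
    sampling_times: Sequence[float],
    seed: int | np.random.Generator,
    etas: tuple[float, float] | None = None,
) -> SubjectRecord:
    """Simulate observations for one subject at the given sampling times.

    Observed log-concentration = log(individual prediction) + eps with
    eps ~ N(0, sigma^2).  Times with a zero model prediction (e.g. before the
    first dose) come back flagged BLQ rather than log-transformed.  Pass
    ``etas`` to reuse externally drawn random effects; otherwise one pair is
    drawn from spec.omega.
    """
    rng = seed if isinstance(seed, np.random.Generator) else subject_rng(seed, subject.id)
    times = np.asarray(sampling_times, dtype=float)
    if len(subject.regimen) == 0 and times.size:
        import warnings

        warnings.warn(f"subject {subject.id}: no doses; all samples censored")
        obs = tuple(Observation(time=t, conc=float("nan"), blq=True) for t in times)
        return replace(subject, observations=obs)
    if etas is None:
        eta_cl, eta_v1 = sample_etas(spec, 1, rng)[0]
    else:
        eta_cl, eta_v1 = etas
    params = individual_params(theta, subject.covariates, eta_cl, eta_v1)
    pred = concentration(params, list(subject.regimen), times)
    eps = rng.normal(0.0, spec.sigma, size=times.size)
    observations = []
    for t, c, e in zip(times, np.atleast_1d(pred), eps):
        if c <= 0:
            observations.append(Observation(time=float(t), conc=float("nan"), blq=True))
        else:
            observations.append(Observation(time=float(t), conc=float(np.exp(np.log(c) + e))))
    return replace(subject, observations=tuple(observations))
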