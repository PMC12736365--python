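"""Lymphodepletion regimen construction and clinical covariate formulas.

Fludarabine phosphate (f-ara-AMP) is given as a 30-minute infusion on three
consecutive days before CAR T-cell infusion: 30 mg/m2/day with axi-cel and
25 mg/m2/day with tisa-cel (90 and 75 mg/m2 cumulative).  Doses are reduced
for impaired renal function per the treating centre's internal protocol, and
converted to F-ara-A equivalents (x0.78, the molecular weight ratio) because
the measured analyte is the circulating nucleoside.

Cyclophosphamide is co-administered but never modelled; it is carried only
as regimen metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .pk_core import AXI_CEL, TISA_CEL, DoseEvent

__all__ = [
    "RegimenSpec",
    "BelowProtocolRangeError",
    "fara_a_equivalent",
    "renal_adjustment_fraction",
    "bsa",
    "cockcroft_gault",
    "build_regimen",
]

#: f-ara-AMP -> F-ara-A molecular weight ratio
FARA_A_FRACTION = 0.78

#: mg/m2/day fludarabine phosphate by product
DOSE_PER_M2 = {AXI_CEL: 30.0, TISA_CEL: 25.0}

#: mg/m2/day cyclophosphamide by product (metadata only, never modelled)
CYCLOPHOSPHAMIDE_PER_M2 = {AXI_CEL: 500.0, TISA_CEL: 250.0}


class BelowProtocolRangeError(ValueError):
    """eGFR below 30 mL/min: the renal dose-reduction protocol is silent."""


@dataclass(frozen=True)
class RegimenSpec:
    """Product-specific three-day lymphodepletion schedule."""

    product: str
    dose_per_m2: float = 0.0  # mg/m2 f-ara-AMP; 0 -> product default
    n_days: int = 3
    day_times: tuple[float, ...] = (0.0, 24.0, 48.0)
    infusion_duration: float = 0.5

    def __post_init__(self) -> None:
        if self.product not in DOSE_PER_M2:
            raise ValueError(f"unknown product {self.product!r}")
        if self.dose_per_m2 == 0.0:
            object.__setattr__(self, "dose_per_m2", DOSE_PER_M2[self.product])
        if not self.dose_per_m2 > 0:
            raise ValueError("dose_per_m2 must be positive")
        if self.n_days != len(self.day_times):
            raise ValueError("day_times must have one entry per day")


def fara_a_equivalent(dose_amp: float) -> float:
    """Convert an f-ara-AMP dose (mg) to F-ara-A equivalents (mg): x0.78."""
    if dose_amp < 0:
        raise ValueError(f"dose must be non-negative, got {dose_amp}")
    return FARA_A_FRACTION * dose_amp


def renal_adjustment_fraction(egfr: float) -> float:
    """Fraction of the full fludarabine dose given at a measured eGFR (mL/min).

    Internal protocol: full dose at >= 60, 75% in [45, 60), 60% in [30, 45).
    At the interval boundaries the higher fraction applies.  Below 30 mL/min
    the protocol makes no recommendation and an error is raised.
    """
    if not egfr > 0:
        raise ValueError(f"eGFR must be positive, got {egfr}")
    if egfr >= 60:
        return 1.0
    if egfr >= 45:
        return 0.75
    if egfr >= 30:
        return 0.60
    raise BelowProtocolRangeError(
        f"eGFR {egfr} mL/min is below the 30 mL/min protocol floor"
    )


def bsa(height: float, weight: float, method: Literal["dubois", "mosteller"] = "dubois") -> float:
    """Body surface area (m2) from height (cm) and weight (kg).

    Du Bois by default (the usual oncology convention); Mosteller available.
    """
    if not (height > 0 and weight > 0):
        raise ValueError("height and weight must be positive")
    if method == "dubois":
        return 0.007184 * height**0.725 * weight**0.425
    if method == "mosteller":
        return float((height * weight / 3600.0) ** 0.5)
    raise ValueError(f"unknown BSA method {method!r}")


def cockcroft_gault(age: float, weight: float, scr: float, sex: str) -> float:
    """Cockcroft-Gault creatinine clearance (mL/min).

    (140 - age) * weight / (72 * serum creatinine), x0.85 for women; age in
    years, weight kg, serum creatinine mg/dL.
    """
    if not (age > 0 and weight > 0 and scr > 0):
        raise ValueError("age, weight and serum creatinine must be positive")
    if age >= 140:
        raise ValueError(f"age {age} outside the formula's domain")
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    crcl = (140.0 - age) * weight / (72.0 * scr)
    if sex == "female":
        crcl *= 0.85
    return crcl


def build_regimen(spec: RegimenSpec, bsa_m2: float, egfr: float) -> list[DoseEvent]:
    """Three daily F-ara-A infusions with BSA dosing and renal adjustment.

    Each dose is dose_per_m2 * BSA * renal fraction, converted to F-ara-A
    equivalents.  Amounts are exact (no vial rounding).
    """
    if not bsa_m2 > 0:
        raise ValueError(f"BSA must be positive, got {bsa_m2}")
    fraction = renal_adjustment_fraction(egfr)
    amount = fara_a_equivalent(spec.dose_per_m2 * bsa_m2 * fraction)
    return [
        DoseEvent(start_time=t, amount=amount, duration=spec.infusion_duration)
        for t in spec.day_times
    ]
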