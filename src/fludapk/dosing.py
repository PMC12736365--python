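"""Model-informed dose individualization for the remaining infusions.

With linear kinetics, each dose contributes dose/CL to the cumulative
AUC(0, inf), so once a subject's clearance has been estimated from early
(day-1) samples by MAP, hitting a cumulative-exposure target is a matter of
splitting the outstanding AUC evenly over the remaining doses:

    dose_i = CL_MAP * (target - accrued AUC) / n_remaining

No default AUC target is shipped; optimal exposure targets are an open
clinical question and the target is always supplied by the caller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .estimation import StructuralModel, map_estimate
from .pk_core import ThetaVector
from .population import RandomEffectsSpec, SubjectRecord

__all__ = ["DoseRecommendation", "dose_recommend"]


@dataclass(frozen=True)
class DoseRecommendation:
    """Per-dose F-ara-A amounts (mg) plus the exposure arithmetic behind them."""

    amounts: tuple[float, ...]
    map_cl: float                # L/h
    accrued_auc: float           # mg*h/L from doses already given
    predicted_cum_auc: float     # mg*h/L if the recommendation is followed
    based_on_typical: bool = False  # no observations: prior-mode CL used


def dose_recommend(
    subject: SubjectRecord,
    theta: ThetaVector,
    spec: RandomEffectsSpec,
    target_cum_auc: float,
    remaining_doses: int,
    model: StructuralModel | None = None,
) -> DoseRecommendation:
    """Recommend the remaining F-ara-A doses to hit a cumulative AUC target.

    The subject's clearance is MAP-estimated from the available observations
    (falling back, flagged, to the covariate-typical value when there are
    none); the already-administered doses contribute sum(amount)/CL to the
    eventual cumulative AUC and the shortfall is split evenly.
    """
    if not target_cum_auc > 0:
        raise ValueError(f"target AUC must be positive, got {target_cum_auc}")
    if remaining_doses < 1:
        raise ValueError(f"remaining_doses must be >= 1, got {remaining_doses}")
    eta, params = map_estimate(subject, theta, spec, model=model)
    based_on_typical = len(subject.usable_observations()) == 0
    cl = params.cl
    accrued = sum(d.amount for d in subject.regimen) / cl
    shortfall = target_cum_auc - accrued
    if shortfall <= 0:
        warnings.warn(
            f"subject {subject.id}: accrued AUC {accrued:.2f} already meets the "
            f"target {target_cum_auc:.2f}; recommending zero doses"
        )
        amounts = tuple(0.0 for _ in range(remaining_doses))
        return DoseRecommendation(amounts, cl, accrued, accrued, based_on_typical)
    per_dose = cl * shortfall / remaining_doses
    amounts = tuple(per_dose for _ in range(remaining_doses))
    predicted = accrued + sum(amounts) / cl
    return DoseRecommendation(amounts, cl, accrued, predicted, based_on_typical)
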