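"""Dataset CSV dialect (NONMEM-compatible column semantics) and run config.

Columns: ID, TIME (h since first infusion start), AMT (mg F-ara-A, dose rows
only), DUR (infusion h), DV (ng/mL), EVID (1 dose / 0 observation), MDV,
BLQ, ALQ, WT (kg), CRCL (mL/min, absolute), CART (1 axi-cel / 2 tisa-cel),
AGE, SEX (1 male / 2 female), HT (cm), SCR (mg/dL).

Time-varying creatinine clearance is carried on the dose rows: when the
second clinical measurement (taken before the third administration) differs
from baseline, the final dose row holds the updated CRCL and the reader
restores it as ``SubjectRecord.crcl_day3``.

An ``amt_is_prodrug`` switch on :func:`read_dataset` accepts f-ara-AMP
amounts and converts them (x0.78) at read time.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .pk_core import AXI_CEL, TISA_CEL, Covariates, DoseEvent
from .population import Dataset, Observation, SubjectRecord
from .regimen import FARA_A_FRACTION

__all__ = ["COLUMNS", "read_dataset", "write_dataset", "dataset_to_frame", "RunConfig"]

COLUMNS = [
    "ID", "TIME", "AMT", "DUR", "DV", "EVID", "MDV", "BLQ", "ALQ",
    "WT", "CRCL", "CART", "AGE", "SEX", "HT", "SCR",
]

_CART_CODE = {AXI_CEL: 1, TISA_CEL: 2}
_CART_NAME = {1: AXI_CEL, 2: TISA_CEL}
_SEX_CODE = {"male": 1, "female": 2, "": 0}
_SEX_NAME = {1: "male", 2: "female", 0: ""}


class DatasetSchemaError(ValueError):
    pass


def dataset_to_frame(dataset: Dataset) -> pd.DataFrame:
    rows: list[dict[str, Any]] = []
    for s in dataset:
        cov = s.covariates
        base = {
            "ID": s.id,
            "WT": cov.wgt,
            "CRCL": cov.crcl,
            "CART": _CART_CODE[cov.cart],
            "AGE": cov.age,
            "SEX": _SEX_CODE.get(cov.sex, 0),
            "HT": cov.height,
            "SCR": cov.scr,
        }
        doses = list(s.regimen)
        for i, d in enumerate(doses):
            row = dict(base)
            if s.crcl_day3 is not None and i == len(doses) - 1:
                row["CRCL"] = s.crcl_day3
            rows.append(
                {
                    **row,
                    "TIME": d.start_time,
                    "AMT": d.amount,
                    "DUR": d.duration,
                    "DV": np.nan,
                    "EVID": 1,
                    "MDV": 1,
                    "BLQ": 0,
                    "ALQ": 0,
                }
            )
        for o in s.observations:
            rows.append(
                {
                    **base,
                    "TIME": o.time,
                    "AMT": np.nan,
                    "DUR": np.nan,
                    "DV": o.conc if math.isfinite(o.conc) else np.nan,
                    "EVID": 0,
                    "MDV": 0 if math.isfinite(o.conc) else 1,
                    "BLQ": int(o.blq),
                    "ALQ": int(o.alq),
                }
            )
    frame = pd.DataFrame(rows, columns=COLUMNS)
    return frame.sort_values(["ID", "TIME", "EVID"], kind="stable").reset_index(drop=True)


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    dataset_to_frame(dataset).to_csv(path, index=False, float_format="%.10g")


def _frame_to_dataset(frame: pd.DataFrame, amt_is_prodrug: bool = False) -> Dataset:
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise DatasetSchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    subjects = []
    for sid, grp in frame.groupby("ID", sort=False):
        times = grp["TIME"].to_numpy(dtype=float)
        if np.any(np.diff(times) < 0):
            raise DatasetSchemaError(f"subject {sid}: TIME must be non-decreasing")
        dose_rows = grp[grp["EVID"] == 1]
        obs_rows = grp[grp["EVID"] == 0]
        first = grp.iloc[0]
        crcl_base = float(dose_rows.iloc[0]["CRCL"]) if len(dose_rows) else float(first["CRCL"])
        cov = Covariates(
            wgt=float(first["WT"]),
            crcl=crcl_base,
            cart=_CART_NAME[int(first["CART"])],
            age=float(first["AGE"]),
            sex=_SEX_NAME.get(int(first["SEX"]), ""),
            height=float(first["HT"]),
            scr=float(first["SCR"]),
        )
        doses = []
        crcl_day3 = None
        for i, (_, row) in enumerate(dose_rows.iterrows()):
            amount = float(row["AMT"])
            if not amount > 0:
                raise DatasetSchemaError(f"subject {sid}: dose rows need AMT > 0")
            if amt_is_prodrug:
                amount *= FARA_A_FRACTION
            doses.append(
                DoseEvent(start_time=float(row["TIME"]), amount=amount, duration=float(row["DUR"]))
            )
            if i == len(dose_rows) - 1 and float(row["CRCL"]) != crcl_base:
                crcl_day3 = float(row["CRCL"])
        observations = []
        for _, row in obs_rows.iterrows():
            blq, alq = bool(row["BLQ"]), bool(row["ALQ"])
            dv = float(row["DV"]) if pd.notna(row["DV"]) else float("nan")
            if not (blq or alq) and not (math.isfinite(dv) and dv > 0):
                raise DatasetSchemaError(
                    f"subject {sid}: observation at t={row['TIME']} has no DV and no censor flag"
                )
            observations.append(Observation(time=float(row["TIME"]), conc=dv, blq=blq, alq=alq))
        subjects.append(
            SubjectRecord(
                id=str(sid),
                covariates=cov,
                regimen=tuple(doses),
                observations=tuple(observations),
                crcl_day3=crcl_day3,
            )
        )
    return Dataset(subjects=tuple(subjects))


def read_dataset(path: str | Path, amt_is_prodrug: bool = False) -> Dataset:
    """Read a study dataset CSV; validates the schema and per-subject rows."""
    frame = pd.read_csv(path, dtype={"ID": str})
    return _frame_to_dataset(frame, amt_is_prodrug=amt_is_prodrug)


@dataclasses.dataclass
class RunConfig:
    """Pipeline settings; round-trips losslessly through JSON."""

    seed: int = 1
    n_subjects: int = 56
    theta_init: dict[str, float] = dataclasses.field(default_factory=dict)
    fixed: list[str] = dataclasses.field(default_factory=list)
    n_restarts: int = 3
    maxiter: int = 150
    vpc_n_sim: int = 1000
    output_dir: str = "results"

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))
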