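"""Direct (non-iterative) per-lung PVR from CATH pressures and CMR flows.

The per-lung resistance is the transpulmonary gradient over that lung's flow,
R_L = (P_SVC - P_LA) / Q_LPA and likewise for the right lung; in Glenn
physiology both lungs see the same driving gradient, so the two resistances
combine in parallel into the total PVR.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import pandas as pd

from .errors import DomainError
from .patient_data import PatientRecord


def computed_pvr(record: PatientRecord) -> tuple[float, float]:
    """Per-lung PVR (WU*m^2): (P_SVC - P_LA)/Q_LPA and (P_SVC - P_LA)/Q_RPA.

    A negative gradient is physically suspect but not an error; it is returned
    with a warning. Zero branch flow is a domain error naming the branch.
    """
    if record.q_lpa <= 0:
        raise DomainError(f"patient {record.pid}: LPA flow must be positive")
    if record.q_rpa <= 0:
        raise DomainError(f"patient {record.pid}: RPA flow must be positive")
    dp = record.p_svc - record.p_la
    if dp < 0:
        warnings.warn(
            f"patient {record.pid}: negative transpulmonary gradient ({dp} mmHg)",
            stacklevel=2,
        )
    return dp / record.q_lpa, dp / record.q_rpa


def total_pvr(r_l: float, r_r: float) -> float:
    """Total PVR as the parallel combination r_l*r_r/(r_l + r_r).

    Identical to (P_SVC - P_LA)/(Q_LPA + Q_RPA) when both lungs share the
    driving gradient.
    """
    if r_l <= 0 or r_r <= 0:
        raise DomainError(f"per-lung PVR must be positive, got ({r_l}, {r_r})")
    return r_l * r_r / (r_l + r_r)


def computed_pvr_table(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Per-patient computed PVR table: pid, r_l, r_r, r_total, pvr_cath."""
    rows = []
    for rec in records:
        r_l, r_r = computed_pvr(rec)
        rows.append(
            {
                "pid": rec.pid,
                "r_l": r_l,
                "r_r": r_r,
                "r_total": total_pvr(r_l, r_r) if r_l > 0 and r_r > 0 else float("nan"),
                "pvr_cath": rec.pvr_cath,
            }
        )
    return pd.DataFrame(rows)
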