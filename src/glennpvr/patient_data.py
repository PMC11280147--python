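"""Patient hemodynamics records: typed rows, CSV I/O and cohort summaries.

Every quantity is stored in indexed space: flows in L/min/m^2, resistances in
Wood units x m^2 (WU*m^2) and pressures in mmHg, so that an indexed resistance
times an indexed flow is a pressure. A bundled 16-patient Glenn cohort ships as
package data and is the default input of the command-line pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError, SchemaError, TableParseError

#: canonical column order of the patient table
COLUMNS = (
    "pid",
    "sex",
    "bsa",
    "age",
    "q_svc",
    "q_lpa",
    "q_rpa",
    "pvr_cath",
    "qp_cath",
    "p_svc",
    "p_lpa",
    "p_rpa",
    "p_la",
    "p_ra",
)

NUMERIC_COLUMNS = tuple(c for c in COLUMNS if c not in ("pid", "sex"))

#: mapping from the printed clinical-table headers to canonical names
PRINTED_HEADER_MAP = {
    "PID": "pid",
    "Sex": "sex",
    "BSA": "bsa",
    "Age": "age",
    "Q_SVC": "q_svc",
    "Q_LPA": "q_lpa",
    "Q_RPA": "q_rpa",
    "PVR": "pvr_cath",
    "Q_p": "qp_cath",
    "P_SVC": "p_svc",
    "P_LPA": "p_lpa",
    "P_RPA": "p_rpa",
    "P_LA": "p_la",
    "P_RA": "p_ra",
}


@dataclass(frozen=True)
class PatientRecord:
    """One patient: demographics, CMR flows, CATH pressures and CATH PVR/Qp.

    Flows are BSA-indexed (L/min/m^2), pressures in mmHg, PVR in WU*m^2.
    """

    pid: str
    sex: str
    bsa: float
    age: float
    q_svc: float
    q_lpa: float
    q_rpa: float
    pvr_cath: float
    qp_cath: float
    p_svc: float
    p_lpa: float
    p_rpa: float
    p_la: float
    p_ra: float

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise DomainError(f"patient {self.pid}: sex must be 'M' or 'F', got {self.sex!r}")
        if not (self.bsa > 0):
            raise DomainError(f"patient {self.pid}: BSA must be positive, got {self.bsa}")
        for name in ("q_svc", "q_lpa", "q_rpa", "qp_cath"):
            if getattr(self, name) < 0:
                raise DomainError(f"patient {self.pid}: flow {name} must be >= 0")
        for name in NUMERIC_COLUMNS:
            if not math.isfinite(getattr(self, name)):
                raise DomainError(f"patient {self.pid}: {name} is not finite")


@dataclass(frozen=True)
class CohortSummary:
    """Per-column arithmetic mean and sample SD (n-1 denominator)."""

    n: int
    mean: Mapping[str, float]
    sd: Mapping[str, float]


def _bundled_path():
    return resources.files("glennpvr.data").joinpath("table1.csv")


def load_patient_table(
    source: str | Path = "bundled",
    column_map: Mapping[str, str] | None = None,
) -> list[PatientRecord]:
    """Read a patient table CSV into records, preserving row order.

    Parameters
    ----------
    source
        Path to a CSV with the canonical header, or the string ``"bundled"``
        for the packaged 16-patient cohort.
    column_map
        Optional header renaming applied before validation, e.g.
        :data:`PRINTED_HEADER_MAP` for tables using the clinical headers.
    """
    if isinstance(source, str) and source == "bundled":
        with resources.as_file(_bundled_path()) as p:
            df = pd.read_csv(p, dtype=str)
    else:
        df = pd.read_csv(source, dtype=str)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    records: list[PatientRecord] = []
    for i, row in df.iterrows():
        kwargs: dict[str, object] = {"pid": str(row["pid"]), "sex": str(row["sex"])}
        for col in NUMERIC_COLUMNS:
            try:
                kwargs[col] = float(row[col])
            except (TypeError, ValueError) as exc:
                raise TableParseError(
                    f"row {i + 1}, column {col!r}: cannot parse {row[col]!r}"
                ) from exc
        records.append(PatientRecord(**kwargs))  # type: ignore[arg-type]
    return records


def to_dataframe(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Records -> DataFrame in canonical column order."""
    return pd.DataFrame(
        [{f.name: getattr(r, f.name) for f in fields(PatientRecord)} for r in records],
        columns=list(COLUMNS),
    )


def write_patient_table(records: Sequence[PatientRecord], path: str | Path) -> None:
    to_dataframe(records).to_csv(path, index=False)


def summarize_cohort(records: Iterable[PatientRecord]) -> CohortSummary:
    """Mean and sample SD (n-1) of every numeric column; requires n >= 2."""
    df = to_dataframe(list(records))
    if len(df) < 2:
        raise InsufficientDataError(f"cohort summary needs n >= 2, got n = {len(df)}")
    num = df[list(NUMERIC_COLUMNS)].astype(float)
    return CohortSummary(
        n=len(df),
        mean=num.mean().to_dict(),
        sd=num.std(ddof=1).to_dict(),
    )


def index_flow(q_abs: float, bsa: float) -> float:
    """Absolute flow (L/min) -> BSA-indexed flow (L/min/m^2)."""
    if bsa <= 0:
        raise DomainError(f"BSA must be positive, got {bsa}")
    return q_abs / bsa


def deindex_flow(q_idx: float, bsa: float) -> float:
    """BSA-indexed flow (L/min/m^2) -> absolute flow (L/min)."""
    if bsa <= 0:
        raise DomainError(f"BSA must be positive, got {bsa}")
    return q_idx * bsa
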