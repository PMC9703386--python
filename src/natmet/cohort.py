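"""Patient records and delimited-text cohort I/O.

A cohort is a table with one row per woman: tumour diameter at detection
(mm), detection mode (``screen``/``symptomatic``), offsets of prior negative
screens (years before diagnosis, semicolon separated), number of affected
lymph nodes, time to distant metastasis in whole years, and its censoring
status (``event``: diagnosed during follow-up; ``left``: already present at
diagnosis; ``right``: free at end of follow-up).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import D0
from .screening import ScreeningHistory

__all__ = ["PatientRecord", "COLUMNS", "read_cohort", "write_cohort", "records_to_frame", "frame_to_records"]

COLUMNS = ["id", "diameter_mm", "mode", "screens", "n_nodes", "w_years", "status"]

MODES = ("screen", "symptomatic")
STATUSES = ("event", "left", "right")


@dataclass(frozen=True)
class PatientRecord:
    """One woman's observed quantities at and after diagnosis."""

    diameter_mm: float
    mode: str
    n_nodes: int
    w_years: int
    status: str
    screens: ScreeningHistory = field(default_factory=ScreeningHistory)

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.status not in STATUSES:
            raise ValueError(f"status must be one of {STATUSES}")
        if self.diameter_mm <= D0:
            raise ValueError("diameter at detection must exceed the 0.5 mm detectability limit")
        if self.n_nodes < 0:
            raise ValueError("node count must be non-negative")
        if self.status == "left" and self.w_years != 0:
            raise ValueError("left-censored records must have w_years = 0")
        if self.status == "event" and self.w_years < 1:
            raise ValueError("observed events must have w_years >= 1")
        if self.w_years < 0:
            raise ValueError("w_years must be non-negative")


def _format_screens(h: ScreeningHistory) -> str:
    return ";".join(f"{t:g}" for t in h.times_before_dx)


def _parse_screens(s) -> ScreeningHistory:
    if s is None or (isinstance(s, float) and np.isnan(s)) or str(s).strip() == "":
        return ScreeningHistory(())
    return ScreeningHistory(tuple(float(tok) for tok in str(s).split(";")))


def records_to_frame(records) -> pd.DataFrame:
    rows = [
        {
            "id": i,
            "diameter_mm": rec.diameter_mm,
            "mode": rec.mode,
            "screens": _format_screens(rec.screens),
            "n_nodes": rec.n_nodes,
            "w_years": rec.w_years,
            "status": rec.status,
        }
        for i, rec in enumerate(records)
    ]
    return pd.DataFrame(rows, columns=COLUMNS)


def frame_to_records(df: pd.DataFrame):
    missing = [c for c in COLUMNS if c not in df.columns and c != "id"]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")
    out = []
    for idx, row in df.iterrows():
        try:
            out.append(
                PatientRecord(
                    diameter_mm=float(row["diameter_mm"]),
                    mode=str(row["mode"]),
                    screens=_parse_screens(row["screens"]),
                    n_nodes=int(row["n_nodes"]),
                    w_years=int(row["w_years"]),
                    status=str(row["status"]),
                )
            )
        except (ValueError, TypeError) as err:
            raise ValueError(f"invalid cohort record at row {idx}: {err}") from err
    return out


def write_cohort(cohort, path) -> None:
    """Write a cohort (DataFrame or record list) as tab-separated text."""
    df = cohort if isinstance(cohort, pd.DataFrame) else records_to_frame(cohort)
    df.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a tab-separated cohort file, validating every record."""
    df = pd.read_csv(path, sep="\t", dtype={"screens": str})
    if "screens" in df.columns:
        df["screens"] = df["screens"].fillna("")
    if df.empty:
        warnings.warn(f"cohort file {path} contains no records")
        return pd.DataFrame(columns=COLUMNS)
    frame_to_records(df)  # validation with row-numbered errors
    return df
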