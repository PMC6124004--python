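"""CSV / YAML readers and writers.

Observation CSV columns (exact header order): facility, department, date,
shift, cadre, mode, classification, n_present, n_oncall_responded,
provenance. ``date`` carries the 1-based observation day index.

Standards YAML maps department -> cadre -> {morning, evening, night}
minimums; a cadre entry may additionally carry ``mode`` (a CadreMode
value), ``pool`` (list of source cadre names merged into this cadre) and
``rule`` (best / sum / two_pool). A department key of ``"*"`` is a
wildcard.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .core import (
    CadreMode,
    DoctorClassification,
    PoolRule,
    Shift,
    SHIFTS,
    ShiftObservation,
    StaffingStandard,
    Standards,
)

CSV_COLUMNS = ["facility", "department", "date", "shift", "cadre", "mode",
               "classification", "n_present", "n_oncall_responded",
               "provenance"]


class InputFormatError(ValueError):
    """Malformed input file; message carries row-level diagnostics."""


def read_observations(path) -> list[ShiftObservation]:
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise InputFormatError(f"{path}: no observations") from None
    if frame.empty:
        raise InputFormatError(f"{path}: no observations")
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise InputFormatError(f"{path}: missing column(s) {missing}")
    records: list[ShiftObservation] = []
    problems: list[str] = []
    for i, row in frame.iterrows():
        try:
            records.append(_row_to_observation(row))
        except (ValueError, KeyError) as err:
            problems.append(f"row {i + 2}: {err}")  # +2: header + 1-based
    if problems:
        raise InputFormatError(f"{path}:\n" + "\n".join(problems))
    return records


def _row_to_observation(row) -> ShiftObservation:
    mode = CadreMode(row["mode"])
    classification = None
    n_present: Optional[int] = None
    n_oncall = int(row["n_oncall_responded"] or 0)
    if mode is CadreMode.DOCTOR_STYLE:
        classification = DoctorClassification(row["classification"])
    else:
        if row["n_present"] == "":
            raise ValueError(f"headcount cadre {row['cadre']!r} needs n_present")
        n_present = int(row["n_present"])
    return ShiftObservation(
        facility=row["facility"], department=row["department"],
        day_index=int(row["date"]), shift=Shift(row["shift"]),
        cadre=row["cadre"], mode=mode, classification=classification,
        n_present=n_present, n_oncall_responded=n_oncall,
        provenance=row["provenance"] or "observed")


def observations_to_frame(records: Sequence[ShiftObservation]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "facility": r.facility, "department": r.department,
            "date": r.day_index, "shift": r.shift.value, "cadre": r.cadre,
            "mode": r.mode.value,
            "classification": r.classification.value if r.classification else "",
            "n_present": "" if r.n_present is None else r.n_present,
            "n_oncall_responded": r.n_oncall_responded,
            "provenance": r.provenance,
        })
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_observations(records: Sequence[ShiftObservation], path) -> None:
    observations_to_frame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# standards


_DEFAULT_MODE_BY_RULE = {
    PoolRule.TWO_POOL: CadreMode.SUPPORT_POOL,
    PoolRule.BEST: CadreMode.DOCTOR_STYLE,
}


def read_standards(path) -> Standards:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise InputFormatError(f"{path}: standards file is not a mapping")
    standards = []
    for dept, cadres in data.items():
        for cadre, spec in cadres.items():
            try:
                minimums = {s: int(spec[s.value]) for s in SHIFTS}
            except KeyError as err:
                raise InputFormatError(
                    f"{path}: {dept}/{cadre} missing shift minimum {err}")
            rule = PoolRule(spec["rule"]) if "rule" in spec else None
            if "mode" in spec:
                mode = CadreMode(spec["mode"])
            elif rule in _DEFAULT_MODE_BY_RULE:
                mode = _DEFAULT_MODE_BY_RULE[rule]
            elif cadre == "support":
                mode = CadreMode.SUPPORT_POOL
            else:
                mode = CadreMode.GRADED_HEADCOUNT
            standards.append(StaffingStandard(
                department=dept, cadre=cadre, mode=mode,
                min_required=minimums,
                pool_cadres=tuple(spec.get("pool", ())),
                pool_rule=rule))
    return Standards(standards)


# ---------------------------------------------------------------------------
# packaged fixtures


def fixture_path(name: str) -> Path:
    """Path to a packaged fixture file (scenario / standards YAML)."""
    return Path(resources.files("emoncavail") / "fixtures" / name)


__all__ = [
    "CSV_COLUMNS", "InputFormatError", "read_observations",
    "observations_to_frame", "write_observations", "read_standards",
    "fixture_path",
]
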