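"""Turn validated observations into tallies, presence distributions and
the per-shift index matrix.

The pipeline is: classify each shift cell into exactly one exclusive
category, count categories into a tally per (facility, department, cadre,
shift), apply the matching closed-form index, and average the three shift
indices into a day average. Presence distributions (category percentages
per shift) are the intermediate human-readable product.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

from .core import (
    CadreMode,
    CLASSIFICATION_RANK,
    DoctorClassification,
    DoctorTally,
    GradedTally,
    PoolRule,
    Shift,
    SHIFTS,
    ShiftObservation,
    StaffingStandard,
    Standards,
    SupportTally,
    Tally,
    UndefinedIndexError,
)
from . import indices as idx

# neutral category: counted in N, no credit, no penalty
NEUTRAL = "x"

_DOCTOR_CATEGORY = {
    DoctorClassification.PRESENT_MAJORITY: "a",
    DoctorClassification.PRESENT_MINORITY: "b",
    DoctorClassification.OFFSITE_RESPONDED: "c",
    DoctorClassification.OFFSITE_NO_RESPONSE: "d",
    DoctorClassification.OFFSITE_NOT_CALLED: NEUTRAL,
}


def classify_shift(obs: ShiftObservation, std: StaffingStandard) -> str:
    """Assign one exclusive category label to a single observation.

    Doctor-style records map their classification to a/b/c/d (or neutral).
    Headcount records at or above the shift minimum take the top-coded
    category; below it, the exact-count category. A zero on-site headcount
    for an on-call cadre becomes an on-call category when a response was
    observed, otherwise neutral (no call arose, so no failure was shown);
    for a plain ward cadre it is the zero category.
    """
    if obs.mode is CadreMode.DOCTOR_STYLE:
        return _DOCTOR_CATEGORY[obs.classification]
    n = obs.n_present or 0
    if obs.mode is CadreMode.SUPPORT_POOL:
        return "s2" if n >= std.minimum(obs.shift) else ("s1" if n == 1 else "s0")
    minimum = std.minimum(obs.shift)
    if n >= minimum:
        return f"m{minimum}"
    if n > 0:
        return f"m{n}"
    if obs.mode is CadreMode.GRADED_HEADCOUNT_WITH_ONCALL:
        k = obs.n_oncall_responded
        if k >= minimum:
            return "m2a"
        if k == 1:
            return "m1a"
        return NEUTRAL
    return "m0"


def _merge_cell(rows: Sequence[ShiftObservation],
                std: StaffingStandard) -> str:
    """Classify one (facility, department, day, shift) cell, pooling rows
    of the standard's source cadres according to its pool rule."""
    if len(rows) == 1 and not std.pool_cadres:
        return classify_shift(rows[0], std)
    rule = std.pool_rule or (PoolRule.BEST if std.mode is CadreMode.DOCTOR_STYLE
                             else PoolRule.SUM)
    if rule is PoolRule.BEST:
        best = max(rows, key=lambda r: CLASSIFICATION_RANK[r.classification])
        return _DOCTOR_CATEGORY[best.classification]
    if rule is PoolRule.TWO_POOL:
        by_cadre = {r.cadre: (r.n_present or 0) for r in rows}
        pools = std.pool_cadres or tuple(by_cadre)
        counts = [by_cadre.get(c, 0) for c in pools]
        if len(counts) >= 2 and all(k >= 1 for k in counts):
            return "s2"
        return "s1" if sum(counts) >= 1 else "s0"
    # SUM: add headcounts; an on-site presence supersedes on-call arrivals
    total = sum(r.n_present or 0 for r in rows)
    oncall = 0 if total else sum(r.n_oncall_responded for r in rows)
    merged = ShiftObservation(rows[0].facility, rows[0].department,
                              rows[0].day_index, rows[0].shift, std.cadre,
                              std.mode, n_present=total,
                              n_oncall_responded=oncall)
    return classify_shift(merged, std)


def _select(records: Iterable[ShiftObservation], facility: str,
            department: str, std: StaffingStandard,
            shift: Optional[Shift]) -> dict[int, list[ShiftObservation]]:
    names = set(std.pool_cadres) | {std.cadre}
    cells: dict[int, list[ShiftObservation]] = {}
    for r in records:
        if (r.facility == facility and r.department == department
                and r.cadre in names
                and (shift is None or r.shift is shift)):
            cells.setdefault(r.day_index, []).append(r)
    return cells


def _tally_from_counts(counts: dict[str, int], mode: CadreMode, n: int) -> Tally:
    if mode is CadreMode.DOCTOR_STYLE:
        return DoctorTally(a=counts.get("a", 0), b=counts.get("b", 0),
                           c=counts.get("c", 0), d=counts.get("d", 0), N=n)
    if mode is CadreMode.SUPPORT_POOL:
        return SupportTally(s2=counts.get("s2", 0), s1=counts.get("s1", 0),
                            s0=counts.get("s0", 0), N=n)
    return GradedTally(m3=counts.get("m3", 0), m2=counts.get("m2", 0),
                       m1=counts.get("m1", 0), m0=counts.get("m0", 0),
                       m2a=counts.get("m2a", 0), m1a=counts.get("m1a", 0), N=n)


def build_tally(records: Iterable[ShiftObservation], facility: str,
                department: str, cadre: str, shift: Shift,
                standards: Standards) -> Tally:
    """Count exclusive categories over the selected shifts; N = number of
    observed shifts (days with no observation are dropped, not imputed)."""
    std = _resolve_standard(standards, department, cadre, records, facility)
    cells = _select(records, facility, department, std, shift)
    if not cells:
        raise UndefinedIndexError(
            f"no observations for {facility}/{department}/{cadre}/{shift.value}")
    counts: dict[str, int] = {}
    for _, rows in cells.items():
        label = _merge_cell(rows, std)
        counts[label] = counts.get(label, 0) + 1
    counts.pop(NEUTRAL, None)
    return _tally_from_counts(counts, std.mode, len(cells))


def _resolve_standard(standards: Standards, department: str, cadre: str,
                      records: Iterable[ShiftObservation],
                      facility: str) -> StaffingStandard:
    try:
        return standards.lookup(department, cadre)
    except KeyError:
        for r in records:
            if (r.facility == facility and r.department == department
                    and r.cadre == cadre):
                return standards.lookup(department, cadre, r.mode)
        raise


def shift_index(tally: Tally, std: StaffingStandard, shift: Shift) -> idx.IndexValue:
    """Apply the index formula matching the cadre mode and shift minimum."""
    if isinstance(tally, DoctorTally):
        v = idx.doctor_index(tally)
    elif isinstance(tally, SupportTally):
        v = idx.support_index(tally)
    else:
        v = idx.graded_index(tally, std.minimum(shift))
    return idx.IndexValue(v.value, shift.value)


# presentation order of categories per tally kind
_CATEGORY_ORDER = {
    CadreMode.DOCTOR_STYLE: ["a", "b", "c", "d", NEUTRAL],
    CadreMode.GRADED_HEADCOUNT: ["m3", "m2", "m1", "m0"],
    CadreMode.GRADED_HEADCOUNT_WITH_ONCALL: ["m3", "m2", "m1", "m2a", "m1a",
                                             "m0", NEUTRAL],
    CadreMode.SUPPORT_POOL: ["s2", "s1", "s0"],
}


@dataclass
class PresenceDistribution:
    """Category percentages per shift for one facility/department/cadre."""

    facility: str
    department: str
    cadre: str
    frame: pd.DataFrame  # columns: shift, category, count, n, percent


def _analysis_units(records: Sequence[ShiftObservation],
                    standards: Standards):
    """Yield (facility, department, std) for every standard with data."""
    seen = set()
    for r in records:
        mapping = standards.source_cadres(r.department)
        std = mapping.get(r.cadre)
        if std is None:
            std = _resolve_standard(standards, r.department, r.cadre,
                                    records, r.facility)
        key = (r.facility, r.department, std.cadre)
        if key not in seen:
            seen.add(key)
            yield r.facility, r.department, std


def presence_distribution(records: Sequence[ShiftObservation],
                          standards: Standards) -> list[PresenceDistribution]:
    """Category counts / N x 100 per shift, every category printed even
    when zero, grouped per facility, department and cadre.

    Distributions use one category layout across all three shifts,
    top-coded at the cadre's highest shift minimum (so a ward with a
    morning minimum of three reports >=3 / 2 / 1 / 0 for every shift),
    which keeps the evening and night index categories derivable from the
    printed rows.
    """
    out = []
    for facility, department, std in _analysis_units(records, standards):
        max_min = (max(std.min_required.values())
                   if std.mode is not CadreMode.DOCTOR_STYLE else 1)
        dist_std = replace(std, min_required={s: max_min for s in SHIFTS})
        rows = []
        for shift in SHIFTS:
            try:
                tally = build_tally(records, facility, department, std.cadre,
                                    shift, Standards([dist_std]))
            except UndefinedIndexError:
                continue
            counts = _tally_counts(tally)
            n = tally.N
            order = _category_order(dist_std, shift)
            for cat in order:
                k = counts.get(cat, 0)
                rows.append({"shift": shift.value, "category": cat,
                             "count": k, "n": n, "percent": k / n * 100})
        if rows:
            out.append(PresenceDistribution(
                facility, department, std.cadre, pd.DataFrame(rows)))
    return out


def _category_order(std: StaffingStandard, shift: Shift) -> list[str]:
    order = list(_CATEGORY_ORDER[std.mode])
    if std.mode in (CadreMode.GRADED_HEADCOUNT,
                    CadreMode.GRADED_HEADCOUNT_WITH_ONCALL):
        if std.minimum(shift) < 3:
            order = [c for c in order if c != "m3"]
    return order


def _tally_counts(tally: Tally) -> dict[str, int]:
    if isinstance(tally, DoctorTally):
        counts = {"a": tally.a, "b": tally.b, "c": tally.c, "d": tally.d}
        counts[NEUTRAL] = tally.N - sum(counts.values())
    elif isinstance(tally, SupportTally):
        counts = {"s2": tally.s2, "s1": tally.s1, "s0": tally.s0}
    else:
        counts = {"m3": tally.m3, "m2": tally.m2, "m1": tally.m1,
                  "m0": tally.m0, "m2a": tally.m2a, "m1a": tally.m1a}
        counts[NEUTRAL] = tally.N - sum(counts.values())
    return counts


@dataclass
class IndexReport:
    """Per-shift availability indices and day averages for one run.

    ``matrix`` holds full-precision values (columns: facility, department,
    cadre, morning, evening, night, day_average); undefined cells are NaN
    and listed in ``undefined``. ``distributions`` carries the presence
    tables the indices were computed from.
    """

    matrix: pd.DataFrame
    distributions: list[PresenceDistribution]
    undefined: list[str]

    def to_frame(self, decimals: int = 1,
                 clamp_negative: bool = False) -> pd.DataFrame:
        out = self.matrix.copy()
        cols = ["morning", "evening", "night", "day_average"]
        for col in cols:
            out[col] = [
                idx.IndexValue(v, col).rounded(decimals, clamp_negative)
                if pd.notna(v) else v
                for v in out[col]
            ]
        return out

    def to_text(self, decimals: int = 1, clamp_negative: bool = False) -> str:
        frame = self.to_frame(decimals, clamp_negative)
        return frame.to_string(index=False,
                               float_format=lambda v: f"{v:.{decimals}f}")


def index_report(records: Sequence[ShiftObservation],
                 standards: Standards) -> IndexReport:
    """Full index matrix: three shift indices and the day average per
    (facility, department, cadre); a cell with no observations is left NaN
    without disturbing the others."""
    rows = []
    undefined: list[str] = []
    for facility, department, std in _analysis_units(records, standards):
        values: dict[str, float] = {}
        per_shift: list[idx.IndexValue] = []
        for shift in SHIFTS:
            try:
                tally = build_tally(records, facility, department, std.cadre,
                                    shift, standards)
                v = shift_index(tally, std, shift)
                values[shift.value] = v.value
                per_shift.append(v)
            except UndefinedIndexError as err:
                values[shift.value] = float("nan")
                undefined.append(str(err))
        if len(per_shift) == 3:
            values["day_average"] = idx.day_average(*per_shift).value
        else:
            values["day_average"] = float("nan")
            undefined.append(
                f"day average undefined for {facility}/{department}/{std.cadre}")
        rows.append({"facility": facility, "department": department,
                     "cadre": std.cadre, **values})
    matrix = pd.DataFrame(rows, columns=["facility", "department", "cadre",
                                         "morning", "evening", "night",
                                         "day_average"])
    return IndexReport(matrix, presence_distribution(records, standards),
                       undefined)


__all__ = [
    "classify_shift", "build_tally", "shift_index", "presence_distribution",
    "PresenceDistribution", "IndexReport", "index_report", "NEUTRAL",
]
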