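"""Domain model for shift-level provider-availability observations.

The observational unit is one (facility, department, day, shift, cadre)
cell. Two payload families exist:

* **doctor-style** cadres (consultants, medical officers, anesthetists,
  medical technologists, nurse aides) are recorded as a single exclusive
  classification of the shift: on-site for the majority of the shift,
  on-site for a minority, off-site but responded to an emergency call,
  off-site and failed to respond, or off-site with no call arising.
* **headcount** cadres (nurses, family welfare visitors, pooled support
  staff) are recorded as the number of providers present, plus — for
  operating-theatre nurses — the number who arrived in response to an
  emergency call when nobody was on site.

Minimum staffing standards per department x cadre x shift determine which
headcount meets the "fully staffed" bar.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence, Union


class Shift(str, Enum):
    """The three daily duty periods.

    Nominal durations differ (morning 8 AM-2 PM, evening 2 PM-9 PM,
    night 9 PM-8 AM) but shifts are weighted equally in every index.
    """

    MORNING = "morning"
    EVENING = "evening"
    NIGHT = "night"

    @property
    def nominal_hours(self) -> float:
        return _NOMINAL_HOURS[self]


_NOMINAL_HOURS = {Shift.MORNING: 6.0, Shift.EVENING: 7.0, Shift.NIGHT: 11.0}

SHIFTS: tuple[Shift, Shift, Shift] = (Shift.MORNING, Shift.EVENING, Shift.NIGHT)


class CadreMode(str, Enum):
    """How presence is recorded for a cadre, which fixes its index formula."""

    DOCTOR_STYLE = "doctor_style"
    GRADED_HEADCOUNT = "graded_headcount"
    GRADED_HEADCOUNT_WITH_ONCALL = "graded_headcount_with_oncall"
    SUPPORT_POOL = "support_pool"


class DoctorClassification(str, Enum):
    """Exclusive per-shift presence state for a doctor-style provider.

    ``OFFSITE_NOT_CALLED`` covers shifts where no provider was on site and
    no emergency call arose, so responsiveness could not be judged; such
    shifts count in the denominator but earn no credit and no penalty.
    """

    PRESENT_MAJORITY = "present_majority"      # on site > 50% of the shift
    PRESENT_MINORITY = "present_minority"      # on site < 50% of the shift
    OFFSITE_RESPONDED = "offsite_responded"    # came when called
    OFFSITE_NO_RESPONSE = "offsite_no_response"  # called, did not come
    OFFSITE_NOT_CALLED = "offsite_not_called"  # off site, no call arose


#: Ranking used when pooling several providers' classifications into one
#: shift classification: the shift takes the best state achieved by anyone.
#: On-site majority beats on-call response (equal credit, tie to on-site).
CLASSIFICATION_RANK: Mapping[DoctorClassification, int] = {
    DoctorClassification.PRESENT_MAJORITY: 4,
    DoctorClassification.OFFSITE_RESPONDED: 3,
    DoctorClassification.PRESENT_MINORITY: 2,
    DoctorClassification.OFFSITE_NOT_CALLED: 1,
    DoctorClassification.OFFSITE_NO_RESPONSE: 0,
}


@dataclass(frozen=True)
class DoctorPresence:
    classification: DoctorClassification


@dataclass(frozen=True)
class HeadcountPresence:
    n_present: int
    n_oncall_responded: int = 0


@dataclass(frozen=True)
class CadreClass:
    name: str
    mode: CadreMode


@dataclass(frozen=True)
class ShiftObservation:
    """One observed (facility, department, day, shift, cadre) record."""

    facility: str
    department: str
    day_index: int
    shift: Shift
    cadre: str
    mode: CadreMode
    classification: Optional[DoctorClassification] = None
    n_present: Optional[int] = None
    n_oncall_responded: int = 0
    provenance: str = "observed"

    @property
    def key(self) -> tuple:
        return (self.facility, self.department, self.day_index,
                self.shift, self.cadre)

    @property
    def payload(self) -> Union[DoctorPresence, HeadcountPresence]:
        if self.mode is CadreMode.DOCTOR_STYLE:
            if self.classification is None:
                raise ValueError(f"doctor-style record without classification: {self.key}")
            return DoctorPresence(self.classification)
        if self.n_present is None:
            raise ValueError(f"headcount record without n_present: {self.key}")
        return HeadcountPresence(self.n_present, self.n_oncall_responded)


# ---------------------------------------------------------------------------
# staffing standards


class PoolRule(str, Enum):
    """How observation rows of several source cadres merge into one shift cell.

    ``BEST``     — the best classification achieved by any pooled provider
                   (doctor-style; consultants and medical officers combined).
    ``SUM``      — headcounts added before classification.
    ``TWO_POOL`` — fully staffed requires at least one provider from EACH of
                   exactly two sub-pools; any single provider scores partial.
    """

    BEST = "best"
    SUM = "sum"
    TWO_POOL = "two_pool"


@dataclass(frozen=True)
class StaffingStandard:
    """Minimum required headcount per shift for one department x cadre."""

    department: str
    cadre: str
    mode: CadreMode
    min_required: Mapping[Shift, int]
    pool_cadres: tuple[str, ...] = ()
    pool_rule: Optional[PoolRule] = None

    def minimum(self, shift: Shift) -> int:
        return self.min_required[shift]


class Standards:
    """Lookup table of staffing standards keyed by (department, cadre).

    A department of ``"*"`` acts as a wildcard fallback, and doctor-style
    cadres default to a minimum of one provider per shift.
    """

    def __init__(self, standards: Iterable[StaffingStandard]):
        self._by_key: dict[tuple[str, str], StaffingStandard] = {}
        for s in standards:
            self._by_key[(s.department, s.cadre)] = s

    def __iter__(self):
        return iter(self._by_key.values())

    def lookup(self, department: str, cadre: str,
               mode: Optional[CadreMode] = None) -> StaffingStandard:
        std = self._by_key.get((department, cadre)) or self._by_key.get(("*", cadre))
        if std is not None:
            return std
        if mode is CadreMode.DOCTOR_STYLE:
            return StaffingStandard(department, cadre, mode,
                                    {s: 1 for s in SHIFTS})
        raise KeyError(f"no staffing standard for {department!r}/{cadre!r}")

    def source_cadres(self, department: str) -> dict[str, StaffingStandard]:
        """Map each raw observation cadre to the standard that consumes it."""
        out: dict[str, StaffingStandard] = {}
        for (dept, _), std in self._by_key.items():
            if dept not in (department, "*"):
                continue
            if std.pool_cadres:
                for src in std.pool_cadres:
                    out[src] = std
            else:
                out[std.cadre] = std
        return out


def default_standards() -> Standards:
    """The study facilities' minimum staffing requirements.

    Ob/gyn and pediatric wards need three nurses in the morning and two in
    each of the evening and night shifts; the operating theatre needs two
    nurses in every shift; the pooled support staff (peon / ward boy / aya /
    sweeper / guard) needs two in every shift; each doctor-style discipline
    needs at least one provider per shift.
    """
    ward = {Shift.MORNING: 3, Shift.EVENING: 2, Shift.NIGHT: 2}
    two = {s: 2 for s in SHIFTS}
    one = {s: 1 for s in SHIFTS}
    return Standards([
        StaffingStandard("obgyn_ward", "nurse", CadreMode.GRADED_HEADCOUNT, ward),
        StaffingStandard("pediatric_ward", "nurse", CadreMode.GRADED_HEADCOUNT, ward),
        StaffingStandard("operating_theatre", "nurse",
                         CadreMode.GRADED_HEADCOUNT_WITH_ONCALL, two),
        StaffingStandard("*", "support", CadreMode.SUPPORT_POOL, two),
        StaffingStandard("*", "doctor", CadreMode.DOCTOR_STYLE, one,
                         pool_cadres=("consultant", "medical_officer"),
                         pool_rule=PoolRule.BEST),
    ])


# ---------------------------------------------------------------------------
# tallies


@dataclass(frozen=True)
class DoctorTally:
    """Shift counts for a doctor-style cadre.

    ``a`` majority-present, ``b`` minority-present, ``c`` off-site but
    responded, ``d`` off-site and did not respond. Shifts with no call and
    nobody on site count only in ``N``.
    """

    a: int = 0
    b: int = 0
    c: int = 0
    d: int = 0
    N: int = 0

    def __post_init__(self):
        if self.a + self.b + self.c + self.d > self.N:
            raise ValueError("category counts exceed total shifts N")


@dataclass(frozen=True)
class GradedTally:
    """Shift counts for a headcount cadre, categories exclusive.

    ``m3`` at or above a morning minimum of three, ``m2`` exactly two
    (top-coded to "two or more" where the minimum is two), ``m1`` exactly
    one, ``m0`` none. ``m2a``/``m1a`` count shifts covered purely by an
    on-call response (two-or-more / exactly one arriving when called).
    """

    m3: int = 0
    m2: int = 0
    m1: int = 0
    m0: int = 0
    m2a: int = 0
    m1a: int = 0
    N: int = 0

    def __post_init__(self):
        if self.m3 + self.m2 + self.m1 + self.m0 + self.m2a + self.m1a > self.N:
            raise ValueError("category counts exceed total shifts N")


@dataclass(frozen=True)
class SupportTally:
    """Shift counts for the pooled support staff: >=2, exactly 1, none."""

    s2: int = 0
    s1: int = 0
    s0: int = 0
    N: int = 0

    def __post_init__(self):
        if self.s2 + self.s1 + self.s0 > self.N:
            raise ValueError("category counts exceed total shifts N")


Tally = Union[DoctorTally, GradedTally, SupportTally]


# ---------------------------------------------------------------------------
# validation


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_for_errors(self) -> None:
        if self.errors:
            raise ObservationValidationError("\n".join(self.errors))


class ObservationValidationError(ValueError):
    pass


class UndefinedIndexError(ValueError):
    """Raised when an index is requested over zero observed shifts."""


HEADCOUNT_SANITY_BOUND = 20


def validate_observations(records: Sequence[ShiftObservation]) -> ValidationReport:
    """Check structural integrity of an observation set.

    Hard errors: duplicate (facility, department, day, shift, cadre) keys;
    payload fields inconsistent with the cadre mode; simultaneous on-site
    and on-call headcounts. Warnings: gaps in the day sequence and
    implausibly large headcounts.
    """
    report = ValidationReport()
    seen: dict[tuple, int] = {}
    days: dict[tuple, set[int]] = {}
    for i, r in enumerate(records):
        if r.key in seen:
            report.errors.append(
                f"duplicate observation key {r.key} at rows {seen[r.key]} and {i}")
        else:
            seen[r.key] = i

        if r.mode is CadreMode.DOCTOR_STYLE:
            if r.classification is None:
                report.errors.append(
                    f"row {i}: doctor-style cadre {r.cadre!r} lacks a classification")
            if r.n_present not in (None, 0) or r.n_oncall_responded:
                report.errors.append(
                    f"row {i}: doctor-style cadre {r.cadre!r} carries headcounts")
        else:
            if r.classification is not None:
                report.errors.append(
                    f"row {i}: headcount cadre {r.cadre!r} carries a classification")
            if r.n_present is None or r.n_present < 0:
                report.errors.append(
                    f"row {i}: headcount cadre {r.cadre!r} needs n_present >= 0")
            else:
                if r.n_present > HEADCOUNT_SANITY_BOUND:
                    report.warnings.append(
                        f"row {i}: suspicious headcount {r.n_present} for {r.cadre!r}")
                if r.n_present > 0 and r.n_oncall_responded > 0:
                    report.errors.append(
                        f"row {i}: on-site and on-call headcounts both positive")
            if (r.n_oncall_responded
                    and r.mode is not CadreMode.GRADED_HEADCOUNT_WITH_ONCALL):
                report.errors.append(
                    f"row {i}: on-call headcount on cadre {r.cadre!r} "
                    f"whose mode {r.mode.value!r} does not accept one")
        days.setdefault((r.facility, r.department, r.cadre, r.shift),
                        set()).add(r.day_index)

    for key, ds in days.items():
        missing = set(range(min(ds), max(ds) + 1)) - ds
        if missing:
            report.warnings.append(
                f"day gap for {key}: missing day(s) {sorted(missing)}")
    return report


__all__ = [
    "Shift", "SHIFTS", "CadreMode", "DoctorClassification",
    "CLASSIFICATION_RANK", "DoctorPresence", "HeadcountPresence",
    "CadreClass", "ShiftObservation", "PoolRule", "StaffingStandard",
    "Standards", "default_standards", "DoctorTally", "GradedTally",
    "SupportTally", "Tally", "ValidationReport", "validate_observations",
    "ObservationValidationError", "UndefinedIndexError",
    "HEADCOUNT_SANITY_BOUND",
]
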