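"""Classification, tallying, presence distributions and the index matrix."""

import math

import pytest

from emoncavail.core import (
    CadreMode,
    DoctorClassification,
    DoctorTally,
    GradedTally,
    PoolRule,
    Shift,
    SHIFTS,
    ShiftObservation,
    StaffingStandard,
    Standards,
    UndefinedIndexError,
    default_standards,
)
from emoncavail.indices import graded_index
from emoncavail.tabulation import (
    NEUTRAL,
    build_tally,
    classify_shift,
    index_report,
    presence_distribution,
    shift_index,
)


def _obs(department="obgyn_ward", shift=Shift.MORNING, n=None, oncall=0,
         cls=None, cadre="nurse", day=1, facility="F",
         mode=CadreMode.GRADED_HEADCOUNT):
    return ShiftObservation(facility, department, day, shift, cadre, mode,
                            classification=cls, n_present=n,
                            n_oncall_responded=oncall)


@pytest.fixture(scope="module")
def stds():
    return default_standards()


class TestClassifyShift:
    def _std(self, stds, dept, cadre="nurse"):
        return stds.lookup(dept, cadre)

    @pytest.mark.parametrize("shift, n, expected", [
        (Shift.MORNING, 5, "m3"),   # above minimum, top-coded
        (Shift.MORNING, 3, "m3"),   # exactly at minimum is top category
        (Shift.MORNING, 2, "m2"),
        (Shift.MORNING, 1, "m1"),
        (Shift.MORNING, 0, "m0"),
        (Shift.EVENING, 2, "m2"),   # off-peak minimum of two, top-coded
        (Shift.EVENING, 3, "m2"),
        (Shift.EVENING, 1, "m1"),
        (Shift.NIGHT, 0, "m0"),
    ])
    def test_ward_nurse_categories(self, stds, shift, n, expected):
        std = self._std(stds, "obgyn_ward")
        assert classify_shift(_obs(shift=shift, n=n), std) == expected

    @pytest.mark.parametrize("n, oncall, expected", [
        (2, 0, "m2"),
        (1, 0, "m1"),
        (0, 2, "m2a"),
        (0, 1, "m1a"),
        (0, 0, NEUTRAL),  # nobody on site, no call arose: unscored
    ])
    def test_operating_theatre_oncall_categories(self, stds, n, oncall,
                                                 expected):
        std = self._std(stds, "operating_theatre")
        obs = _obs("operating_theatre", Shift.EVENING, n=n, oncall=oncall,
                   mode=CadreMode.GRADED_HEADCOUNT_WITH_ONCALL)
        assert classify_shift(obs, std) == expected

    @pytest.mark.parametrize("cls, expected", [
        (DoctorClassification.PRESENT_MAJORITY, "a"),
        (DoctorClassification.PRESENT_MINORITY, "b"),
        (DoctorClassification.OFFSITE_RESPONDED, "c"),
        (DoctorClassification.OFFSITE_NO_RESPONSE, "d"),
        (DoctorClassification.OFFSITE_NOT_CALLED, NEUTRAL),
    ])
    def test_doctor_categories(self, stds, cls, expected):
        std = stds.lookup("emergency", "doctor")
        obs = _obs("emergency", cls=cls, cadre="doctor",
                   mode=CadreMode.DOCTOR_STYLE, n=None)
        assert classify_shift(obs, std) == expected

    @pytest.mark.parametrize("n, expected", [(3, "s2"), (2, "s2"),
                                             (1, "s1"), (0, "s0")])
    def test_support_pool_categories(self, stds, n, expected):
        std = stds.lookup("general", "support")
        obs = _obs("general", n=n, cadre="support",
                   mode=CadreMode.SUPPORT_POOL)
        assert classify_shift(obs, std) == expected


class TestBuildTally:
    def test_reconstructed_ward_morning_tally(self, dh_records, stds):
        t = build_tally(dh_records, "DH", "obgyn_ward", "nurse",
                        Shift.MORNING, stds)
        assert t == GradedTally(m3=29, m2=1, N=30)

    def test_emergency_doctors_always_present(self, dh_records, stds):
        t = build_tally(dh_records, "DH", "emergency", "doctor",
                        Shift.MORNING, stds)
        assert t == DoctorTally(a=30, N=30)

    def test_single_shift_selection(self, stds):
        t = build_tally([_obs(n=2)], "F", "obgyn_ward", "nurse",
                        Shift.MORNING, stds)
        assert t == GradedTally(m2=1, N=1)

    def test_empty_selection_is_undefined(self, stds):
        with pytest.raises(UndefinedIndexError):
            build_tally([], "F", "obgyn_ward", "nurse", Shift.MORNING, stds)

    def test_missing_day_reduces_n(self, dh_records, stds):
        thinned = [r for r in dh_records
                   if not (r.department == "obgyn_ward" and r.day_index == 7
                           and r.shift is Shift.MORNING)]
        t = build_tally(thinned, "DH", "obgyn_ward", "nurse",
                        Shift.MORNING, stds)
        assert t.N == 29 and t.m3 + t.m2 == 29
        # other shifts untouched
        e = build_tally(thinned, "DH", "obgyn_ward", "nurse",
                        Shift.EVENING, stds)
        assert e.N == 30

    def test_tally_conservation(self, dh_records, stds):
        for shift in SHIFTS:
            t = build_tally(dh_records, "DH", "pediatric_ward", "nurse",
                            shift, stds)
            assert t.m3 + t.m2 + t.m1 + t.m0 == t.N == 30


class TestPooling:
    def test_doctor_pool_takes_best_classification(self, stds):
        rows = [
            _obs("obgyn_ward", cadre="consultant", mode=CadreMode.DOCTOR_STYLE,
                 cls=DoctorClassification.OFFSITE_NO_RESPONSE),
            _obs("obgyn_ward", cadre="medical_officer",
                 mode=CadreMode.DOCTOR_STYLE,
                 cls=DoctorClassification.OFFSITE_RESPONDED),
        ]
        t = build_tally(rows, "F", "obgyn_ward", "doctor", Shift.MORNING, stds)
        assert t == DoctorTally(c=1, N=1)

    def test_two_pool_support_needs_one_from_each(self, mcwc_standards):
        def pair(day, pg, sa):
            return [_obs("general", n=pg, cadre="peon_guard", day=day,
                         mode=CadreMode.SUPPORT_POOL),
                    _obs("general", n=sa, cadre="sweeper_aya", day=day,
                         mode=CadreMode.SUPPORT_POOL)]
        rows = pair(1, 1, 1) + pair(2, 2, 0) + pair(3, 0, 0)
        t = build_tally(rows, "F", "general", "support", Shift.MORNING,
                        mcwc_standards)
        # two from one sub-pool alone is only partial coverage
        assert (t.s2, t.s1, t.s0, t.N) == (1, 1, 1, 3)

    def test_sum_pooling_combines_headcounts(self):
        std = StaffingStandard("ward", "nursing", CadreMode.GRADED_HEADCOUNT,
                               {s: 3 for s in SHIFTS},
                               pool_cadres=("fwv", "ana"),
                               pool_rule=PoolRule.SUM)
        rows = [_obs("ward", n=2, cadre="fwv"), _obs("ward", n=1, cadre="ana")]
        t = build_tally(rows, "F", "ward", "nursing", Shift.MORNING,
                        Standards([std]))
        assert t == GradedTally(m3=1, N=1)


class TestPresenceDistribution:
    def _dist(self, records, standards, department, cadre):
        for d in presence_distribution(records, standards):
            if d.department == department and d.cadre == cadre:
                return d
        raise AssertionError("distribution not found")

    def test_ward_morning_matches_recorded_percentages(self, dh_records, stds):
        d = self._dist(dh_records, stds, "obgyn_ward", "nurse")
        morning = d.frame.query("shift == 'morning'").set_index("category")
        assert morning.loc["m3", "percent"] == pytest.approx(96.6667, abs=1e-3)
        assert morning.loc["m2", "percent"] == pytest.approx(3.3333, abs=1e-3)
        assert morning.loc["m1", "percent"] == 0.0  # printed, never omitted
        assert morning.loc["m0", "percent"] == 0.0

    def test_offpeak_rows_keep_morning_category_layout(self, mcwc_records,
                                                       mcwc_standards):
        d = self._dist(mcwc_records, mcwc_standards, "obgyn_ward", "fwv")
        night = d.frame.query("shift == 'night'").set_index("category")
        got = [round(night.loc[c, "percent"], 1) for c in
               ("m3", "m2", "m1", "m0")]
        assert got == [3.3, 36.7, 56.7, 3.3]

    def test_percentages_sum_to_100(self, dh_records, stds):
        for d in presence_distribution(dh_records, stds):
            sums = d.frame.groupby("shift")["percent"].sum()
            assert all(abs(s - 100.0) < 0.2 for s in sums)


class TestIndexReport:
    def test_pipeline_identity_with_formula_path(self, dh_records, stds):
        report = index_report(dh_records, stds)
        row = report.matrix.query(
            "department == 'pediatric_ward'").iloc[0]
        for shift in SHIFTS:
            t = build_tally(dh_records, "DH", "pediatric_ward", "nurse",
                            shift, stds)
            std = stds.lookup("pediatric_ward", "nurse")
            assert row[shift.value] == pytest.approx(
                shift_index(t, std, shift).value)

    def test_undefined_cell_leaves_others_intact(self, dh_records, stds):
        # drop every operating-theatre night observation
        thinned = [r for r in dh_records
                   if not (r.department == "operating_theatre"
                           and r.shift is Shift.NIGHT)]
        report = index_report(thinned, stds)
        row = report.matrix.query(
            "department == 'operating_theatre'").iloc[0]
        assert math.isnan(row["night"]) and math.isnan(row["day_average"])
        assert row["morning"] == pytest.approx(26 / 30 * 100)
        assert report.undefined

    def test_recomputing_from_emitted_counts_is_idempotent(self, dh_records,
                                                           stds):
        report = index_report(dh_records, stds)
        d = next(x for x in report.distributions
                 if x.department == "obgyn_ward")
        std = stds.lookup("obgyn_ward", "nurse")
        for shift in SHIFTS:
            counts = dict(zip(
                d.frame.query(f"shift == '{shift.value}'")["category"],
                d.frame.query(f"shift == '{shift.value}'")["count"]))
            # distribution top-codes at the morning minimum; fold for off-peak
            if std.minimum(shift) == 2:
                counts["m2"] = counts.get("m2", 0) + counts.pop("m3", 0)
            t = GradedTally(N=30, **{k: v for k, v in counts.items()
                                     if k != "x"})
            recomputed = graded_index(t, std.minimum(shift)).value
            row = report.matrix.query("department == 'obgyn_ward'").iloc[0]
            assert recomputed == pytest.approx(row[shift.value])
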