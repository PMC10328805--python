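"""Window conventions, screens and series assembly for the case series."""

import numpy as np
import pandas as pd
import pytest

from glycopipe.sccs import (
    build_drug_series,
    exclusion_screen,
    first_exposure_index,
    lab_qc,
    outcome_delta_glucose,
    outcome_delta_hba1c,
    persistence_check,
)
from glycopipe.synthetic import generate_ehr

from conftest import DRUG_GROUPS, make_truth, noiseless_config


def rx(patient, drug, day, event_type="fill", days_supply=30.0):
    return {
        "patient_id": patient,
        "drug_id": drug,
        "day": day,
        "event_type": event_type,
        "days_supply": days_supply,
    }


def lab(patient, day, value, analyte="hba1c", setting="outpatient"):
    return {
        "patient_id": patient,
        "analyte": analyte,
        "day": day,
        "value": value,
        "setting": setting,
    }


class TestFirstExposure:
    def test_earliest_event_wins(self):
        events = pd.DataFrame([rx("p1", "D", 160), rx("p1", "D", 100), rx("p2", "D", 5)])
        t0 = first_exposure_index(events, "D")
        assert t0["p1"] == 100 and t0["p2"] == 5

    def test_duplicate_earliest_day_collapses(self):
        events = pd.DataFrame([rx("p1", "D", 7), rx("p1", "D", 7)])
        t0 = first_exposure_index(events, "D")
        assert len(t0) == 1 and t0["p1"] == 7

    def test_unexposed_patient_absent(self):
        events = pd.DataFrame([rx("p1", "OTHER", 10)])
        assert first_exposure_index(events, "D").empty


GROUPS = {"D": "experimental", "SAME": "experimental", "OTHER": "glucose_increasing"}


class TestExclusionScreen:
    @pytest.mark.parametrize(
        "other_day,eligible",
        [
            (100, False),   # ever before (t0 - 400)
            (500, False),   # simultaneous at t0
            (600, False),   # inside follow-up
            (680, False),   # boundary: day t0 + 180 still excludes
            (681, True),    # just outside the follow-up window
            (700, True),    # well outside
        ],
    )
    def test_other_group_timing(self, other_day, eligible):
        events = pd.DataFrame([rx("p1", "D", 500), rx("p1", "OTHER", other_day)])
        t0 = first_exposure_index(events, "D")
        out = exclusion_screen(events, t0, "experimental", GROUPS)
        assert bool(out.loc["p1", "eligible"]) is eligible

    def test_same_group_coprescription_keeps_patient(self):
        events = pd.DataFrame([rx("p1", "D", 500), rx("p1", "SAME", 500)])
        t0 = first_exposure_index(events, "D")
        out = exclusion_screen(events, t0, "experimental", GROUPS)
        assert out.loc["p1", "eligible"]

    def test_unknown_drug_is_configuration_error(self):
        events = pd.DataFrame([rx("p1", "MYSTERY", 10)])
        with pytest.raises(KeyError, match="MYSTERY"):
            exclusion_screen(events, pd.Series({"p1": 10}), "experimental", GROUPS)


class TestPersistence:
    def test_fills_refill_and_cumulative_supply(self):
        events = pd.DataFrame(
            [rx("p1", "D", 0, days_supply=90), rx("p1", "D", 60, days_supply=90)]
        )
        ok = persistence_check(events, pd.Series({"p1": 0}), "fills")
        assert bool(ok["p1"])

    def test_fills_single_fill_fails_despite_supply(self):
        events = pd.DataFrame([rx("p1", "D", 0, days_supply=90)])
        ok = persistence_check(events, pd.Series({"p1": 0}), "fills")
        assert not bool(ok["p1"])

    def test_fills_insufficient_cumulative_supply_fails(self):
        events = pd.DataFrame(
            [rx("p1", "D", 0, days_supply=30), rx("p1", "D", 60, days_supply=30)]
        )
        ok = persistence_check(events, pd.Series({"p1": 0}), "fills")
        assert not bool(ok["p1"])

    def test_fills_refill_outside_180_days_fails(self):
        events = pd.DataFrame(
            [rx("p1", "D", 0, days_supply=90), rx("p1", "D", 181, days_supply=90)]
        )
        ok = persistence_check(events, pd.Series({"p1": 0}), "fills")
        assert not bool(ok["p1"])

    @pytest.mark.parametrize(
        "days,expected", [([0, 90], True), ([0], False), ([0, 180], True), ([0, 181], False)]
    )
    def test_mentions_two_within_180(self, days, expected):
        events = pd.DataFrame(
            [rx("p1", "D", d, event_type="mention", days_supply=np.nan) for d in days]
        )
        ok = persistence_check(events, pd.Series({"p1": 0}), "mentions")
        assert bool(ok["p1"]) is expected

    def test_unknown_dialect_raises(self):
        with pytest.raises(ValueError):
            persistence_check(pd.DataFrame([rx("p1", "D", 0)]), pd.Series({"p1": 0}), "faxes")


class TestLabQc:
    @pytest.mark.parametrize(
        "analyte,value,kept",
        [
            ("hba1c", 2.9, False),
            ("hba1c", 3.0, True),
            ("hba1c", 18.0, True),
            ("hba1c", 18.1, False),
            ("glucose", 4.9, False),
            ("glucose", 5.0, True),
            ("glucose", 2750.0, True),
            ("glucose", 2800.0, False),
        ],
    )
    def test_physiologic_bounds_inclusive(self, analyte, value, kept):
        labs = pd.DataFrame([lab("p1", 10, value, analyte=analyte)])
        assert (len(lab_qc(labs)) == 1) is kept

    def test_inpatient_measures_dropped(self):
        labs = pd.DataFrame([lab("p1", 10, 7.0, setting="inpatient")])
        assert lab_qc(labs).empty

    @pytest.mark.parametrize("lab_day,dropped", [(100, True), (30, True), (29, False)])
    def test_pregnancy_window(self, lab_day, dropped):
        labs = pd.DataFrame([lab("p1", lab_day, 7.0)])
        pregnancy = pd.DataFrame([{"patient_id": "p1", "day": 300}])
        out = lab_qc(labs, pregnancy, apply_pregnancy=True)
        assert out.empty is dropped  # |lab - 300| <= 270 drops

    def test_pregnancy_only_applies_to_same_patient(self):
        labs = pd.DataFrame([lab("p2", 100, 7.0)])
        pregnancy = pd.DataFrame([{"patient_id": "p1", "day": 300}])
        assert len(lab_qc(labs, pregnancy, apply_pregnancy=True)) == 1

    def test_unknown_analyte_raises(self):
        labs = pd.DataFrame([lab("p1", 10, 7.0, analyte="ketones")])
        with pytest.raises(ValueError, match="ketones"):
            lab_qc(labs)


class TestOutcomeWindows:
    def test_hba1c_most_recent_baseline_first_followup(self):
        t0 = 1000
        labs = pd.DataFrame(
            [
                lab("p1", t0 - 200, 8.2),
                lab("p1", t0 - 10, 7.5),
                lab("p1", t0 + 15, 7.4),
                lab("p1", t0 + 40, 7.0),
                lab("p1", t0 + 100, 6.8),
            ]
        )
        assert outcome_delta_hba1c(labs, t0) == (7.5, 7.0)

    def test_hba1c_window_boundaries(self):
        t0 = 1000
        labs = pd.DataFrame([lab("p1", t0 - 180, 8.0), lab("p1", t0 + 31, 7.2)])
        assert outcome_delta_hba1c(labs, t0) == (8.0, 7.2)

    def test_hba1c_excluded_boundary_days(self):
        # a lab exactly at t0, at t0+30 or before t0-180 never qualifies
        t0 = 1000
        labs = pd.DataFrame(
            [lab("p1", t0 - 181, 8.0), lab("p1", t0, 7.7), lab("p1", t0 + 30, 7.5)]
        )
        assert outcome_delta_hba1c(labs, t0) is None

    def test_hba1c_absent_without_baseline(self):
        labs = pd.DataFrame([lab("p1", 1040, 7.0)])
        assert outcome_delta_hba1c(labs, 1000) is None

    def test_hba1c_same_day_duplicates_average(self):
        t0 = 1000
        labs = pd.DataFrame(
            [lab("p1", t0 - 10, 7.0), lab("p1", t0 - 10, 8.0), lab("p1", t0 + 40, 7.0)]
        )
        assert outcome_delta_hba1c(labs, t0) == (7.5, 7.0)

    def test_glucose_means_each_side(self):
        t0 = 1000
        labs = pd.DataFrame(
            [
                lab("p1", t0 - 30, 90.0, analyte="glucose"),
                lab("p1", t0 - 10, 110.0, analyte="glucose"),
                lab("p1", t0 + 5, 95.0, analyte="glucose"),
                lab("p1", t0 + 50, 105.0, analyte="glucose"),
                lab("p1", t0 + 90, 130.0, analyte="glucose"),
            ]
        )
        base, follow = outcome_delta_glucose(labs, t0)
        assert base == pytest.approx(100.0)
        assert follow == pytest.approx(110.0)

    def test_glucose_absent_without_followup(self):
        labs = pd.DataFrame([lab("p1", 900, 100.0, analyte="glucose")])
        assert outcome_delta_glucose(labs, 1000) is None


class TestBuildSeries:
    def test_noiseless_recovery_is_exact(self, truth, noiseless_tables):
        res = build_drug_series(
            noiseless_tables["prescriptions"],
            noiseless_tables["labs"],
            "EXP_A",
            "hba1c",
            "fills",
            DRUG_GROUPS,
        )
        assert not res.suppressed and res.n >= 30
        np.testing.assert_allclose(res.deltas, -0.5, rtol=0, atol=1e-12)

    def test_noiseless_glucose_recovery(self, truth, noiseless_tables):
        res = build_drug_series(
            noiseless_tables["prescriptions"],
            noiseless_tables["labs"],
            "DEC_B",
            "glucose",
            "fills",
            DRUG_GROUPS,
        )
        assert res.n >= 30
        np.testing.assert_allclose(res.deltas, -30.0, rtol=0, atol=1e-12)

    def test_full_contamination_excludes_every_assigned_patient(self, truth):
        """With contamination certain, no patient assigned the experimental
        drug survives the other-group screen (contaminants fall before, at,
        or inside the follow-up of t0 by construction)."""
        cfg = noiseless_config(n_patients=100, seed=21)
        cfg.contamination_fraction = 1.0
        tables = generate_ehr(cfg, truth)
        rx_t, demo = tables["prescriptions"], tables["demographics"]
        assigned = set(demo.loc[demo["series_drug"] == "EXP_A", "patient_id"])
        t0 = first_exposure_index(rx_t, "EXP_A")
        screen = exclusion_screen(rx_t, t0, "experimental", DRUG_GROUPS)
        eligible = set(screen.index[screen["eligible"]])
        assert assigned and not (assigned & eligible)

    def test_min_n_suppression_threshold(self, truth, noiseless_tables):
        res = build_drug_series(
            noiseless_tables["prescriptions"],
            noiseless_tables["labs"],
            "EXP_A",
            "hba1c",
            "fills",
            DRUG_GROUPS,
            min_n=10_000,
        )
        assert res.suppressed and res.cases.empty
        assert res.attrition["with_outcome"] > 0

    def test_row_shuffle_invariance(self, truth, ehr_tables):
        kwargs = dict(drug_id="EXP_A", analyte="hba1c", dialect="fills", groups=DRUG_GROUPS)
        a = build_drug_series(
            ehr_tables["prescriptions"], ehr_tables["labs"], **kwargs
        )
        b = build_drug_series(
            ehr_tables["prescriptions"].sample(frac=1, random_state=3),
            ehr_tables["labs"].sample(frac=1, random_state=4),
            **kwargs,
        )
        pd.testing.assert_frame_equal(a.cases, b.cases)

    def test_screens_compose_as_intersection(self, truth, ehr_tables):
        """The included patients are exactly those passing every screen
        applied independently."""
        rx_t, labs_t = ehr_tables["prescriptions"], ehr_tables["labs"]
        res = build_drug_series(rx_t, labs_t, "EXP_A", "hba1c", "fills", DRUG_GROUPS)
        t0 = first_exposure_index(rx_t, "EXP_A")
        screen = exclusion_screen(rx_t, t0, "experimental", DRUG_GROUPS)
        persist = persistence_check(rx_t[rx_t["drug_id"] == "EXP_A"], t0, "fills")
        clean = lab_qc(labs_t)
        clean = clean[clean["analyte"] == "hba1c"]
        with_outcome = {
            pid
            for pid in t0.index
            if outcome_delta_hba1c(clean[clean["patient_id"] == pid], int(t0[pid]))
            is not None
        }
        expected = (
            set(t0.index[screen["eligible"]]) & set(t0.index[persist]) & with_outcome
        )
        assert set(res.cases["patient_id"]) == expected
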