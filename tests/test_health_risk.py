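"""Dose models, hazard quotients/indices, carcinogenic risk, contributions."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sedrisk.health_risk import (
    assess_health_risk,
    carcinogenic_risk,
    cdd_dermal,
    cdd_ingestion,
    cdd_inhalation,
    hazard_index,
    hazard_quotient,
    risk_contributions,
    tcr_category,
)
from sedrisk.reference_data import ElementDoseResponse, ExposureProfile


def make_profile(**overrides) -> ExposureProfile:
    params = dict(
        receptor="adult", ABW=70.0, IR=100.0, IHR=20.0, SA=5700.0, SAF=0.07,
        DAF={"As": 0.03, "default": 0.001}, ED=24.0, EF_days=350.0,
        AET_nc=24.0 * 365, AET_ca=70.0 * 365, PEF=1.36e9, CFU=1e-6,
    )
    params.update(overrides)
    return ExposureProfile(**params)


class TestChronicDailyDose:
    def test_zero_concentration_gives_zero_dose(self, adult):
        assert cdd_ingestion(0.0, adult) == 0.0
        assert cdd_inhalation(0.0, adult) == 0.0
        assert cdd_dermal(0.0, adult, "As") == 0.0

    def test_adult_arsenic_ingestion_worked_value(self, adult):
        # downstream zone-mean As, non-carcinogenic averaging
        assert cdd_ingestion(15.4, adult, "nc") == pytest.approx(
            2.1095890410958904e-05, rel=1e-12
        )

    def test_doubling_ed_cancels_under_nc_averaging(self):
        # AET_nc = ED*365, so ED cancels from the non-carcinogenic dose
        p1 = make_profile(ED=24.0, AET_nc=24.0 * 365)
        p2 = make_profile(ED=48.0, AET_nc=48.0 * 365)
        assert cdd_ingestion(5.0, p1, "nc") == pytest.approx(
            cdd_ingestion(5.0, p2, "nc"), rel=1e-12
        )

    @given(cm=st.floats(min_value=1e-3, max_value=1e4))
    def test_inhalation_to_ingestion_ratio_is_element_free(self, adult, cm):
        ratio = cdd_inhalation(cm, adult) / cdd_ingestion(cm, adult)
        expected = adult.IHR / (adult.IR * adult.CFU * adult.PEF)
        assert ratio == pytest.approx(expected, rel=1e-12)

    def test_dermal_with_daf_one_mirrors_ingestion(self):
        p = make_profile(DAF={"default": 1.0})
        derm = cdd_dermal(3.0, p, "Pb")
        ing = cdd_ingestion(3.0, p)
        assert derm / ing == pytest.approx(p.SA * p.SAF / p.IR, rel=1e-12)

    def test_carcinogenic_dose_never_exceeds_nc_dose(self, adult):
        assert cdd_ingestion(9.9, adult, "ca") <= cdd_ingestion(9.9, adult, "nc")

    @given(
        cm=st.floats(min_value=0, max_value=1e4),
        abw=st.floats(min_value=5, max_value=120),
        ir=st.floats(min_value=10, max_value=500),
        ihr=st.floats(min_value=1, max_value=40),
        sa=st.floats(min_value=100, max_value=20000),
        saf=st.floats(min_value=0.01, max_value=1.0),
        ed=st.floats(min_value=1, max_value=70),
        ef=st.floats(min_value=10, max_value=365),
        daf=st.floats(min_value=1e-4, max_value=1.0),
    )
    def test_routes_match_single_expression_oracles(
        self, cm, abw, ir, ihr, sa, saf, ed, ef, daf
    ):
        p = make_profile(
            ABW=abw, IR=ir, IHR=ihr, SA=sa, SAF=saf, ED=ed, EF_days=ef,
            AET_nc=ed * 365, AET_ca=70 * 365, DAF={"default": daf},
        )
        for aet, mode in ((ed * 365, "nc"), (70 * 365, "ca")):
            assert cdd_ingestion(cm, p, mode) == pytest.approx(
                cm * ir * ed * ef / (abw * aet) * 1e-6, rel=1e-12, abs=0
            )
            assert cdd_inhalation(cm, p, mode) == pytest.approx(
                cm * ihr * ed * ef / (abw * aet * 1.36e9), rel=1e-12, abs=0
            )
            assert cdd_dermal(cm, p, "Pb", mode) == pytest.approx(
                cm * sa * saf * daf * ed * ef / (abw * aet) * 1e-6, rel=1e-12, abs=0
            )


class TestHazard:
    def test_hq_closed_forms(self):
        assert hazard_quotient(3e-4, 3e-4) == pytest.approx(1.0)
        assert hazard_quotient(0.0, 3e-4) == 0.0
        with pytest.raises(ValueError):
            hazard_quotient(1.0, 0.0)

    def test_arsenic_ingestion_hq_worked_value(self, adult, dose_response):
        cdd = cdd_ingestion(15.4, adult, "nc")
        hq = hazard_quotient(cdd, dose_response["As"].rfd_ing)
        assert hq == pytest.approx(0.0703196, rel=1e-6)

    def test_single_route_hi_equals_hq(self):
        hi, cat = hazard_index({"ing": 0.4})
        assert hi == 0.4 and cat == "insignificant"

    @pytest.mark.parametrize(
        "hi, category",
        [(0.99, "insignificant"), (1.0, "insignificant"),
         (1.01, "possible chronic adverse effect")],
    )
    def test_hi_threshold_is_strict(self, hi, category):
        assert hazard_index([hi])[1] == category

    def test_hi_commutes_over_route_order(self):
        a = hazard_index({"ing": 0.1, "inh": 0.2, "derm": 0.3})[0]
        b = hazard_index({"derm": 0.3, "ing": 0.1, "inh": 0.2})[0]
        assert a == b


class TestCarcinogenicRisk:
    def test_zero_doses_mean_no_significant_risk(self, dose_response):
        cr, tcr, cat = carcinogenic_risk(
            {"ing": 0.0, "inh": 0.0, "derm": 0.0}, dose_response["As"]
        )
        assert tcr == 0.0 and cat == "no significant risk"

    def test_adult_arsenic_ingestion_worked_value(self, adult, dose_response):
        cdd_ca = cdd_ingestion(15.4, adult, "ca")
        cr, tcr, _ = carcinogenic_risk({"ing": cdd_ca}, dose_response["As"])
        assert cr["ing"] == pytest.approx(1.0849315068493149e-05, rel=1e-12)

    @pytest.mark.parametrize(
        "tcr, category",
        [(5e-7, "no significant risk"), (5e-5, "acceptable"),
         (1e-4, "acceptable"), (2e-4, "unacceptable")],
    )
    def test_tcr_bands(self, tcr, category):
        assert tcr_category(tcr) == category

    def test_dermal_slope_factor_uses_giabs(self, dose_response):
        dr = dose_response["Cd"]  # GIABS = 0.025
        cr, _, _ = carcinogenic_risk({"derm": 1e-6}, dr, dermal_mode="giabs")
        assert cr["derm"] == pytest.approx(1e-6 * dr.sf_ing / dr.giabs, rel=1e-12)
        cr2, _, _ = carcinogenic_risk({"derm": 1e-6}, dr, dermal_mode="oral_sf")
        assert cr2["derm"] == pytest.approx(1e-6 * dr.sf_ing, rel=1e-12)

    def test_routes_without_potency_factors_are_skipped(self):
        dr = ElementDoseResponse(element="Mn", rfd_ing=0.14)  # no SF, no IUR
        cr, tcr, cat = carcinogenic_risk({"ing": 1e-6, "inh": 1e-9}, dr)
        assert cr == {} and tcr == 0.0


class TestContributions:
    def test_single_element_gets_everything(self):
        assert risk_contributions({"As": 0.7}) == {"As": 100.0}

    def test_equal_split(self):
        shares = risk_contributions({"As": 2.0, "Cd": 2.0, "Cr": 2.0, "Pb": 2.0})
        assert all(v == pytest.approx(25.0) for v in shares.values())

    def test_zero_total_is_undefined(self):
        assert risk_contributions({"As": 0.0}) is None


class TestAssessment:
    def test_contributions_sum_to_100(self, adult, dose_response):
        result = assess_health_risk(
            {"As": 15.4, "Cd": 0.4, "Pb": 23.1, "Cr": 9.5, "Ni": 11.0},
            adult, dose_response, site="S",
        )
        assert sum(result.hi_contributions.values()) == pytest.approx(100.0)
        assert sum(result.tcr_contributions.values()) == pytest.approx(100.0)

    def test_hi_and_tcr_are_route_and_element_sums(self, adult, dose_response):
        result = assess_health_risk({"As": 15.4, "Pb": 23.1}, adult, dose_response)
        for el, hi in result.hi_by_element.items():
            assert hi == pytest.approx(
                sum(v for (e, _), v in result.hq.items() if e == el)
            )
            assert result.tcr_by_element[el] == pytest.approx(
                sum(v for (e, _), v in result.cr.items() if e == el)
            )
        assert result.hi_total == pytest.approx(sum(result.hi_by_element.values()))
        assert result.tcr_total == pytest.approx(sum(result.tcr_by_element.values()))

    def test_homogeneous_of_degree_one_in_concentration(self, adult, dose_response):
        base = assess_health_risk({"As": 10.0, "Pb": 20.0}, adult, dose_response)
        scaled = assess_health_risk({"As": 30.0, "Pb": 60.0}, adult, dose_response)
        assert scaled.hi_total == pytest.approx(3 * base.hi_total, rel=1e-12)
        assert scaled.tcr_total == pytest.approx(3 * base.tcr_total, rel=1e-12)

    def test_elements_without_dose_response_are_skipped(self, adult, dose_response):
        result = assess_health_risk(
            {"As": 15.4, "Zn": 101.3}, adult, dose_response
        )
        assert set(result.hi_by_element) == {"As"}
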