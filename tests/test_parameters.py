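"""Parameter types, the packaged baseline, validation, and round-trips."""

import math

import pytest
import yaml

from nbscea.parameters import (
    CANONICAL_SEQUELAE,
    DISEASE_CODES,
    ParameterError,
    apply_override,
    incidence_from_ratio,
    load_parameter_set,
    parameter_set_to_dict,
    save_parameter_set,
    validate_parameter_set,
)

# printed 1:N ratios alongside the printed decimal incidences
PRINTED_INCIDENCES = {
    "PKU": (14_028, 0.00007128),
    "MSUD": (206_667, 0.00000484),
    "CIT1": (265_700, 0.00000376),
    "HCY": (212_622, 0.0000047),
    "MMA": (46_500, 0.00002151),
    "IVA": (265_900, 0.00000376),
    "GA1": (310_200, 0.00000322),
    "PA": (310_200, 0.00000322),
    "PCD": (23_862, 0.00004191),
    "MCAD": (372_252, 0.00000269),
    "VLCAD": (620_421, 0.000001611),
}


class TestIncidenceRatio:
    @pytest.mark.parametrize("text,expected", [
        ("1:14,028", 1 / 14028),
        ("1:1", 1.0),
        ("1:620,421", 1 / 620421),
        ("1: 265,700", 1 / 265700),
    ])
    def test_parses_printed_ratios(self, text, expected):
        assert incidence_from_ratio(text) == pytest.approx(expected, rel=1e-12)

    def test_matches_printed_decimals_to_printed_precision(self):
        # the published decimals are truncated, so agree to one unit in
        # the last printed digit
        for code, (n, decimal) in PRINTED_INCIDENCES.items():
            digits = len(str(decimal).split(".")[1])
            assert incidence_from_ratio(f"1:{n:,}") == pytest.approx(decimal, abs=10.0 ** -digits), code

    def test_inverse_product_is_one(self):
        for code, (n, _) in PRINTED_INCIDENCES.items():
            assert incidence_from_ratio(f"1:{n}") * n == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("bad", ["", "2:3", "1:0", "1:-5", "1/400", "one in four"])
    def test_rejects_malformed(self, bad):
        with pytest.raises(ParameterError):
            incidence_from_ratio(bad)


class TestBaseline:
    def test_is_valid_with_full_panel(self, baseline):
        assert validate_parameter_set(baseline) == []
        assert sorted(baseline.disease_codes) == sorted(DISEASE_CODES)
        assert len(baseline.diseases) == 12

    def test_assay_table(self, baseline):
        msms, iff = baseline.assays["MSMS"], baseline.assays["IF"]
        assert (msms.sensitivity, msms.specificity) == (1.0, 1.0)
        assert (iff.sensitivity, iff.specificity) == (1.0, 0.786)
        assert (msms.screen_cost, msms.confirm_cost, msms.followup_cost) == (296.0, 296.0, 1184.0)
        assert (iff.screen_cost, iff.confirm_cost, iff.followup_cost) == (23.0, 319.0, 1276.0)

    def test_incidence_table(self, baseline):
        for code, (_, decimal) in PRINTED_INCIDENCES.items():
            assert baseline.disease(code).incidence == decimal

    def test_cit2_incidence_is_assumed_equal_to_cit1(self, baseline):
        cit1, cit2 = baseline.disease("CIT1"), baseline.disease("CIT2")
        assert cit2.incidence == cit1.incidence
        assert cit2.incidence_assumed and not cit1.incidence_assumed
        assert cit2.treatment_cost_0_5 == cit1.treatment_cost_0_5 == 48202.46
        assert cit2.treatment_cost_6_82 == cit1.treatment_cost_6_82 == 20833.77

    @pytest.mark.parametrize("code,young,old", [
        ("MSUD", 13440.90, 6083.00),
        ("HCY", 13772.13, 5952.51),
        ("MMA", 19023.76, 24692.53),
        ("IVA", 17567.81, 13045.01),
        ("GA1", 17567.81, 13045.01),
        ("PA", 17567.81, 19839.39),
        ("PCD", 15853.26, 15853.26),
        ("PKU", 15000.00, 15000.00),
    ])
    def test_treatment_cost_bands(self, baseline, code, young, old):
        d = baseline.disease(code)
        assert (d.treatment_cost_0_5, d.treatment_cost_6_82) == (young, old)
        assert d.treatment_cost_at(5) == young and d.treatment_cost_at(6) == old

    def test_cost_and_utility_tables(self, baseline):
        c, u = baseline.costs, baseline.utilities
        assert c.sequela_care == {"DD": 3064.0, "ND": 53400.0, "MR": 12000.0, "RD": 70213.0}
        assert (c.transport, c.lost_productivity) == (435.0, 3060.0)
        assert sum(c.program_fixed.values()) == 1_222_000.0
        assert c.program_per_person == {"utilities": 2.52, "admin": 1.81}
        assert u.values["NS"] == 0.900 and u.bounds["NS"] == (0.850, 0.950)
        assert u.values["RD"] == 0.670 and u.bounds["RD"] == (0.580, 0.740)
        assert u.values["Alive"] == 1.0 and u.values["Dead"] == 0.0

    def test_econ_settings(self, baseline):
        e = baseline.econ
        assert (e.discount_rate, e.cohort_size, e.horizon) == (0.03, 200_000, 82)
        assert e.icer_threshold == 3 * e.per_capita_gdp == 568_704.0
        assert (e.gov_share_screening, e.gov_share_treatment, e.bia_years) == (0.80, 0.60, 10)

    def test_sequela_mapping_is_canonical(self, baseline):
        for d in baseline.diseases:
            assert tuple(d.sequelae) == CANONICAL_SEQUELAE[d.code], d.code


class TestRoundTripAndValidation:
    def test_save_load_roundtrip_is_value_identical(self, baseline, tmp_path):
        path = tmp_path / "ps.yaml"
        save_parameter_set(baseline, path)
        loaded = load_parameter_set(path)
        assert loaded == baseline
        assert loaded.content_hash() == baseline.content_hash()

    def test_empty_disease_list_rejected(self, baseline):
        doc = parameter_set_to_dict(baseline)
        doc["diseases"] = []
        with pytest.raises(ParameterError, match="diseases"):
            load_parameter_set(doc)

    def test_out_of_range_specificity_names_the_field(self, baseline):
        doc = parameter_set_to_dict(baseline)
        doc["assays"]["IF"]["specificity"] = 1.2
        with pytest.raises(ParameterError, match="assays.IF.specificity"):
            load_parameter_set(doc)

    def test_validation_returns_each_offending_path(self, baseline):
        ps = baseline.copy()
        ps.utilities.values["NS"] = 1.5
        ps.assays["MSMS"].screen_cost = -1.0
        paths = {v.path for v in validate_parameter_set(ps)}
        # NS out of range also breaks its bounds bracket; both get reported
        assert paths == {"utilities.NS", "utilities.bounds.NS", "assays.MSMS.screen_cost"}

    def test_overloaded_course_probabilities_flagged_with_age(self, baseline):
        ps = baseline.copy()
        curve = ps.disease("PKU").course_unscreened
        curve.p_death[2] = 0.9
        curve.p_onset["ND"][2] = 0.4  # sums to 1.3 at age 2
        [v] = validate_parameter_set(ps)
        assert "age=2" in v.path and math.isclose(v.value, 1.3)

    def test_unknown_disease_code_rejected(self, baseline):
        doc = parameter_set_to_dict(baseline)
        doc["diseases"][0]["code"] = "XYZ"
        with pytest.raises(ParameterError, match="code"):
            load_parameter_set(doc)


class TestOverrides:
    def test_dotted_paths_reach_every_group(self, baseline):
        ps = baseline.copy()
        apply_override(ps, "econ.discount_rate", 0.0)
        apply_override(ps, "assays.MSMS.screen_cost", 300)
        apply_override(ps, "diseases.PKU.incidence", 1e-4)
        apply_override(ps, "utilities.values.NS", 0.88)
        apply_override(ps, "costs.sequela_care.ND", 50000)
        assert ps.econ.discount_rate == 0.0
        assert ps.assays["MSMS"].screen_cost == 300.0
        assert ps.disease("PKU").incidence == 1e-4
        assert ps.utilities.values["NS"] == 0.88
        assert ps.costs.sequela_care["ND"] == 50000.0

    def test_unknown_path_raises(self, baseline):
        ps = baseline.copy()
        with pytest.raises(ParameterError, match="unknown parameter path"):
            apply_override(ps, "econ.no_such_field", 1)

    def test_baseline_loadable_without_courses(self):
        ps = load_parameter_set("baseline/shenzhen_2018", fill_courses=False)
        assert ps.disease("PKU").course_screened is None
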