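"""Cohort/policy enumeration and the parameter fixture's contracts."""

import copy

import pytest

from brcasim.parameters import (
    PAPER_BODY,
    PLACEHOLDER,
    CohortProfile,
    Policy,
    SchemaError,
    ValidationError,
    default_parameters,
    enumerate_cohorts,
    enumerate_policies,
    load_parameters,
    parameter_table,
    policy_by_id,
    save_parameters,
    without_hazards,
)


class TestCohorts:
    def test_cross_product_sizes(self):
        assert len(enumerate_cohorts(include_chemo=True)) == 144
        assert len(enumerate_cohorts(include_chemo=False)) == 72

    def test_all_profiles_distinct_and_order_stable(self):
        cohorts = enumerate_cohorts()
        assert len(set(cohorts)) == 144
        assert cohorts == enumerate_cohorts()

    def test_representative_ages(self):
        ages = {c.age_group: c.representative_age for c in enumerate_cohorts()}
        assert ages == {"<40": 35, "40-50": 45, ">50": 65}

    def test_invalid_field_rejected(self):
        with pytest.raises(ValueError):
            CohortProfile("BRCA3", "11", "<40", "luminal", "I", False)


class TestPolicies:
    def test_nine_policies_in_printed_order(self):
        ids = [p.id for p in enumerate_policies()]
        assert ids == [
            "surveillance",
            "CRRM",
            "RRBM",
            "CRRM+RRBSO",
            "RRBM+RRBSO",
            "TAM5",
            "CRRM+TAM5",
            "RRBSO",
            "RRBM+TAM5",
        ]

    def test_surveillance_has_no_components(self):
        assert policy_by_id("surveillance").components == frozenset()

    def test_rrbm_covers_both_breasts(self):
        for pid in ("RRBM", "RRBM+RRBSO", "RRBM+TAM5"):
            comp = policy_by_id(pid).components
            assert {"contralateral_mastectomy", "ipsilateral_mastectomy"} <= comp

    def test_chemo_cross_yields_18_treatment_policies(self):
        crossed = {(p.id, chemo) for p in enumerate_policies() for chemo in (False, True)}
        assert len(crossed) == 18

    def test_unknown_component_rejected(self):
        with pytest.raises(ValueError):
            Policy("x", frozenset({"radiotherapy"}))


class TestDefaultParameters:
    def test_validates_and_carries_printed_effect_sizes(self, params):
        eff = params.effects
        assert eff.rrbso_ipsilateral_reduction == 0.58
        assert eff.chemo_ipsilateral_reduction == 0.49
        assert eff.rrbso_ovarian_reduction == {"BRCA1": 0.80, "BRCA2": 0.79}
        assert eff.tamoxifen_contralateral_reduction == {"BRCA1": 0.56, "BRCA2": 0.67}
        assert eff.tamoxifen_15y_mortality_reduction == 0.30
        assert params.dcis_mortality == 0.033
        assert params.metastatic_mortality == 1.0
        assert params.tn_prevalence == {"BRCA1": 0.69, "BRCA2": 0.15}
        assert params.contralateral_risk["BRCA1"]["40-50"].segments[0] == (10, 0.27)
        assert params.contralateral_risk["BRCA2"]["40-50"].segments[0] == (10, 0.19)

    def test_primary_stage_distribution_stored_as_printed(self, params):
        dist = params.primary_stage_distribution
        assert dist == {"I": 0.523, "II": 0.431, "III": 0.04}
        assert sum(dist.values()) == pytest.approx(0.994)

    def test_second_event_distribution_normalised(self, params):
        assert sum(params.second_event_stage_distribution.values()) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_every_entry_has_a_known_provenance_tag(self, params):
        assert set(params.provenance.values()) <= {PAPER_BODY, PLACEHOLDER}
        table = parameter_table(params)
        assert len(table) == len(params.provenance)
        assert (table["provenance"].isin([PAPER_BODY, PLACEHOLDER])).all()

    def test_printed_anchors_tagged_paper_body(self, params):
        prov = params.provenance
        assert prov["effects.rrbso_ipsilateral_reduction"] == PAPER_BODY
        assert prov["dcis_mortality"] == PAPER_BODY
        assert prov["bc_mortality.I.luminal"] == PLACEHOLDER


class TestSerialisation:
    def test_round_trip_identity(self, params, tmp_path):
        path = tmp_path / "params.yaml"
        save_parameters(params, path)
        assert load_parameters(path) == params

    def test_probability_out_of_range_rejected(self, params, tmp_path):
        d = params.to_dict()
        d["contralateral_risk"]["BRCA1"]["<40"][0][1] = 1.3
        path = tmp_path / "bad.yaml"
        import yaml

        path.write_text(yaml.safe_dump(d))
        with pytest.raises(ValidationError):
            load_parameters(path)

    def test_missing_required_key_names_it(self, params, tmp_path):
        d = params.to_dict()
        del d["ovarian_lifetime_risk"]
        path = tmp_path / "missing.yaml"
        import yaml

        path.write_text(yaml.safe_dump(d))
        with pytest.raises(SchemaError, match="ovarian_lifetime_risk"):
            load_parameters(path)

    def test_unknown_key_rejected(self, params, tmp_path):
        d = params.to_dict()
        d["mystery"] = 1
        path = tmp_path / "unknown.yaml"
        import yaml

        path.write_text(yaml.safe_dump(d))
        with pytest.raises(SchemaError, match="mystery"):
            load_parameters(path)

    def test_missing_provenance_tag_rejected(self, params):
        d = copy.deepcopy(params.to_dict())
        del d["provenance"]["dcis_mortality"]
        from brcasim.parameters import ParameterSet

        with pytest.raises(ValidationError, match="dcis_mortality"):
            ParameterSet.from_dict(d)


class TestWithoutHazards:
    def test_unknown_channel_rejected(self, params):
        with pytest.raises(ValueError):
            without_hazards(params, "cosmic_rays")

    def test_zeroed_channels_still_validate(self, params):
        zeroed = without_hazards(
            params, "ipsilateral", "contralateral", "ovarian", "bc_mortality", "other"
        )
        assert zeroed.ovarian_lifetime_risk["BRCA1"]["11"] == 0.0
        assert zeroed.effects == params.effects
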