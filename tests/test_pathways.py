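"""Indirect pathways: incidence, stunting shift, deficiency and custom interventions."""

import pytest

from averted import (
    EtiologyFractionTable,
    FieldValidationError,
    IncidenceState,
    InterventionSpec,
    MortalityEnvelope,
    RiskFactorDistribution,
    UnparameterizedPathwayError,
    cascade,
    deficiency_affected_fraction,
    dummy_vaccine_templates,
    incidence_multiplier,
    mortality_multiplier_from_shift,
    register_custom_intervention,
    run_pipeline,
    stunting_shift_from_incidence,
)


@pytest.fixture
def binary_stunting():
    return RiskFactorDistribution(
        factor="stunting",
        strata=("not_stunted", "stunted"),
        prevalences=(0.6, 0.4),
        mortality_rr=(1.0, 2.0),
    )


@pytest.fixture
def incidence():
    return IncidenceState(episodes_per_child_year=4.0, etiologic_fractions={"rotavirus": 0.4})


class TestIncidenceMultiplier:
    def test_rotavirus_vaccine_on_rotavirus_share(self):
        vaccine = InterventionSpec(
            name="rota",
            incidence_efficacy=0.5,
            incidence_affected_fraction=0.4,
        )
        assert incidence_multiplier([vaccine], {"rota": 1.0}) == pytest.approx(0.8)

    def test_no_incidence_links_is_unity(self):
        plain = InterventionSpec(name="x", efficacy=0.9)
        assert incidence_multiplier([plain], {"x": 1.0}) == 1.0

    def test_two_interventions_compound_order_free(self):
        a = InterventionSpec(name="a", incidence_efficacy=0.5, incidence_affected_fraction=0.4)
        b = InterventionSpec(name="b", incidence_efficacy=0.3)
        changes = {"a": 1.0, "b": 0.5}
        fwd = incidence_multiplier([a, b], changes)
        rev = incidence_multiplier([b, a], changes)
        assert fwd == pytest.approx(rev)
        assert fwd == pytest.approx(0.8 * (1 - 0.15))


class TestStuntingShift:
    def test_unchanged_incidence_is_identity(self, binary_stunting, incidence):
        out = stunting_shift_from_incidence(binary_stunting, incidence, 1.0, 1.05)
        assert out.prevalences == binary_stunting.prevalences

    def test_unit_odds_parameter_is_identity(self, binary_stunting, incidence):
        out = stunting_shift_from_incidence(binary_stunting, incidence, 0.5, 1.0)
        assert out.prevalences == binary_stunting.prevalences

    def test_odds_transform_hand_computed(self, binary_stunting, incidence):
        # halving 4 episodes/child-year: delta = -2; odds 0.4/0.6 x 1.05^-2
        out = stunting_shift_from_incidence(binary_stunting, incidence, 0.5, 1.05)
        odds = 0.4 / 0.6 * 1.05**-2
        assert out.prevalences[1] == pytest.approx(odds / (1 + odds))
        assert sum(out.prevalences) == pytest.approx(1.0, abs=1e-12)

    def test_missing_odds_parameter_errors_loudly(self, binary_stunting, incidence):
        with pytest.raises(UnparameterizedPathwayError, match="odds_per_episode"):
            stunting_shift_from_incidence(binary_stunting, incidence, 0.5, None)

    def test_four_strata_within_group_ratios_preserved(self, incidence):
        dist = RiskFactorDistribution(
            factor="stunting",
            strata=("haz>=-1", "-1>haz>=-2", "-2>haz>=-3", "haz<-3"),
            prevalences=(0.35, 0.25, 0.25, 0.15),
            mortality_rr=(1.0, 1.6, 2.5, 4.6),
            shift_strata=("-2>haz>=-3", "haz<-3"),
        )
        out = stunting_shift_from_incidence(dist, incidence, 0.7, 1.08)
        assert out.prevalences[2] / out.prevalences[3] == pytest.approx(0.25 / 0.15)
        assert out.prevalences[0] / out.prevalences[1] == pytest.approx(0.35 / 0.25)
        assert sum(out.prevalences) == pytest.approx(1.0, abs=1e-12)


class TestMortalityMultiplierFromShift:
    def test_identical_distributions_unity(self, binary_stunting):
        assert mortality_multiplier_from_shift(binary_stunting, binary_stunting) == 1.0

    def test_hand_computed_ratio(self):
        before = RiskFactorDistribution(
            factor="stunting", strata=("a", "b"), prevalences=(0.6, 0.4), mortality_rr=(1.0, 4.0)
        )
        after = before.model_copy(update={"prevalences": (0.8, 0.2)})
        assert mortality_multiplier_from_shift(before, after) == pytest.approx(1.6 / 2.2)

    def test_strata_mismatch_rejected(self, binary_stunting):
        other = RiskFactorDistribution(
            factor="wasting", strata=("a", "b"), prevalences=(0.6, 0.4), mortality_rr=(1.0, 2.0)
        )
        with pytest.raises(FieldValidationError):
            mortality_multiplier_from_shift(binary_stunting, other)

    def test_reference_stratum_rr_must_be_one(self):
        with pytest.raises(ValueError, match="RR exactly 1"):
            RiskFactorDistribution(
                factor="stunting", strata=("a", "b"), prevalences=(0.5, 0.5), mortality_rr=(1.5, 2.0)
            )


class TestDeficiencyAffectedFraction:
    def test_prevalence_becomes_affected_fraction(self):
        vit_a = InterventionSpec(name="vitamin_a", efficacy=0.4)
        out = deficiency_affected_fraction(vit_a, 0.3)
        assert out.affected_fraction == 0.3
        assert out.efficacy == 0.4  # everything else untouched

    def test_zero_deficiency_makes_intervention_inert(self):
        env = MortalityEnvelope(diarrhea_deaths=10_000)
        inert = deficiency_affected_fraction(InterventionSpec(name="zn", efficacy=0.5), 0.0)
        assert cascade(env, [inert], {"zn": 1.0}).total_averted == 0.0

    def test_full_deficiency_reduces_to_plain_cascade(self):
        env = MortalityEnvelope(diarrhea_deaths=10_000)
        spec = InterventionSpec(name="zn", efficacy=0.5)
        full = deficiency_affected_fraction(spec, 1.0)
        assert (
            cascade(env, [full], {"zn": 0.5}).residual_deaths
            == cascade(env, [spec], {"zn": 0.5}).residual_deaths
        )

    def test_out_of_range_prevalence_rejected(self):
        with pytest.raises(FieldValidationError):
            deficiency_affected_fraction(InterventionSpec(name="zn"), 1.2)


class TestCustomInterventions:
    def test_cholera_vaccine_on_etiologic_fraction(self):
        table = EtiologyFractionTable(fractions={"cholera": 0.05})
        vaccine = register_custom_intervention(
            "cholera_vaccine", efficacy=0.6, etiology="cholera", etiology_table=table
        )
        env = MortalityEnvelope(diarrhea_deaths=10_000)
        result = cascade(env, [vaccine], {"cholera_vaccine": 1.0})
        assert result.total_averted == pytest.approx(300.0)

    def test_blank_dummy_vaccine_rejected_until_defined(self):
        template = dummy_vaccine_templates()["vaccine_b"]
        with pytest.raises(FieldValidationError, match="link"):
            register_custom_intervention(
                template["name"],
                efficacy=template["efficacy"],
                incidence_efficacy=template["incidence_efficacy"],
            )

    def test_unknown_etiology_rejected(self):
        table = EtiologyFractionTable(fractions={"dysentery": 0.039})
        with pytest.raises(FieldValidationError, match="etiology"):
            register_custom_intervention("etec_vaccine", efficacy=0.5, etiology="etec",
                                         etiology_table=table)

    def test_custom_equals_builtin_with_same_parameters(self):
        env = MortalityEnvelope(diarrhea_deaths=10_000)
        builtin = InterventionSpec(name="v", efficacy=0.5)
        custom = register_custom_intervention("v", efficacy=0.5)
        assert (
            cascade(env, [custom], {"v": 0.5}).residual_deaths
            == cascade(env, [builtin], {"v": 0.5}).residual_deaths
        )


class TestPipeline:
    def make_specs(self):
        return [
            InterventionSpec(
                name="rota", role="prevention", efficacy=0.2,
                incidence_efficacy=0.5, incidence_affected_fraction=0.4,
            ),
            InterventionSpec(name="ors", role="treatment", efficacy=0.69),
        ]

    def test_neutral_indirect_pathway_matches_direct_cascade(self, binary_stunting, incidence):
        """With odds_per_episode=1 the pipeline reproduces the direct-only cascade."""
        env = MortalityEnvelope(diarrhea_deaths=10_000)
        specs = self.make_specs()
        changes = {"rota": 0.8, "ors": 0.5}
        piped = run_pipeline(
            env, specs, changes,
            incidence=incidence, stunting=binary_stunting, odds_per_episode=1.0,
        )
        direct = cascade(env, specs, changes)
        assert piped.residual_deaths == pytest.approx(direct.residual_deaths)
        assert piped.stunting_mortality_multiplier == 1.0

    def test_unit_rrs_neutralize_pathway(self, incidence):
        flat = RiskFactorDistribution(
            factor="stunting", strata=("a", "b"), prevalences=(0.6, 0.4), mortality_rr=(1.0, 1.0)
        )
        env = MortalityEnvelope(diarrhea_deaths=10_000)
        specs = self.make_specs()
        changes = {"rota": 1.0, "ors": 1.0}
        piped = run_pipeline(env, specs, changes, incidence=incidence, stunting=flat,
                             odds_per_episode=1.05)
        assert piped.residual_deaths == pytest.approx(
            cascade(env, specs, changes).residual_deaths
        )

    def test_stunting_pathway_averts_additional_deaths(self, binary_stunting, incidence):
        env = MortalityEnvelope(diarrhea_deaths=10_000)
        specs = self.make_specs()
        changes = {"rota": 1.0, "ors": 0.0}
        piped = run_pipeline(
            env, specs, changes,
            incidence=incidence, stunting=binary_stunting, odds_per_episode=1.05,
        )
        direct = cascade(env, specs, changes)
        assert piped.incidence_multiplier == pytest.approx(0.8)
        assert piped.stunting_mortality_multiplier < 1.0
        assert piped.residual_deaths < direct.residual_deaths
        # ordering: prevention step, then the pathway step, then treatment
        names = [s.intervention for s in piped.cascade.averted_by_step]
        assert names == ["rota", "_stunting_pathway", "ors"]
        assert sum(s.averted for s in piped.cascade.averted_by_step) == pytest.approx(
            piped.cascade.total_averted
        )

    def test_pipeline_requires_incidence_state_when_stunting_given(self, binary_stunting):
        env = MortalityEnvelope(diarrhea_deaths=10_000)
        with pytest.raises(UnparameterizedPathwayError):
            run_pipeline(env, self.make_specs(), {"rota": 1.0},
                         stunting=binary_stunting, odds_per_episode=1.05)
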