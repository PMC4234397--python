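"""Indirect risk-factor pathways and etiology-specific effects.

Prevention interventions can lower diarrhea incidence as well as direct
mortality. Fewer episodes mean less stunting, and stunting carries a
graded relative risk of diarrhea death — so an incidence reduction feeds
back into mortality through the stunting distribution. The pipeline
order each year is:

1. prevention interventions update incidence and direct mortality,
2. the stunting distribution shifts in response to the incidence change,
3. the resulting mortality multiplier is applied to the residual,
4. treatment interventions act on what remains.

The incidence-to-stunting link requires an explicit per-episode odds
parameter; invoking the pathway without one is an error, never a silent
default.
"""

from __future__ import annotations

from typing import Iterable, Literal, Mapping, Sequence

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .engine import _resolve_changes, cascade
from .errors import FieldValidationError, UnparameterizedPathwayError
from .types import (
    CascadeResult,
    CascadeStep,
    CoverageScenario,
    InterventionSpec,
    MortalityEnvelope,
)

DEFAULT_STUNTING_STRATA = ("haz>=-1", "-1>haz>=-2", "-2>haz>=-3", "haz<-3")


class IncidenceState(BaseModel):
    """Diarrhea incidence: episodes per child-year, optionally by etiology."""

    model_config = ConfigDict(extra="forbid")

    episodes_per_child_year: float = Field(ge=0)
    etiologic_fractions: dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _validate(self) -> "IncidenceState":
        for k, v in self.etiologic_fractions.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"etiologic fraction {k!r}={v} outside [0, 1]")
        return self


class RiskFactorDistribution(BaseModel):
    """Prevalence over ordered severity strata with mortality relative risks.

    The first stratum is the reference and must carry RR exactly 1.
    ``shift_strata`` names the strata whose collective odds move when
    incidence changes (default: every non-reference stratum).
    """

    model_config = ConfigDict(extra="forbid")

    factor: Literal["stunting", "wasting"]
    strata: tuple[str, ...]
    prevalences: tuple[float, ...]
    mortality_rr: tuple[float, ...]
    shift_strata: tuple[str, ...] | None = None

    @model_validator(mode="after")
    def _validate(self) -> "RiskFactorDistribution":
        n = len(self.strata)
        if len(self.prevalences) != n or len(self.mortality_rr) != n:
            raise ValueError("strata, prevalences and mortality_rr must have equal length")
        if n == 0:
            raise ValueError("at least one stratum required")
        if abs(sum(self.prevalences) - 1.0) > 1e-9:
            raise ValueError(f"prevalences sum to {sum(self.prevalences)!r}, not 1")
        if any(p < 0 for p in self.prevalences):
            raise ValueError("prevalences must be non-negative")
        if any(r < 0 for r in self.mortality_rr):
            raise ValueError("relative risks must be non-negative")
        if self.mortality_rr[0] != 1.0:
            raise ValueError(
                f"reference stratum {self.strata[0]!r} must have RR exactly 1, "
                f"got {self.mortality_rr[0]}"
            )
        if self.shift_strata is not None:
            unknown = set(self.shift_strata) - set(self.strata)
            if unknown:
                raise ValueError(f"shift_strata not in strata: {sorted(unknown)}")
        return self

    def shifted_indices(self) -> list[int]:
        if self.shift_strata is None:
            return list(range(1, len(self.strata)))
        return [i for i, s in enumerate(self.strata) if s in self.shift_strata]

    def weighted_rr(self) -> float:
        return sum(p * r for p, r in zip(self.prevalences, self.mortality_rr))


class EtiologyFractionTable(BaseModel):
    """Fractions of diarrhea deaths by etiologic agent, tagged by region.

    Regional defaults, overridable with country data where available.
    """

    model_config = ConfigDict(extra="forbid")

    region: str = "default"
    fractions: dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _validate(self) -> "EtiologyFractionTable":
        for k, v in self.fractions.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"etiology fraction {k!r}={v} outside [0, 1]")
        return self


def incidence_multiplier(
    specs: Iterable[InterventionSpec],
    scenario: CoverageScenario | Mapping[str, float],
    year: int = 2015,
) -> float:
    """Combined multiplier on episodes per child-year.

    Each incidence-linked intervention removes
    ``incidence_efficacy x incidence_affected_fraction x coverage_change``
    of episodes; effects compound multiplicatively (order-free), so with no
    incidence-linked interventions the multiplier is exactly 1.
    """
    mult = 1.0
    for spec in specs:
        if isinstance(scenario, CoverageScenario):
            delta = scenario.change(spec.name, year)
        else:
            delta = float(scenario.get(spec.name, 0.0))
        if not (0.0 <= delta <= 1.0):
            raise FieldValidationError("coverage_change", delta, "must be in [0, 1]")
        mult *= 1.0 - spec.incidence_efficacy * spec.incidence_affected_fraction * delta
    return mult


def stunting_shift_from_incidence(
    baseline: RiskFactorDistribution,
    incidence: IncidenceState,
    incidence_mult: float,
    odds_per_episode: float | None,
) -> RiskFactorDistribution:
    """Shift a stunting distribution in response to an incidence change.

    The collective odds of the shifted (stunted) strata scale by
    ``odds_per_episode ** delta_episodes`` where ``delta_episodes`` is the
    change in episodes per child-year implied by ``incidence_mult``. Within
    the shifted and unshifted groups, relative shares are preserved and the
    result renormalizes to 1. ``incidence_mult = 1`` or
    ``odds_per_episode = 1`` are both identities.
    """
    if incidence_mult == 1.0:
        return baseline
    if odds_per_episode is None:
        raise UnparameterizedPathwayError(
            "the incidence->stunting pathway requires odds_per_episode "
            "(pathway_params.odds_per_episode); refusing a silent default"
        )
    if odds_per_episode <= 0:
        raise FieldValidationError("odds_per_episode", odds_per_episode, "must be > 0")
    if odds_per_episode == 1.0:
        return baseline

    delta_episodes = incidence.episodes_per_child_year * (incidence_mult - 1.0)
    idx = baseline.shifted_indices()
    p = sum(baseline.prevalences[i] for i in idx)
    if p <= 0.0 or p >= 1.0:
        return baseline  # no mass to move in or out of the stunted group
    odds = p / (1.0 - p) * odds_per_episode**delta_episodes
    p_new = odds / (1.0 + odds)

    scale_in = p_new / p
    scale_out = (1.0 - p_new) / (1.0 - p)
    new_prev = tuple(
        q * (scale_in if i in idx else scale_out) for i, q in enumerate(baseline.prevalences)
    )
    total = sum(new_prev)
    new_prev = tuple(q / total for q in new_prev)
    return baseline.model_copy(update={"prevalences": new_prev})


def mortality_multiplier_from_shift(
    before: RiskFactorDistribution, after: RiskFactorDistribution
) -> float:
    """Ratio of prevalence-weighted mean RRs, after over before.

    Applied multiplicatively to the mortality envelope before the treatment
    cascade; 1 on identical distributions, and invariant to rescaling all
    RRs (apart from the reference-stratum normalization).
    """
    if before.factor != after.factor or before.strata != after.strata:
        raise FieldValidationError(
            "strata", (before.factor, after.factor), "distributions must share factor and strata"
        )
    return after.weighted_rr() / before.weighted_rr()


def deficiency_affected_fraction(
    intervention: InterventionSpec, deficiency_prevalence: float
) -> InterventionSpec:
    """Restrict an intervention to the deficient share of the population.

    Micronutrient interventions (vitamin A, preventive zinc) only benefit
    children at risk of the deficiency; the regional deficiency prevalence
    becomes the intervention's affected fraction, leaving the cascade math
    unchanged.
    """
    if not (0.0 <= deficiency_prevalence <= 1.0):
        raise FieldValidationError(
            "deficiency_prevalence", deficiency_prevalence, "must be in [0, 1]"
        )
    return intervention.model_copy(update={"affected_fraction": deficiency_prevalence})


def register_custom_intervention(
    name: str,
    *,
    role: str = "prevention",
    efficacy: float | None = None,
    incidence_efficacy: float | None = None,
    etiology: str | None = None,
    etiology_table: EtiologyFractionTable | None = None,
    age_band_months: tuple[int, int] = (1, 59),
) -> InterventionSpec:
    """Build a user-defined intervention (e.g. a new vaccine).

    At least one outcome link — direct mortality ``efficacy`` or
    ``incidence_efficacy`` — must be given. If ``etiology`` is named, the
    intervention acts only on that agent's share of diarrhea deaths: the
    etiology's death fraction becomes the affected fraction.
    """
    if efficacy is None and incidence_efficacy is None:
        raise FieldValidationError(
            "links", name, "a custom intervention needs at least one outcome link "
            "(efficacy and/or incidence_efficacy)"
        )
    affected = 1.0
    if etiology is not None:
        if etiology_table is None or etiology not in etiology_table.fractions:
            raise FieldValidationError(
                "etiology", etiology, "not present in the etiology fraction table"
            )
        affected = etiology_table.fractions[etiology]
    return InterventionSpec(
        name=name,
        role=role,  # type: ignore[arg-type]
        efficacy=efficacy or 0.0,
        affected_fraction=affected,
        incidence_efficacy=incidence_efficacy or 0.0,
        age_band_months=age_band_months,
    )


def dummy_vaccine_templates() -> dict[str, dict]:
    """Blank templates for hypothetical vaccines ('vaccine B', 'vaccine C').

    Links and efficacy values are left blank; passing a template unchanged
    to :func:`register_custom_intervention` is rejected until the user
    defines its links.
    """
    return {
        name: {"name": name, "role": "prevention", "efficacy": None,
               "incidence_efficacy": None, "etiology": None}
        for name in ("vaccine_b", "vaccine_c")
    }


class PipelineResult(BaseModel):
    """One year of the full direct + indirect pipeline."""

    model_config = ConfigDict(extra="forbid")

    cascade: CascadeResult
    incidence_multiplier: float
    stunting_after: RiskFactorDistribution | None = None
    stunting_mortality_multiplier: float = 1.0

    @property
    def residual_deaths(self) -> float:
        return self.cascade.residual_deaths


def run_pipeline(
    envelope: MortalityEnvelope,
    specs: Sequence[InterventionSpec],
    scenario: CoverageScenario | Mapping[str, float],
    *,
    incidence: IncidenceState | None = None,
    stunting: RiskFactorDistribution | None = None,
    odds_per_episode: float | None = None,
    strict: bool = False,
) -> PipelineResult:
    """Run the full yearly pipeline: prevention, stunting shift, treatment.

    With the indirect pathway neutral (no stunting distribution, or
    ``odds_per_episode = 1``, or all RRs 1) this reproduces the direct-only
    cascade exactly.
    """
    prevention = [s for s in specs if s.role == "prevention"]
    treatment = [s for s in specs if s.role == "treatment"]
    changes = _resolve_changes(list(specs), scenario, envelope.year)

    prev_changes = {s.name: changes[s.name] for s in prevention}
    treat_changes = {s.name: changes[s.name] for s in treatment}
    prev_result = cascade(envelope, prevention, prev_changes, strict=strict)
    inc_mult = incidence_multiplier(prevention, prev_changes, envelope.year)

    stunting_after = None
    mort_mult = 1.0
    if stunting is not None and inc_mult != 1.0:
        if incidence is None:
            raise UnparameterizedPathwayError(
                "stunting pathway requires a baseline IncidenceState"
            )
        stunting_after = stunting_shift_from_incidence(
            stunting, incidence, inc_mult, odds_per_episode
        )
        mort_mult = mortality_multiplier_from_shift(stunting, stunting_after)

    residual_after_indirect = prev_result.residual_deaths * mort_mult
    indirect_averted = prev_result.residual_deaths - residual_after_indirect

    treat_env = MortalityEnvelope(year=envelope.year, diarrhea_deaths=residual_after_indirect)
    treat_result = cascade(treat_env, treatment, treat_changes, strict=strict)

    steps = list(prev_result.averted_by_step)
    if stunting_after is not None:
        steps.append(CascadeStep(intervention="_stunting_pathway", averted=indirect_averted))
    steps.extend(treat_result.averted_by_step)

    combined = CascadeResult(
        year=envelope.year,
        baseline_deaths=envelope.diarrhea_deaths,
        residual_deaths=treat_result.residual_deaths,
        averted_by_step=steps,
    )
    return PipelineResult(
        cascade=combined,
        incidence_multiplier=inc_mult,
        stunting_after=stunting_after,
        stunting_mortality_multiplier=mort_mult,
    )
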