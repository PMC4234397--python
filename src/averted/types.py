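"""Domain types for the deaths-averted cascade.

The model operates on one cause of death (diarrhea) in one age window
(children 1-59 months). Its primitives are:

* a :class:`MortalityEnvelope` — the annual baseline death count the
  cascade depletes;
* an :class:`InterventionSpec` — one intervention's cause-specific
  efficacy, the fraction of deaths it can mechanistically act on (the
  *affected fraction*), its cascade role (prevention acts before
  treatment), and an optional link to diarrhea incidence;
* a :class:`CoverageScenario` — per-intervention baseline and target
  coverage by calendar year; the engine scales effects by the coverage
  *change*;
* a :class:`CascadeResult` — residual deaths plus a per-step attribution.

All rates are fractions in [0, 1] internally; percent appears only in
file IO (with an explicit unit tag) and in rendered reports.
"""

from __future__ import annotations

from typing import Iterable, Literal, Mapping

from pydantic import BaseModel, ConfigDict, Field, model_validator

Role = Literal["prevention", "treatment"]


class MortalityEnvelope(BaseModel):
    """Annual diarrhea deaths among children 1-59 months."""

    model_config = ConfigDict(extra="forbid")

    year: int = 2015
    diarrhea_deaths: float = Field(ge=0)


class InterventionSpec(BaseModel):
    """One intervention's effect profile.

    ``efficacy`` is the proportional reduction in diarrhea-specific
    mortality at full coverage *among the affected fraction*;
    ``affected_fraction`` is the share of diarrhea deaths the intervention
    can act on (etiology- or deficiency-specific; 1 means all deaths).
    ``incidence_efficacy`` (with its own affected fraction of incidence)
    drives the indirect stunting pathway and episode counts; it is 0 for
    interventions with no incidence link.
    """

    model_config = ConfigDict(extra="forbid")

    name: str
    role: Role = "prevention"
    efficacy: float = Field(default=0.0, ge=0, le=1)
    affected_fraction: float = Field(default=1.0, ge=0, le=1)
    incidence_efficacy: float = Field(default=0.0, ge=0, le=1)
    incidence_affected_fraction: float = Field(default=1.0, ge=0, le=1)
    age_band_months: tuple[int, int] = (1, 59)
    notes: str | None = None

    @model_validator(mode="after")
    def _check_band(self) -> "InterventionSpec":
        lo, hi = self.age_band_months
        if not (0 <= lo < hi):
            raise ValueError(f"age_band_months={self.age_band_months} must be an increasing month range")
        return self


class CoverageEntry(BaseModel):
    model_config = ConfigDict(extra="forbid")

    intervention: str
    year: int
    baseline_coverage: float = Field(ge=0, le=1)
    target_coverage: float = Field(ge=0, le=1)

    @property
    def change(self) -> float:
        return self.target_coverage - self.baseline_coverage


class CoverageScenario(BaseModel):
    """Per-intervention coverage by year.

    An intervention absent from the scenario for a given year contributes a
    coverage change of 0 (it is held constant, not an error); an intervention
    present in the scenario but unknown to the parameter set is an error,
    raised by the engine at run time.
    """

    model_config = ConfigDict(extra="forbid")

    entries: list[CoverageEntry] = Field(default_factory=list)

    @model_validator(mode="after")
    def _no_duplicates(self) -> "CoverageScenario":
        seen = set()
        for e in self.entries:
            key = (e.intervention, e.year)
            if key in seen:
                raise ValueError(f"duplicate scenario entry for {key}")
            seen.add(key)
        return self

    def change(self, intervention: str, year: int) -> float:
        for e in self.entries:
            if e.intervention == intervention and e.year == year:
                return e.change
        return 0.0

    def years(self) -> list[int]:
        return sorted({e.year for e in self.entries})

    def interventions(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e.intervention not in out:
                out.append(e.intervention)
        return out

    @classmethod
    def from_changes(cls, changes: Mapping[str, float], year: int = 2015) -> "CoverageScenario":
        """Build a single-year scenario from coverage *changes* (baseline 0)."""
        return cls(
            entries=[
                CoverageEntry(
                    intervention=name, year=year, baseline_coverage=0.0, target_coverage=delta
                )
                for name, delta in changes.items()
            ]
        )


class CascadeStep(BaseModel):
    model_config = ConfigDict(extra="forbid")

    intervention: str
    averted: float


class CascadeResult(BaseModel):
    """Outcome of one year's cascade over one envelope."""

    model_config = ConfigDict(extra="forbid")

    year: int
    baseline_deaths: float
    residual_deaths: float
    averted_by_step: list[CascadeStep] = Field(default_factory=list)

    @property
    def total_averted(self) -> float:
        return self.baseline_deaths - self.residual_deaths


def order_for_cascade(specs: Iterable[InterventionSpec]) -> list[InterventionSpec]:
    """Stable prevention-before-treatment ordering.

    Input order is preserved within each role group; the residual is a
    commutative product so the ordering only matters for per-step
    attribution labels.
    """
    specs = list(specs)
    return [s for s in specs if s.role == "prevention"] + [
        s for s in specs if s.role == "treatment"
    ]
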