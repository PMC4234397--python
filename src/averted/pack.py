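"""Parameter packs: the structured config that drives a run.

A pack bundles the intervention catalogue, breastfeeding patterns and
relative risks, etiology fractions, risk-factor distributions and
pathway parameters, under a versioned schema. Files may declare values
in percent or fractions — once per file, never mixed — and are
normalized to fractions on load.

``reference_pack()`` builds the bundled defaults: the handful of
effect sizes this model ships with (zinc treatment 23%; dysentery
antibiotics 99% on a 3.9% affected fraction; rotavirus incidence
reduction 50%; ORS 69% mortality reduction observed at 74% coverage,
extrapolated linearly to full coverage). Everything else — regional
etiology fractions, deficiency prevalences, breastfeeding and stunting
relative risks, the incidence-to-stunting odds parameter — is
user-supplied, and the corresponding pathways stay inert or error
loudly until it is.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .breastfeeding import BreastfeedingPattern, PromotionEffect
from .engine import linear_effectiveness_at_coverage
from .errors import PackValidationError
from .pathways import EtiologyFractionTable, IncidenceState, RiskFactorDistribution
from .types import InterventionSpec

SCHEMA_VERSION = 1

# Fields that carry rates: scaled by 1/100 when a file declares units: percent.
_PERCENT_SCALAR_KEYS = frozenset(
    {
        "efficacy",
        "affected_fraction",
        "incidence_efficacy",
        "incidence_affected_fraction",
        "baseline_coverage",
        "target_coverage",
        "promotion_coverage",
        "episodes_per_child_year_change",
    }
)
_PERCENT_MAP_KEYS = frozenset({"prevalences", "fractions", "etiologic_fractions"})


class PathwayParams(BaseModel):
    model_config = ConfigDict(extra="forbid")

    odds_per_episode: float | None = Field(default=None, gt=0)


class BreastfeedingSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    patterns: list[BreastfeedingPattern] = Field(default_factory=list)
    # band -> category -> relative risk of diarrhea death; defaults of 1.0
    # keep the pathway inert until the user supplies evidence-based values
    mortality_rr: dict[str, dict[str, float]] = Field(default_factory=dict)
    promotion: PromotionEffect | None = None


class CustomInterventionDef(BaseModel):
    """A user-defined intervention as declared in a pack (may be blank)."""

    model_config = ConfigDict(extra="forbid")

    name: str
    role: str = "prevention"
    efficacy: float | None = None
    incidence_efficacy: float | None = None
    etiology: str | None = None
    age_band_months: tuple[int, int] = (1, 59)


class ParameterPack(BaseModel):
    model_config = ConfigDict(extra="forbid")

    schema_version: int = SCHEMA_VERSION
    units: str = "fraction"
    interventions: list[InterventionSpec] = Field(default_factory=list)
    breastfeeding: BreastfeedingSection = Field(default_factory=BreastfeedingSection)
    etiology_fractions: EtiologyFractionTable | None = None
    risk_factors: list[RiskFactorDistribution] = Field(default_factory=list)
    incidence: IncidenceState | None = None
    pathway_params: PathwayParams = Field(default_factory=PathwayParams)
    custom_interventions: list[CustomInterventionDef] = Field(default_factory=list)

    def intervention(self, name: str) -> InterventionSpec:
        for spec in self.interventions:
            if spec.name == name:
                return spec
        raise KeyError(name)

    def names(self) -> set[str]:
        return {s.name for s in self.interventions}


def _scale_percents(node: Any, parent_key: str | None = None) -> Any:
    """Recursively divide percent-declared rate fields by 100."""
    if isinstance(node, dict):
        out = {}
        for key, value in node.items():
            if key in _PERCENT_SCALAR_KEYS and isinstance(value, (int, float)):
                out[key] = _pct(value, key)
            elif key in _PERCENT_MAP_KEYS and isinstance(value, dict):
                out[key] = {k: _pct(v, f"{key}.{k}") for k, v in value.items()}
            elif key == "prevalences" and isinstance(value, (list, tuple)):
                out[key] = [_pct(v, key) for v in value]
            else:
                out[key] = _scale_percents(value, key)
        return out
    if isinstance(node, list):
        return [_scale_percents(v, parent_key) for v in node]
    return node


def _pct(value: float, label: str) -> float:
    if value > 100.0 or value < 0.0:
        raise PackValidationError([f"/{label}: percent value {value} outside [0, 100]"])
    return value / 100.0


def _pointer_errors(exc: ValidationError) -> list[str]:
    out = []
    for err in exc.errors():
        path = "/" + "/".join(str(p) for p in err["loc"])
        out.append(f"{path}: {err['msg']}")
    return out


def pack_from_dict(raw: dict) -> ParameterPack:
    """Validate a raw mapping into a pack, normalizing percent units."""
    if not isinstance(raw, dict):
        raise PackValidationError(["/: pack must be a mapping"])
    units = raw.get("units", "fraction")
    if units not in ("fraction", "percent"):
        raise PackValidationError([f"/units: must be 'fraction' or 'percent', got {units!r}"])
    if units == "percent":
        raw = _scale_percents({k: v for k, v in raw.items() if k != "units"})
        raw["units"] = "fraction"
    try:
        pack = ParameterPack.model_validate(raw)
    except ValidationError as exc:
        raise PackValidationError(_pointer_errors(exc)) from exc
    _check_cross_references(pack)
    return pack


def _check_cross_references(pack: ParameterPack) -> None:
    problems = []
    known_etiologies = set(pack.etiology_fractions.fractions) if pack.etiology_fractions else set()
    for custom in pack.custom_interventions:
        if custom.etiology is not None and custom.etiology not in known_etiologies:
            problems.append(
                f"/custom_interventions/{custom.name}/etiology: "
                f"{custom.etiology!r} not in etiology_fractions"
            )
    if problems:
        raise PackValidationError(problems)


def load_parameter_pack(path: str | Path) -> ParameterPack:
    """Load and validate a pack from YAML or JSON."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise PackValidationError([f"/: file does not parse as YAML/JSON: {exc}"]) from exc
    return pack_from_dict(raw)


def save_parameter_pack(pack: ParameterPack, path: str | Path) -> None:
    """Write a pack (always in fraction units, stable key order)."""
    path = Path(path)
    payload = pack.model_dump(mode="json")
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=True), encoding="utf-8")
    else:
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def pack_digest(pack: ParameterPack) -> str:
    import hashlib

    canon = json.dumps(pack.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


# Observed ORS community effectiveness: 69% mortality reduction at 74% coverage.
ORS_OBSERVED_EFFECT = 0.69
ORS_OBSERVED_COVERAGE = 0.74


def reference_pack() -> ParameterPack:
    """The bundled default parameter pack.

    Carries only the model's core published effect sizes; regional and
    evidence-supplement quantities are left for the user (see module
    docstring). The ORS full-coverage effectiveness is derived at build
    time from the observed (effect, coverage) pair by linear extrapolation.
    """
    ors_full = linear_effectiveness_at_coverage(ORS_OBSERVED_EFFECT, ORS_OBSERVED_COVERAGE, 1.0)
    return ParameterPack(
        interventions=[
            InterventionSpec(
                name="rotavirus_vaccine",
                role="prevention",
                efficacy=0.0,
                incidence_efficacy=0.5,
                notes=(
                    "Direct mortality efficacy and the rotavirus affected fraction "
                    "are region-specific and user-supplied; only the 50% reduction "
                    "in rotavirus diarrhea incidence ships as a default. Set "
                    "incidence_affected_fraction to the rotavirus share of incidence."
                ),
            ),
            InterventionSpec(
                name="zinc_treatment",
                role="treatment",
                efficacy=0.23,
                notes="Effectiveness of therapeutic zinc on diarrhea mortality.",
            ),
            InterventionSpec(
                name="ors",
                role="treatment",
                efficacy=ors_full,
                notes=(
                    f"Linear extrapolation to 100% coverage of a "
                    f"{ORS_OBSERVED_EFFECT:.0%} mortality reduction observed at "
                    f"{ORS_OBSERVED_COVERAGE:.0%} coverage."
                ),
            ),
            InterventionSpec(
                name="antibiotics_dysentery",
                role="treatment",
                efficacy=0.99,
                affected_fraction=0.039,
                notes=(
                    "99% clinical effectiveness against Shigella dysentery, acting "
                    "on the 3.9% of diarrhea deaths attributable to Shigella."
                ),
            ),
        ],
        etiology_fractions=EtiologyFractionTable(
            region="default", fractions={"dysentery": 0.039}
        ),
        custom_interventions=[
            CustomInterventionDef(name="vaccine_b"),
            CustomInterventionDef(name="vaccine_c"),
        ],
    )
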