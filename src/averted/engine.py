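"""Deterministic residual-deaths cascade.

The core arithmetic of the model: the deaths an intervention averts are

    averted = deaths x efficacy x affected_fraction x coverage_change

and interventions in a package are applied sequentially, each to the
*residual* deaths left by those before it, so that no death is counted
twice:

    residual = D x prod_i (1 - e_i * AF_i * dc_i)

The product is commutative, so the residual does not depend on
intervention order; the prevention-before-treatment convention only
determines which step each averted death is attributed to.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from .errors import FieldValidationError, UndefinedSlopeError, UnknownInterventionError
from .types import (
    CascadeResult,
    CascadeStep,
    CoverageScenario,
    InterventionSpec,
    MortalityEnvelope,
    order_for_cascade,
)

__all__ = [
    "deaths_averted_single",
    "cascade",
    "linear_effectiveness_at_coverage",
    "attribute_by_isolation",
    "coverage_linearity_ratio",
    "AttributionResult",
]


def deaths_averted_single(
    deaths: float,
    spec: InterventionSpec,
    coverage_change: float,
    *,
    allow_decline: bool = False,
) -> float:
    """Deaths averted by one intervention acting alone.

    Parameters
    ----------
    deaths
        Cause-specific deaths the intervention is applied to (>= 0).
    spec
        The intervention's efficacy, affected fraction and role.
    coverage_change
        Change in coverage, target minus baseline, in [0, 1]. A coverage
        decline (negative change, yielding *added* deaths) is rejected
        unless ``allow_decline`` is set.

    Returns
    -------
    float
        ``deaths * efficacy * affected_fraction * coverage_change``;
        never exceeds ``deaths``.
    """
    if deaths < 0:
        raise FieldValidationError("deaths", deaths, "must be >= 0")
    lo = -1.0 if allow_decline else 0.0
    if not (lo <= coverage_change <= 1.0):
        bound = "[-1, 1]" if allow_decline else "[0, 1]"
        raise FieldValidationError("coverage_change", coverage_change, f"must be in {bound}")
    return deaths * spec.efficacy * spec.affected_fraction * coverage_change


def _resolve_changes(
    specs: Sequence[InterventionSpec],
    scenario: CoverageScenario | Mapping[str, float] | None,
    year: int,
) -> dict[str, float]:
    if scenario is None:
        return {s.name: 0.0 for s in specs}
    if isinstance(scenario, CoverageScenario):
        known = {s.name for s in specs}
        referenced = {e.intervention for e in scenario.entries if e.year == year}
        unknown = referenced - known
        if unknown:
            raise UnknownInterventionError(unknown)
        return {s.name: scenario.change(s.name, year) for s in specs}
    # plain mapping name -> coverage change
    unknown = set(scenario) - {s.name for s in specs}
    if unknown:
        raise UnknownInterventionError(unknown)
    return {s.name: float(scenario.get(s.name, 0.0)) for s in specs}


def cascade(
    envelope: MortalityEnvelope,
    specs: Iterable[InterventionSpec],
    scenario: CoverageScenario | Mapping[str, float] | None = None,
    *,
    strict: bool = False,
    residual_ceiling: float | None = None,
) -> CascadeResult:
    """Apply a package of interventions to an annual mortality envelope.

    Interventions are ordered prevention first (stable within role) and each
    acts on the residual deaths left by its predecessors. An empty package
    returns the envelope unchanged. ``scenario`` may be a
    :class:`CoverageScenario` (looked up at ``envelope.year``) or a plain
    ``{name: coverage_change}`` mapping.

    ``strict`` rejects coverage declines; otherwise a decline yields a
    negative averted count (added deaths), and ``residual_ceiling`` — when
    given — caps how far the residual may grow above baseline.
    """
    ordered = order_for_cascade(specs)
    changes = _resolve_changes(ordered, scenario, envelope.year)

    residual = float(envelope.diarrhea_deaths)
    steps: list[CascadeStep] = []
    for spec in ordered:
        delta = changes[spec.name]
        averted = deaths_averted_single(residual, spec, delta, allow_decline=not strict)
        residual -= averted
        if residual_ceiling is not None and residual > residual_ceiling:
            averted += residual - residual_ceiling
            residual = residual_ceiling
        steps.append(CascadeStep(intervention=spec.name, averted=averted))
    return CascadeResult(
        year=envelope.year,
        baseline_deaths=envelope.diarrhea_deaths,
        residual_deaths=residual,
        averted_by_step=steps,
    )


def linear_effectiveness_at_coverage(
    observed_effect: float, observed_coverage: float, target_coverage: float
) -> float:
    """Extrapolate an observed mortality reduction linearly in coverage.

    Community effectiveness studies report a relative mortality reduction at
    the coverage their program achieved; the model assumes a linear trend
    through the origin, so effectiveness at another coverage is
    ``observed_effect * target_coverage / observed_coverage``, clamped to 1.
    """
    if not (0 <= observed_effect <= 1):
        raise FieldValidationError("observed_effect", observed_effect, "must be in [0, 1]")
    if observed_coverage == 0:
        raise UndefinedSlopeError(
            "observed_coverage is 0: the effect-per-coverage slope is undefined"
        )
    if not (0 < observed_coverage <= 1):
        raise FieldValidationError("observed_coverage", observed_coverage, "must be in (0, 1]")
    if not (0 <= target_coverage <= 1):
        raise FieldValidationError("target_coverage", target_coverage, "must be in [0, 1]")
    return min(1.0, observed_effect * target_coverage / observed_coverage)


class AttributionResult(dict):
    """Per-intervention isolated averted deaths, plus the package total.

    Maps intervention name -> deaths averted when run *alone* at its
    scenario coverage. Because isolated runs each start from the full
    baseline while the package applies interventions to residuals, the sum
    of isolated effects generally exceeds ``package_total``.
    """

    def __init__(self, isolated: Mapping[str, float], package_total: float):
        super().__init__(isolated)
        self.package_total = float(package_total)

    @property
    def isolated_total(self) -> float:
        return sum(self.values())


def attribute_by_isolation(
    envelope: MortalityEnvelope,
    specs: Iterable[InterventionSpec],
    scenario: CoverageScenario | Mapping[str, float] | None = None,
    *,
    strict: bool = False,
) -> AttributionResult:
    """Attribute deaths averted by running each intervention in isolation.

    The package output does not attribute deaths to single interventions
    (the cascade deliberately entangles them), so per-intervention
    contributions are estimated by re-running the model with one
    intervention at a time and comparing against the full-package total.
    """
    specs = list(specs)
    full = cascade(envelope, specs, scenario, strict=strict)
    changes = _resolve_changes(specs, scenario, envelope.year)
    isolated = {
        s.name: cascade(envelope, [s], {s.name: changes[s.name]}, strict=strict).total_averted
        for s in specs
    }
    return AttributionResult(isolated, full.total_averted)


def coverage_linearity_ratio(
    spec: InterventionSpec, coverage_hi: float, coverage_lo: float
) -> float:
    """Ratio of deaths averted at ``coverage_lo`` vs ``coverage_hi``.

    The single-intervention formula is linear in coverage change, so the
    ratio is exactly ``coverage_lo / coverage_hi`` whenever the intervention
    has any effect; halving coverage halves the deaths prevented.
    """
    if coverage_hi <= 0:
        raise FieldValidationError("coverage_hi", coverage_hi, "must be > 0")
    hi = deaths_averted_single(1.0, spec, coverage_hi)
    lo = deaths_averted_single(1.0, spec, coverage_lo)
    if hi == 0.0:  # inert intervention: fall back to the analytic ratio
        return coverage_lo / coverage_hi
    return lo / hi
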