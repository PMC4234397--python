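"""Breastfeeding patterns, promotion, and the breastfeeding risk factor.

Feeding practice is tracked in four age bands. Under six months the
categories are the four degrees of breastfeeding — exclusive,
predominant, partial, none — and the optimal practice is exclusive
breastfeeding. From 6 to 23 months the distinction is simply any
(continued) breastfeeding versus none, and any is optimal.

Breastfeeding promotion raises the optimal category's prevalence; the
remaining sub-optimal mass is redistributed over the sub-optimal
categories *in proportion to their shares before promotion*. Sub-optimal
feeding then enters mortality as a risk factor via per-category relative
risks (optimal category RR = 1).
"""

from __future__ import annotations

import warnings
from typing import Literal, Mapping

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import DegenerateDistributionError, FieldValidationError

AgeBand = Literal["0-1", "1-5", "6-11", "12-23"]

UNDER6_CATEGORIES = ("exclusive", "predominant", "partial", "none")
OVER6_CATEGORIES = ("any", "none")

_SUM_TOL = 1e-9


def categories_for_band(age_band: AgeBand) -> tuple[str, ...]:
    return UNDER6_CATEGORIES if age_band in ("0-1", "1-5") else OVER6_CATEGORIES


def optimal_category(age_band: AgeBand) -> str:
    """Exclusive under 6 months; any/continued at 6-23 months."""
    return "exclusive" if age_band in ("0-1", "1-5") else "any"


class BreastfeedingPattern(BaseModel):
    """Prevalence distribution over feeding categories in one age band."""

    model_config = ConfigDict(extra="forbid")

    age_band: AgeBand
    prevalences: dict[str, float]

    @model_validator(mode="after")
    def _validate(self) -> "BreastfeedingPattern":
        expected = categories_for_band(self.age_band)
        if tuple(self.prevalences) != expected:
            raise ValueError(
                f"age band {self.age_band} requires categories {expected}, "
                f"got {tuple(self.prevalences)}"
            )
        for cat, p in self.prevalences.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"prevalence of {cat!r} is {p}, outside [0, 1]")
        total = sum(self.prevalences.values())
        if abs(total - 1.0) > _SUM_TOL:
            raise ValueError(f"prevalences sum to {total!r}, not 1")
        return self

    @property
    def optimal(self) -> float:
        return self.prevalences[optimal_category(self.age_band)]


class PromotionEffect(BaseModel):
    """Effect of breastfeeding promotion on the optimal category.

    ``relative_risk`` mode scales the baseline optimal prevalence by the
    relative risk of appropriate breastfeeding given promotion, weighted by
    the change in promotion coverage; ``target_rate`` mode moves the optimal
    prevalence toward an explicit target rate (users directly changing the
    rates are modelled this way).
    """

    model_config = ConfigDict(extra="forbid")

    mode: Literal["relative_risk", "target_rate"]
    value: float = Field(gt=0)
    promotion_coverage: float = Field(default=1.0, ge=0, le=1)

    @model_validator(mode="after")
    def _validate(self) -> "PromotionEffect":
        if self.mode == "target_rate" and self.value > 1.0:
            raise ValueError(f"target_rate value {self.value} must be in (0, 1]")
        return self

    def promoted_rate(self, baseline_optimal: float) -> float:
        if self.mode == "target_rate":
            rate = baseline_optimal + (self.value - baseline_optimal) * self.promotion_coverage
        else:
            rate = baseline_optimal + (self.value - 1.0) * baseline_optimal * self.promotion_coverage
        if rate > 1.0:
            warnings.warn(
                f"promoted appropriate-breastfeeding rate {rate:.4f} exceeds 1; capped",
                stacklevel=3,
            )
            rate = 1.0
        return max(rate, 0.0)


def apply_promotion(pattern: BreastfeedingPattern, effect: PromotionEffect) -> BreastfeedingPattern:
    """Shift a pattern under breastfeeding promotion.

    The optimal category moves to the promoted rate; the remaining mass is
    split over the sub-optimal categories in proportion to their baseline
    shares, so their ratios to one another are preserved.
    """
    opt = optimal_category(pattern.age_band)
    promoted = effect.promoted_rate(pattern.optimal)

    sub = {c: p for c, p in pattern.prevalences.items() if c != opt}
    sub_mass = sum(sub.values())
    remaining = 1.0 - promoted

    if sub_mass <= 0.0:
        if remaining > _SUM_TOL:
            raise DegenerateDistributionError(
                "baseline has no sub-optimal mass to redistribute but the "
                f"promoted optimal rate is {promoted:.4f} < 1"
            )
        shifted = {c: 0.0 for c in sub}
    else:
        shifted = {c: p * remaining / sub_mass for c, p in sub.items()}

    new = {c: (promoted if c == opt else shifted[c]) for c in pattern.prevalences}
    # guard against float drift before re-validation
    total = sum(new.values())
    new = {c: p / total for c, p in new.items()}
    return BreastfeedingPattern(age_band=pattern.age_band, prevalences=new)


def pattern_mortality_multiplier(
    before: BreastfeedingPattern,
    after: BreastfeedingPattern,
    rrs: Mapping[str, float],
) -> float:
    """Mortality multiplier from a breastfeeding pattern shift.

    ``rrs`` maps each category to its relative risk of diarrhea death, with
    the optimal category normalized to 1. The multiplier is the ratio of
    prevalence-weighted mean relative risks after versus before the shift,
    and is applied to diarrhea deaths in the band. Identical patterns give
    exactly 1; the ratio is invariant to rescaling all RRs by a constant.
    """
    if before.age_band != after.age_band:
        raise FieldValidationError(
            "age_band", (before.age_band, after.age_band), "patterns must share an age band"
        )
    missing = [c for c in before.prevalences if c not in rrs]
    if missing:
        raise FieldValidationError("rrs", missing, "missing relative risk for category")
    num = sum(after.prevalences[c] * rrs[c] for c in after.prevalences)
    den = sum(before.prevalences[c] * rrs[c] for c in before.prevalences)
    return num / den
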