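"""Seeded fixture generator for tests and demos.

Produces random-but-valid model inputs: a parameter pack of synthetic
interventions, a coverage scenario with monotone non-decreasing
scale-up trajectories, and an annual mortality envelope. All randomness
flows from a named seed through a local numpy Generator — no global RNG
state — so the same seed yields byte-identical fixtures.
"""

from __future__ import annotations

import numpy as np

from .pack import ParameterPack
from .types import CoverageEntry, CoverageScenario, InterventionSpec, MortalityEnvelope

__all__ = ["generate_fixture", "worked_example_fixture"]


def generate_fixture(
    seed: int,
    n_interventions: int = 4,
    years: int | tuple[int, ...] = 3,
    *,
    baseline_deaths: float = 10_000.0,
    start_year: int = 2015,
) -> tuple[ParameterPack, CoverageScenario, list[MortalityEnvelope]]:
    """Generate a reproducible (pack, scenario, envelopes) triple.

    ``years`` may be a count (consecutive years from ``start_year``) or an
    explicit tuple of calendar years. Coverage trajectories start from a
    random baseline and rise monotonically toward the final target.
    """
    if n_interventions < 0:
        raise ValueError("n_interventions must be >= 0")
    rng = np.random.default_rng(seed)
    year_list = (
        tuple(range(start_year, start_year + years)) if isinstance(years, int) else tuple(years)
    )

    specs = []
    for i in range(n_interventions):
        role = "prevention" if rng.random() < 0.5 else "treatment"
        has_incidence = role == "prevention" and rng.random() < 0.5
        specs.append(
            InterventionSpec(
                name=f"intervention_{i:02d}",
                role=role,
                efficacy=round(float(rng.uniform(0.05, 0.95)), 6),
                affected_fraction=round(float(rng.uniform(0.05, 1.0)), 6),
                incidence_efficacy=round(float(rng.uniform(0.05, 0.8)), 6) if has_incidence else 0.0,
            )
        )
    pack = ParameterPack(interventions=specs)

    entries = []
    for spec in specs:
        baseline = round(float(rng.uniform(0.0, 0.5)), 6)
        # monotone non-decreasing targets: cumulative increments above baseline
        increments = rng.uniform(0.0, (1.0 - baseline) / max(len(year_list), 1), len(year_list))
        target = baseline
        for year, inc in zip(year_list, increments):
            target = min(1.0, round(target + float(inc), 6))
            entries.append(
                CoverageEntry(
                    intervention=spec.name,
                    year=year,
                    baseline_coverage=baseline,
                    target_coverage=target,
                )
            )
    scenario = CoverageScenario(entries=entries)

    envelopes = [
        MortalityEnvelope(
            year=year,
            diarrhea_deaths=round(float(baseline_deaths * rng.uniform(0.85, 1.15)), 1),
        )
        for year in year_list
    ]
    return pack, scenario, envelopes


def worked_example_fixture() -> tuple[ParameterPack, CoverageScenario, list[MortalityEnvelope]]:
    """The canonical worked example: 10,000 deaths, one 50%-effective vaccine at 50% coverage."""
    pack = ParameterPack(
        interventions=[
            InterventionSpec(name="new_vaccine", role="prevention", efficacy=0.5)
        ]
    )
    scenario = CoverageScenario(
        entries=[
            CoverageEntry(
                intervention="new_vaccine",
                year=2015,
                baseline_coverage=0.0,
                target_coverage=0.5,
            )
        ]
    )
    return pack, scenario, [MortalityEnvelope(year=2015, diarrhea_deaths=10_000)]
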