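"""Deterministic run reports.

A RunReport collects per-year cascade results (sequential attribution),
isolated per-intervention effects, input digests and run metadata, and
writes them as CSV and JSON with stable ordering. Numbers are rounded
only at this layer: deaths render as round-half-up integers, percents to
one decimal; the underlying results keep full precision. Timestamps are
confined to metadata so re-runs produce identical result payloads.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .engine import AttributionResult
from .pack import ParameterPack, pack_digest
from .rounding import round_half_up
from .types import CascadeResult, CoverageScenario

__all__ = ["RunReport", "build_report", "scenario_from_csv", "scenario_to_csv"]

SCENARIO_COLUMNS = ["intervention", "year", "baseline_coverage", "target_coverage"]


def scenario_from_csv(path: str | Path) -> CoverageScenario:
    """Read a scenario CSV (intervention,year,baseline_coverage,target_coverage)."""
    frame = pd.read_csv(path)
    missing = [c for c in SCENARIO_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"scenario CSV missing column(s): {', '.join(missing)}")
    return CoverageScenario.model_validate(
        {"entries": frame[SCENARIO_COLUMNS].to_dict(orient="records")}
    )


def scenario_to_csv(scenario: CoverageScenario, path: str | Path) -> None:
    frame = pd.DataFrame(
        [e.model_dump() for e in scenario.entries], columns=SCENARIO_COLUMNS
    )
    frame.to_csv(path, index=False)


class RunReport(BaseModel):
    model_config = ConfigDict(extra="forbid")

    results: list[CascadeResult]
    isolated: dict[int, dict[str, float]] = Field(default_factory=dict)
    metadata: dict[str, str] = Field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        """Long-form per-step table: year, intervention, averted, residual."""
        rows = []
        for res in self.results:
            running = res.baseline_deaths
            for step in res.averted_by_step:
                running -= step.averted
                rows.append(
                    {
                        "year": res.year,
                        "intervention": step.intervention,
                        "averted": step.averted,
                        "residual": running,
                    }
                )
            if not res.averted_by_step:
                rows.append(
                    {
                        "year": res.year,
                        "intervention": "",
                        "averted": 0.0,
                        "residual": res.residual_deaths,
                    }
                )
        return pd.DataFrame(rows, columns=["year", "intervention", "averted", "residual"])

    def summary(self) -> dict:
        """JSON-ready summary with stable key order; deaths rounded half-up."""
        years = {}
        for res in sorted(self.results, key=lambda r: r.year):
            entry = {
                "baseline_deaths": round_half_up(res.baseline_deaths),
                "residual_deaths": round_half_up(res.residual_deaths),
                "total_averted": round_half_up(res.total_averted),
                "averted_by_step": {
                    s.intervention: round_half_up(s.averted) for s in res.averted_by_step
                },
            }
            if res.year in self.isolated:
                entry["isolated_averted"] = {
                    name: round_half_up(v) for name, v in sorted(self.isolated[res.year].items())
                }
            years[str(res.year)] = entry
        return {"metadata": dict(sorted(self.metadata.items())), "years": years}

    def write(self, out_dir: str | Path, stem: str = "report") -> tuple[Path, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        csv_path = out_dir / f"{stem}.csv"
        json_path = out_dir / f"{stem}.json"
        self.frame().to_csv(csv_path, index=False, float_format="%.6f")
        json_path.write_text(
            json.dumps(self.summary(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        return csv_path, json_path


def build_report(
    pack: ParameterPack,
    scenario: CoverageScenario,
    results: list[CascadeResult],
    isolated: dict[int, AttributionResult] | None = None,
    *,
    timestamp: bool = True,
) -> RunReport:
    metadata = {
        "pack_digest": pack_digest(pack),
        "n_interventions": str(len(pack.interventions)),
        "scenario_years": ",".join(str(y) for y in scenario.years()),
    }
    if timestamp:
        metadata["generated_at"] = datetime.now(timezone.utc).isoformat()
    iso = {year: dict(attr) for year, attr in (isolated or {}).items()}
    return RunReport(results=results, isolated=iso, metadata=metadata)
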