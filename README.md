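# averted

Deterministic deaths-averted modelling for child diarrhea interventions,
in the tradition of the Lives Saved Tool (LiST).

`averted` is for epidemiologists and child-health program planners who
need to project how scaling up the coverage of diarrhea prevention and
treatment interventions — ORS, therapeutic zinc, antibiotics for
dysentery, rotavirus vaccination, breastfeeding promotion — changes
annual diarrhea deaths among children 1–59 months, without waiting for a
mortality impact study.

## The model

The model is linear and deterministic. For a single intervention with
cause-specific efficacy *e*, affected fraction *AF* (the share of
diarrhea deaths it can mechanistically act on), and coverage change
Δ*c*, deaths averted from a baseline envelope *D* are

    averted = D · e · AF · Δc

Interventions in a package are applied sequentially, each to the
*residual* deaths left by those before it (prevention before treatment),
so no death is counted twice:

    residual = D · ∏ᵢ (1 − eᵢ · AFᵢ · Δcᵢ)

The product is commutative: the residual never depends on intervention
order, only the per-step attribution labels do. On top of the direct
cascade sit indirect pathways: breastfeeding promotion shifts feeding
patterns (a mortality risk factor with per-category relative risks),
and incidence-reducing interventions shrink the stunting distribution
(log-odds-linear in episodes per child-year), which lowers mortality
through per-stratum relative risks before the treatment cascade runs.

## Worked example

```python
from averted import InterventionSpec, MortalityEnvelope, cascade

env = MortalityEnvelope(year=2015, diarrhea_deaths=10_000)
vaccine = InterventionSpec(name="new_vaccine", role="prevention", efficacy=0.5)
result = cascade(env, [vaccine], {"new_vaccine": 0.5})
print(result.total_averted, result.residual_deaths)
```

prints `2500.0 7500.0`: a vaccine that is 50% effective against diarrhea
mortality, scaled up to 50% coverage, averts 10,000 × 0.5 × 0.5 = 2,500
deaths and leaves a residual of 7,500 deaths/year. Adding a second,
identical intervention acts on that residual and leaves
10,000 × (1 − 0.25)² = 5,625. The `examples/` directory has one short
script per capability (single interventions, packages with attribution,
breastfeeding promotion, the stunting pathway, file/CLI workflows); each
prints its numbers with a line on what they mean.

A thin CLI wraps the same library:

```
averted fixture --seed 42 --out fixture/
averted run --params fixture/pack.yaml --scenario fixture/scenario.csv \
    --envelope fixture/envelope.csv --out results/
averted attribute ...   # adds per-intervention isolation runs
averted validate --params fixture/pack.yaml
```

Parameter packs are YAML/JSON (percent or fraction units, declared once
per file); scenarios are CSV with columns
`intervention,year,baseline_coverage,target_coverage`; reports are
written as CSV plus a deterministic JSON summary that reconciles
(baseline = residual + averted) every year.

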