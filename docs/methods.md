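# Methods

## Model and assumptions

`averted` is a linear, deterministic model of cause-specific mortality:
it maps changes in intervention coverage to diarrhea deaths averted
among children 1–59 months. Identical inputs always produce identical
outputs. The core assumptions are:

* **One cause, one age window.** Only diarrhea deaths are modelled; no
  secondary cross-cause effects (e.g. a measles vaccine has no effect on
  diarrhea deaths here), no all-cause accounting, no demographic
  projection.
* **Efficacy × coverage scaling.** An intervention's cause-specific
  efficacy is realized in proportion to its coverage *change*
  (target − baseline); at half the coverage, half the deaths are
  prevented. Baseline coverage defaults to 0 so that "introduce a new
  intervention at coverage c" and "coverage change c" coincide.
* **Affected fractions.** Interventions that only act on an
  etiology-specific (Shigella for dysentery antibiotics, rotavirus for
  its vaccine) or deficiency-specific (vitamin A, preventive zinc) share
  of deaths are scaled by that share.
* **Residual cascade, prevention first.** In a package, each
  intervention acts on the residual deaths left by its predecessors,
  which prevents double counting; the residual is a commutative product,
  so ordering matters only for per-step attribution labels. Per-step
  attribution is sequential as literally defined by the cascade; for
  intervention-specific totals, the attribution-by-isolation operation
  re-runs the model with one intervention at a time.
* **Independent coverage.** Coverages of different interventions are
  assumed uncorrelated; strongly correlated scale-up would bias a linear
  model of this kind and is out of scope.
* **Annual time steps.** Each year's cascade starts from that year's
  mortality envelope; there are no within-year dynamics, and risk-factor
  shifts apply in the same year (the model is silent on lags).

## Parameters

All rates are fractions in [0, 1] internally. Files may declare
`units: percent` (once per file, never per field) and are normalized on
load; values above 100 in percent mode are unit errors.

Bundled defaults (`reference_pack()`), all on the intervention scale the
field reports them:

| parameter | default | meaning |
|---|---|---|
| zinc treatment efficacy | 0.23 | reduction in diarrhea mortality at full coverage |
| dysentery antibiotics efficacy | 0.99 | clinical effectiveness against Shigella dysentery |
| dysentery affected fraction | 0.039 | Shigella share of diarrhea deaths |
| rotavirus incidence efficacy | 0.50 | reduction in rotavirus diarrhea incidence |
| ORS observed effect / coverage | 0.69 / 0.74 | community effectiveness at achieved coverage |

The ORS full-coverage effectiveness (≈0.932, reported as 93%) is derived
at pack-build time by linear extrapolation through the origin
(`min(1, effect × target/observed)`), never stored. Everything else —
regional etiology fractions (including the rotavirus death share),
deficiency prevalences, breastfeeding and stunting relative risks, the
incidence→stunting odds parameter — is deliberately user-supplied:
defaults of 1.0 (relative risks) keep a pathway inert, and the stunting
shift raises an explicit unparameterized-pathway error rather than
assuming an effect size.

## Breastfeeding

Feeding patterns live in four age bands: 0–1 and 1–5 months use the four
degrees (exclusive, predominant, partial, none; exclusive optimal), 6–11
and 12–23 months use any/none (any optimal). Promotion moves the optimal
category to its promoted rate — either a target rate, or
`baseline + (RR − 1) × baseline × Δcoverage` in relative-risk mode,
capped at 1 with a warning — and redistributes the remaining mass over
the sub-optimal categories in proportion to their pre-promotion shares,
so their mutual ratios are preserved. The relative-risk composition with
promotion coverage is the simplest form consistent with the engine's
coverage-change semantics; bands are treated independently. Setting
rates directly and promoting to the same target are the same operation.
A pattern shift becomes a mortality multiplier via the ratio of
prevalence-weighted mean relative risks (optimal category RR = 1); the
ratio is invariant to rescaling all RRs.

## Incidence and stunting

Incidence-linked interventions multiply episodes per child-year by
`∏(1 − incidence_efficacy × incidence_AF × Δc)`. The implied change in
episodes shifts the stunting distribution by scaling the collective odds
of the stunted strata by `odds_per_episode^Δepisodes` — a log-odds form
linear in episodes, chosen because it is the simplest transform that is
symmetric, keeps prevalences in (0, 1), and reduces to the identity at
`odds_per_episode = 1`; the per-episode odds value itself must come from
cohort evidence supplied by the user. Strata default to the conventional
four height-for-age bands (≥−1, −1 to −2, −2 to −3, <−3 SD) with the
first as reference (RR exactly 1); which strata count as "stunted" for
the shift is configurable (`shift_strata`, default all non-reference).
Within the shifted and unshifted groups relative shares are preserved
and the distribution renormalizes to 1 (tolerance 1e−9). Wasting is
wired identically but ships with no parameters. The yearly pipeline
order is: prevention (direct + incidence), stunting shift, mortality
multiplier, then treatment on the residual; neutral pathway parameters
reproduce the direct-only cascade exactly (regression-tested).

## Numerical choices

* Full float precision everywhere in the computation; rounding only at
  the presentation layer — deaths to integers, percents to one decimal,
  both round-half-up (`decimal.Decimal`), matching how such tables are
  conventionally printed. Tests compare counts to 1 death absolute and
  rendered percents to 0.05 points.
* Coverage declines are allowed by default (negative averted deaths,
  i.e. added deaths, optionally bounded by a residual ceiling); `strict`
  mode rejects them.
* Linear effectiveness extrapolation clamps at 1; extrapolating from
  zero observed coverage is an undefined-slope error.
* Tie-breaks: input order is preserved within each role group (it is
  immaterial to the residual).
* Reports use stable key order and confine timestamps to metadata, so
  re-runs are byte-identical apart from metadata.

## Synthetic data

`generate_fixture(seed, n_interventions, years)` draws random-but-valid
inputs from a local numpy Generator: efficacies in [0.05, 0.95],
affected fractions in [0.05, 1], roles at random, monotone
non-decreasing coverage trajectories from a random baseline, and annual
envelopes around 10,000 deaths/year (the scale of the canonical worked
example). The same seed yields byte-identical fixtures. The generator
emulates the *structure* of real inputs, not their epidemiology: it does
not model correlated coverage, survey measurement error, regionally
realistic effect sizes, or herd immunity. Passing tests therefore
demonstrate the arithmetic and its invariants, not predictive accuracy
on any real population. The default suite sweeps 300 seeded fixtures
through validation and the cascade; examples and acceptance runs use
single-year problems of up to ~6 interventions, which the closed-form
model evaluates instantly.

## Known limitations

* Effect sizes outside the bundled handful must be supplied by the user;
  the package ships no evidence-review point estimates.
* No uncertainty intervals: source-study CIs are not propagated.
* No herd immunity, no pathogen-strain structure, no cross-cause
  effects, no cohort demography.
* Per-step attribution is sequential by construction; whether a joint
  normalization would be preferable is a reporting choice, and the
  isolation operation exists precisely because sequential attribution
  depends on cascade position.
* Pregnancy interventions affecting preterm/SGA births enter only as
  user-supplied shifts to the baseline stunting distribution, not as
  first-class interventions.
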