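import pytest

from averted import (
    BreastfeedingPattern,
    InterventionSpec,
    MortalityEnvelope,
)

# Table-reproduced baseline feeding patterns for the two under-six bands.
PATTERN_0_1 = {"exclusive": 0.620, "predominant": 0.250, "partial": 0.103, "none": 0.027}
PATTERN_1_5 = {"exclusive": 0.402, "predominant": 0.291, "partial": 0.292, "none": 0.015}


@pytest.fixture
def envelope_10k() -> MortalityEnvelope:
    """The canonical worked-example envelope: 10,000 diarrhea deaths/year."""
    return MortalityEnvelope(year=2015, diarrhea_deaths=10_000)


@pytest.fixture
def half_effective_vaccine() -> InterventionSpec:
    return InterventionSpec(name="new_vaccine", role="prevention", efficacy=0.5)


@pytest.fixture
def pattern_0_1() -> BreastfeedingPattern:
    return BreastfeedingPattern(age_band="0-1", prevalences=dict(PATTERN_0_1))


@pytest.fixture
def pattern_1_5() -> BreastfeedingPattern:
    return BreastfeedingPattern(age_band="1-5", prevalences=dict(PATTERN_1_5))
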