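from pathlib import Path

import pytest

from rxthreshold import EbmScenario, Regime, UtilityQuadruple

REPO_ROOT = Path(__file__).resolve().parents[1]

# trial arms of the anticoagulation worked example: recurrence 42/594 on
# placebo vs 8/602 on treatment, 4.8% major bleeding on treatment
EINSTEIN_M = 42 / 594
EINSTEIN_M_RX = 8 / 602
EINSTEIN_RRR = 0.812
EINSTEIN_H_RX = 0.048


@pytest.fixture
def einstein_scenario() -> EbmScenario:
    """The worked example with the rounded effect estimates it prints."""
    return EbmScenario(
        baseline_risk=0.071,
        rrr=EINSTEIN_RRR,
        harm_rx=EINSTEIN_H_RX,
        rv_harm=1.0,
        regime=Regime.INDEPENDENT,
    )


@pytest.fixture
def einstein_dependent(einstein_scenario) -> EbmScenario:
    return einstein_scenario.model_copy(update={"regime": Regime.DEPENDENT})


@pytest.fixture
def simple_quadruple() -> UtilityQuadruple:
    return UtilityQuadruple(0.8, 0.9, 0.4, 1.0)


@pytest.fixture
def examples_dir() -> Path:
    return REPO_ROOT / "examples"
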