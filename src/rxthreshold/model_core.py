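"""Decision-tree core: terminal utilities, expected utility, and the
evidence-based parameterization.

The treat / no-treat decision tree has four terminal states, indexed by the
treatment choice and by whether the patient has the disease.  Utilities live
on a 0-1 scale where 1 is perfect health, and disutilities combine
additively: experiencing the disease outcome costs one unit of
morbidity-weighted disutility, experiencing the treatment harm costs
``rv_harm`` relative units.  This additive form is the unique one under
which the generic benefit/harm threshold ``H / (B + H)`` evaluated on the
reconstructed utilities collapses exactly to the evidence-based closed form
``RV_H * H_rx / (RRR * M)``.

Scenario parameters follow the evidence-based-medicine vocabulary:

``M``
    baseline risk of the disease outcome without treatment,
``M_rx`` / ``RRR``
    treated risk, or equivalently the relative risk reduction
    ``(M - M_rx) / M``,
``H_rx``
    probability of the treatment-harm event (e.g. major bleeding),
``RV_H``
    the decision-maker's relative valuation of the harm outcome against
    the disease outcome (1 = equally bad),
``P``
    probability of disease, which the *dependent* regime forces to 1
    because the outcome is part of the disease definition.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import DomainError, InvalidScenarioError

__all__ = [
    "Regime",
    "UtilityQuadruple",
    "EbmScenario",
    "MonteCarloEstimate",
    "expected_utility_treat",
    "expected_utility_notreat",
    "net_benefit",
    "net_harm",
    "utilities_from_ebm",
    "mc_expected_utility",
]

# risks given as both (M, M_rx) and RRR must agree to this relative level
RISK_CONSISTENCY_TOL = 1e-6


class Regime(str, enum.Enum):
    """Whether disease probability and utilities are independent.

    ``DEPENDENT`` means the outcome event is part of the disease definition
    (e.g. recurrent venous thromboembolism, where a new clot both *is* the
    disease and *is* the morbid outcome); evaluating the tree then forces
    P = 1 to avoid counting the same event in both branches.
    """

    INDEPENDENT = "independent"
    DEPENDENT = "dependent"


@dataclass(frozen=True)
class UtilityQuadruple:
    """The four terminal utilities of the treat/no-treat tree.

    Attributes
    ----------
    u_treat_disease : float
        U1 — treated and diseased.
    u_treat_nodisease : float
        U2 — treated, no disease (carries the treatment harm only).
    u_notreat_disease : float
        U3 — untreated and diseased (carries the full outcome morbidity).
    u_notreat_nodisease : float
        U4 — untreated, no disease (perfect health under this scale).
    """

    u_treat_disease: float
    u_treat_nodisease: float
    u_notreat_disease: float
    u_notreat_nodisease: float

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if not math.isfinite(value):
                raise DomainError(f"utility {name} is not finite: {value!r}")
            if not 0.0 <= value <= 1.0:
                raise DomainError(
                    f"utility {name}={value:.6g} outside [0, 1]"
                )


class EbmScenario(BaseModel):
    """A treatment scenario parameterized by trial-style effect estimates.

    Exactly one of ``treated_risk`` and ``rrr`` may be omitted; the missing
    one is derived.  If both are supplied they must be mutually consistent.
    """

    model_config = ConfigDict(frozen=True)

    baseline_risk: float = Field(ge=0.0, le=1.0, description="M")
    treated_risk: float | None = Field(default=None, ge=0.0, le=1.0,
                                       description="M_rx")
    rrr: float | None = Field(default=None, ge=0.0, le=1.0,
                              description="relative risk reduction")
    harm_rx: float = Field(ge=0.0, le=1.0, description="H_rx")
    rv_harm: float = Field(default=1.0, gt=0.0, description="RV_H")
    disease_prob: float | None = Field(default=None, ge=0.0, le=1.0,
                                       description="P")
    regime: Regime = Regime.INDEPENDENT

    @model_validator(mode="after")
    def _check_effect(self) -> "EbmScenario":
        if self.treated_risk is None and self.rrr is None:
            raise ValueError("one of treated_risk or rrr must be supplied")
        if self.rrr is None and self.baseline_risk <= 0.0:
            raise ValueError(
                "rrr cannot be derived from risks when baseline_risk is 0"
            )
        if self.treated_risk is not None and self.rrr is not None:
            if self.baseline_risk <= 0.0:
                raise ValueError(
                    "baseline_risk must be > 0 to check risk/RRR consistency"
                )
            implied = (self.baseline_risk - self.treated_risk) / self.baseline_risk
            if abs(implied - self.rrr) > RISK_CONSISTENCY_TOL:
                raise ValueError(
                    f"treated_risk implies RRR={implied:.8g} but rrr="
                    f"{self.rrr:.8g} was supplied (difference exceeds "
                    f"{RISK_CONSISTENCY_TOL:g})"
                )
        return self

    @property
    def relative_risk_reduction(self) -> float:
        """RRR, derived from the risks if not supplied directly."""
        if self.rrr is not None:
            return self.rrr
        return (self.baseline_risk - self.treated_risk) / self.baseline_risk

    @property
    def treated_risk_value(self) -> float:
        """M_rx, derived as M * (1 - RRR) if not supplied directly."""
        if self.treated_risk is not None:
            return self.treated_risk
        return self.baseline_risk * (1.0 - self.rrr)

    @property
    def effective_disease_prob(self) -> float | None:
        """The disease probability used when the tree is evaluated.

        The dependent regime forces P = 1 regardless of ``disease_prob``.
        """
        if self.regime is Regime.DEPENDENT:
            return 1.0
        return self.disease_prob


@dataclass(frozen=True)
class MonteCarloEstimate:
    """A simulated mean utility with its Monte-Carlo standard error."""

    mean_utility: float
    std_error: float
    n_draws: int
    seed: int


def _check_probability(p: float, name: str = "p") -> None:
    if not 0.0 <= p <= 1.0:
        raise DomainError(f"{name}={p!r} outside [0, 1]")


def expected_utility_treat(p: float, u: UtilityQuadruple) -> float:
    """Expected utility of treating at disease probability ``p``:
    ``p*U1 + (1-p)*U2``."""
    _check_probability(p)
    return p * u.u_treat_disease + (1.0 - p) * u.u_treat_nodisease


def expected_utility_notreat(p: float, u: UtilityQuadruple) -> float:
    """Expected utility of withholding treatment: ``p*U3 + (1-p)*U4``."""
    _check_probability(p)
    return p * u.u_notreat_disease + (1.0 - p) * u.u_notreat_nodisease


def net_benefit(u: UtilityQuadruple) -> float:
    """Net benefit of treatment in the diseased, B = U1 - U3."""
    return u.u_treat_disease - u.u_notreat_disease


def net_harm(u: UtilityQuadruple) -> float:
    """Net harm of treatment in the non-diseased, H = U4 - U2."""
    return u.u_notreat_nodisease - u.u_treat_nodisease


def utilities_from_ebm(s: EbmScenario) -> UtilityQuadruple:
    """Map scenario parameters to the four terminal utilities.

    With additive unit disutilities:

    * U1 = 1 - (1-RRR)*M - RV_H*H_rx  (residual outcome risk plus harm),
    * U2 = 1 - RV_H*H_rx              (harm only),
    * U3 = 1 - M                      (full outcome risk),
    * U4 = 1.

    Raises
    ------
    InvalidScenarioError
        If any terminal utility would fall below 0.  Such scenarios are
        rejected, not clamped, so that the closed-form identities between
        the generic and evidence-based thresholds stay exact.
    """
    m = s.baseline_risk
    rrr = s.relative_risk_reduction
    harm_disutility = s.rv_harm * s.harm_rx

    u1 = 1.0 - (1.0 - rrr) * m - harm_disutility
    u2 = 1.0 - harm_disutility
    u3 = 1.0 - m
    u4 = 1.0
    for name, value in (("u_treat_disease", u1), ("u_treat_nodisease", u2),
                        ("u_notreat_disease", u3)):
        if value < 0.0:
            raise InvalidScenarioError(
                f"{name}={value:.6g} < 0: combined disutility of "
                f"M={m:g}, RRR={rrr:g}, RV_H*H_rx={harm_disutility:g} "
                "exceeds the 0-1 utility scale"
            )
    return UtilityQuadruple(u1, u2, u3, u4)


def mc_expected_utility(
    s: EbmScenario,
    arm: str,
    p: float,
    n: int,
    seed: int,
) -> MonteCarloEstimate:
    """Stochastic oracle for the closed-form expected utilities.

    Simulates ``n`` patients: each has the disease with probability ``p``;
    diseased patients experience the outcome with probability M (no-treat)
    or M*(1-RRR) (treat); treated patients experience the harm event with
    probability H_rx, independently.  Each event subtracts its unit
    disutility (1 for the outcome, RV_H for the harm), so the expectation
    equals the closed-form expected utility on :func:`utilities_from_ebm`.

    Parameters
    ----------
    arm : {"treat", "notreat"}
    seed : int
        Explicit RNG seed; there is no global random state.
    """
    _check_probability(p)
    if arm not in ("treat", "notreat"):
        raise DomainError(f"arm must be 'treat' or 'notreat', got {arm!r}")
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")

    rng = np.random.default_rng(seed)
    diseased = rng.random(n) < p
    if arm == "treat":
        outcome_p = s.baseline_risk * (1.0 - s.relative_risk_reduction)
        outcome = diseased & (rng.random(n) < outcome_p)
        harmed = rng.random(n) < s.harm_rx
        utility = 1.0 - outcome.astype(float) - s.rv_harm * harmed.astype(float)
    else:
        outcome = diseased & (rng.random(n) < s.baseline_risk)
        utility = 1.0 - outcome.astype(float)

    mean = float(utility.mean())
    if n > 1:
        se = float(utility.std(ddof=1) / math.sqrt(n))
    else:
        se = float("nan")
    return MonteCarloEstimate(mean_utility=mean, std_error=se,
                              n_draws=n, seed=seed)
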