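"""Regime guard against double counting, scenario-level threshold
dispatch, and a bisection oracle that locates thresholds directly on the
decision tree.

The guard is the error surface: asking for the disease-probability
threshold of a scenario whose disease definition contains the outcome
(the *dependent* regime) raises :class:`~rxthreshold.errors.DoubleCountingError`
and directs the caller to the outcome-risk threshold, where disease is
taken as certain (P = 1).

The numeric solver finds the indifference point EU_Rx(x) = EU_NoRx(x) by
bisection on the expected-utility difference.  The difference is linear
in each single parameter under the additive utility parameterization, so
any derivative-free method converges; bisection is used because it stays
correct if the parameterization is ever swapped for a nonlinear one.
"""

from __future__ import annotations

from typing import Callable

from .errors import DomainError, DoubleCountingError, NoRootError
from .model_core import (
    EbmScenario,
    Regime,
    expected_utility_notreat,
    expected_utility_treat,
    utilities_from_ebm,
)
from .thresholds import ThresholdResult, ebm_probability_threshold, outcome_threshold

__all__ = [
    "Regime",
    "regime_check",
    "scenario_probability_threshold",
    "scenario_outcome_threshold",
    "numeric_threshold",
]

# bisection stopping rules: interval width, residual EU difference, iterations
_X_TOL = 1e-14
_F_TOL = 1e-12
_MAX_ITER = 200

_SWEEPABLE = ("P", "M", "H_rx", "RV_H", "RRR")


def regime_check(s: EbmScenario, outcome_defines_disease: bool) -> Regime:
    """Classify a scenario's independence regime.

    ``outcome_defines_disease=True`` (e.g. recurrent venous
    thromboembolism, where the diagnosis is made only once a new clot —
    the outcome itself — is seen) yields the dependent regime;
    a disease established by evidence separate from the outcome (e.g. a
    cancer diagnosis by pathology, with utilities based on mortality)
    yields the independent regime.
    """
    return Regime.DEPENDENT if outcome_defines_disease else Regime.INDEPENDENT


def scenario_probability_threshold(s: EbmScenario) -> ThresholdResult:
    """Disease-probability threshold for a scenario, with regime guard.

    Raises
    ------
    DoubleCountingError
        If the scenario is in the dependent regime: the outcome event
        would then be counted in both the probability and the utility
        branches of the tree.
    """
    if s.regime is Regime.DEPENDENT:
        raise DoubleCountingError(
            "disease definition contains the outcome (dependent regime): "
            "the disease-probability threshold would double-count the "
            "outcome event; use the outcome-risk threshold "
            "(scenario_outcome_threshold) instead"
        )
    return ebm_probability_threshold(
        s.rv_harm, s.harm_rx, s.relative_risk_reduction, s.baseline_risk
    )


def scenario_outcome_threshold(s: EbmScenario) -> ThresholdResult:
    """Outcome-risk threshold for a scenario (disease taken as certain).

    Permitted in either regime; the result does not depend on the
    baseline risk or the disease probability.
    """
    return outcome_threshold(s.rv_harm, s.harm_rx, s.relative_risk_reduction)


def _eu_difference(s: EbmScenario, parameter: str) -> Callable[[float], float]:
    """EU_Rx(x) - EU_NoRx(x) as a function of one scenario parameter."""

    def p_for(scenario: EbmScenario) -> float:
        p = scenario.effective_disease_prob
        if p is None:
            raise DomainError(
                f"disease_prob is required to solve over {parameter!r} in "
                "the independent regime"
            )
        return p

    if parameter == "P":
        u = utilities_from_ebm(s)

        def f(x: float) -> float:
            return expected_utility_treat(x, u) - expected_utility_notreat(x, u)

    else:
        update_field = {
            "M": "baseline_risk",
            "H_rx": "harm_rx",
            "RV_H": "rv_harm",
            "RRR": "rrr",
        }[parameter]
        # pin RRR explicitly so varying M does not drag the derived effect
        base = s.model_copy(update={
            "treated_risk": None,
            "rrr": s.relative_risk_reduction,
        })

        def f(x: float) -> float:
            scenario = base.model_copy(update={update_field: x})
            u = utilities_from_ebm(scenario)
            p = p_for(scenario)
            return expected_utility_treat(p, u) - expected_utility_notreat(p, u)

    return f


def numeric_threshold(s: EbmScenario, parameter: str,
                      bracket: tuple[float, float]) -> float:
    """Locate the indifference point of one parameter by bisection.

    Solves ``EU_Rx(x) = EU_NoRx(x)`` for ``parameter`` in
    ``{"P", "M", "H_rx", "RV_H", "RRR"}`` over ``bracket``; all other
    scenario parameters are held fixed (the dependent regime pins the
    disease probability at 1).

    Returns the root ``x`` with ``|EU_Rx - EU_NoRx| < 1e-12``; agrees
    with the corresponding closed form to well under 1e-9.

    Raises
    ------
    NoRootError
        If the expected-utility difference has the same sign at both
        bracket ends — the decision is uniform over the bracket.
    """
    if parameter not in _SWEEPABLE:
        raise DomainError(
            f"parameter must be one of {_SWEEPABLE}, got {parameter!r}"
        )
    lo, hi = bracket
    if not lo < hi:
        raise DomainError(f"invalid bracket {bracket!r}")

    f = _eu_difference(s, parameter)
    f_lo, f_hi = f(lo), f(hi)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if f_lo * f_hi > 0.0:
        raise NoRootError(
            f"expected-utility difference does not change sign over "
            f"{parameter!r} in [{lo:g}, {hi:g}] "
            f"(f({lo:g})={f_lo:.3g}, f({hi:g})={f_hi:.3g}): the decision "
            "is uniform over this range"
        )

    for _ in range(_MAX_ITER):
        mid = 0.5 * (lo + hi)
        f_mid = f(mid)
        if f_mid == 0.0 or (hi - lo) * 0.5 < _X_TOL:
            break
        if f_lo * f_mid < 0.0:
            hi = mid
        else:
            lo, f_lo = mid, f_mid
    mid = 0.5 * (lo + hi)
    if abs(f(mid)) >= _F_TOL:
        raise NoRootError(
            f"bisection failed to reduce the EU residual below {_F_TOL:g} "
            f"at {parameter}={mid:.12g}"
        )
    return mid
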