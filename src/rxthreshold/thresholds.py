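"""Closed-form treatment thresholds and the treat / no-treat decision rule.

Two kinds of threshold are produced:

* **disease-probability threshold** (Pt) — the probability of disease at
  which the expected utilities of treating and not treating are equal;
  treat above it.  Generic form ``Pt = 1 / (1 + B/H)``; evidence-based
  form ``Pt = RV_H * H_rx / (RRR * M)``.
* **outcome-risk threshold** (Mt) — the baseline risk of the disease
  outcome above which treatment is warranted once the diagnosis (the
  predisposition to the outcome) is taken as certain:
  ``Mt = RV_H * H_rx / RRR``.

Thresholds above 1 are returned as computed, flagged ``never_treat``:
an implausibly high threshold is a substantive finding, not an error.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Any, Mapping

from .errors import DomainError, KindMismatchError

__all__ = [
    "ThresholdKind",
    "ThresholdResult",
    "Decision",
    "classic_threshold",
    "ebm_probability_threshold",
    "outcome_threshold",
    "nnt_nnh_threshold",
    "decide",
]


class ThresholdKind(str, enum.Enum):
    DISEASE_PROBABILITY = "disease_probability"
    OUTCOME_RISK = "outcome_risk"


class Decision(str, enum.Enum):
    TREAT = "treat"
    NO_TREAT = "no_treat"
    INDIFFERENT = "indifferent"


@dataclass(frozen=True)
class ThresholdResult:
    """A computed threshold.

    Attributes
    ----------
    kind : ThresholdKind
        What the threshold bounds: disease probability or outcome risk.
    value : float or None
        The threshold on the proportion scale; may exceed 1, or be None
        when undefined (e.g. negative net benefit).
    never_treat : bool
        True when the threshold is undefined or exceeds 1, i.e. no
        attainable probability/risk justifies treatment.
    inputs : mapping
        Echo of the parameters the threshold was computed from.
    message : str
        Diagnostic text for never_treat / degenerate results.
    """

    kind: ThresholdKind
    value: float | None
    never_treat: bool
    inputs: Mapping[str, Any] = field(default_factory=dict)
    message: str = ""

    @property
    def valid(self) -> bool:
        """True iff the threshold is defined and attainable (value <= 1)."""
        return self.value is not None and not self.never_treat

    def display(self, decimals: int | None = None) -> str:
        """Render as a percentage string.

        Defaults to the conventional precision for each kind: whole
        percent for disease-probability thresholds, one decimal for
        outcome-risk thresholds.  Formatting only — the stored value is
        never rounded.
        """
        if self.value is None:
            return "never treat"
        if decimals is None:
            decimals = 0 if self.kind is ThresholdKind.DISEASE_PROBABILITY else 1
        return f"{round(self.value * 100.0, decimals):.{decimals}f}%"


def _result(kind: ThresholdKind, value: float | None,
            inputs: Mapping[str, Any], message: str = "",
            force_never: bool = False) -> ThresholdResult:
    never = force_never or value is None or value > 1.0
    return ThresholdResult(kind=kind, value=value, never_treat=never,
                           inputs=dict(inputs), message=message)


def classic_threshold(b: float, h: float) -> ThresholdResult:
    """Generic disease-probability threshold ``Pt = H / (B + H)``.

    Parameters are the net benefit ``B = U1 - U3`` and net harm
    ``H = U4 - U2`` of the decision tree.  Scale-invariant: (B, H) and
    (kB, kH) give the same threshold for any k > 0.

    Raises
    ------
    DomainError
        If ``h <= 0`` — with no net harm, treatment is warranted at any
        disease probability and no threshold exists.
    """
    if not (math.isfinite(b) and math.isfinite(h)):
        raise DomainError(f"non-finite benefit/harm: B={b!r}, H={h!r}")
    if h <= 0.0:
        raise DomainError(
            f"net harm H={h:g} <= 0: no net harm, treat at any probability"
        )
    inputs = {"B": b, "H": h}
    if b < 0.0:
        return _result(
            ThresholdKind.DISEASE_PROBABILITY, None, inputs,
            message=f"net benefit B={b:g} < 0: treatment is harmful at "
                    "every disease probability",
        )
    return _result(ThresholdKind.DISEASE_PROBABILITY, h / (b + h), inputs)


def ebm_probability_threshold(rv: float, h_rx: float, rrr: float,
                              m: float) -> ThresholdResult:
    """Disease-probability threshold ``Pt = RV_H * H_rx / (RRR * M)``.

    Valid only when disease probability and utilities are independent;
    the regime guard in :mod:`rxthreshold.solvers` enforces that.
    """
    if rv <= 0.0:
        raise DomainError(f"rv_harm={rv:g} must be > 0")
    if h_rx < 0.0:
        raise DomainError(f"harm_rx={h_rx:g} must be >= 0")
    if rrr < 0.0 or m < 0.0:
        raise DomainError(f"rrr={rrr:g} and m={m:g} must be >= 0")
    inputs = {"rv_harm": rv, "harm_rx": h_rx, "rrr": rrr, "m": m}
    if rrr * m == 0.0:
        if h_rx == 0.0:
            # harmless treatment: threshold degenerates to 0, treat always
            return _result(ThresholdKind.DISEASE_PROBABILITY, 0.0, inputs)
        reason = ("treatment cannot avert anything (RRR=0)" if rrr == 0.0
                  else "no baseline risk to avert (M=0)")
        return _result(ThresholdKind.DISEASE_PROBABILITY, None, inputs,
                       message=reason)
    return _result(ThresholdKind.DISEASE_PROBABILITY,
                   rv * h_rx / (rrr * m), inputs)


def outcome_threshold(rv: float, h_rx: float, rrr: float) -> ThresholdResult:
    """Outcome-risk threshold ``Mt = RV_H * H_rx / RRR``.

    The threshold on the *baseline outcome risk* M once disease is taken
    as certain (P = 1); treat iff M exceeds it.  Independent of M and of
    the disease probability by construction.
    """
    if rv <= 0.0:
        raise DomainError(f"rv_harm={rv:g} must be > 0")
    if h_rx < 0.0:
        raise DomainError(f"harm_rx={h_rx:g} must be >= 0")
    if rrr < 0.0:
        raise DomainError(f"rrr={rrr:g} must be >= 0")
    inputs = {"rv_harm": rv, "harm_rx": h_rx, "rrr": rrr}
    if rrr == 0.0:
        return _result(ThresholdKind.OUTCOME_RISK, None, inputs,
                       message="treatment does not affect underlying risk "
                               "(RRR=0)")
    return _result(ThresholdKind.OUTCOME_RISK, rv * h_rx / rrr, inputs)


def nnt_nnh_threshold(nnt: float, nnh: float,
                      rv: float = 1.0) -> ThresholdResult:
    """Disease-probability threshold from trial summary metrics:
    ``Pt = RV_H * NNT / NNH``.

    Algebraically identical to :func:`ebm_probability_threshold` with
    ``NNT = 1/(M*RRR)`` and ``NNH = 1/H_rx``.  The preference weight
    defaults to 1 (the classical NNT/NNH ratio); values below 1 discount
    the harm outcome consistently with the evidence-based form.
    """
    if nnt <= 0.0:
        raise DomainError(f"nnt={nnt:g} must be > 0 (no benefit)")
    if nnh <= 0.0:
        raise DomainError(f"nnh={nnh:g} must be > 0 (no harm)")
    if rv <= 0.0:
        raise DomainError(f"rv={rv:g} must be > 0")
    inputs = {"nnt": nnt, "nnh": nnh, "rv": rv}
    return _result(ThresholdKind.DISEASE_PROBABILITY, rv * nnt / nnh, inputs)


def decide(estimate: float, t: ThresholdResult,
           estimate_kind: ThresholdKind | None = None) -> Decision:
    """Apply the decision rule: treat iff the estimate exceeds the
    threshold; exact equality is the indifference point.

    Parameters
    ----------
    estimate : float
        The patient's estimated disease probability (for
        disease-probability thresholds) or baseline outcome risk (for
        outcome-risk thresholds), as a proportion.
    estimate_kind : ThresholdKind, optional
        What the estimate measures; if given, it must match the
        threshold's kind.
    """
    if not 0.0 <= estimate <= 1.0:
        raise DomainError(f"estimate={estimate!r} outside [0, 1]")
    if estimate_kind is not None and estimate_kind is not t.kind:
        raise KindMismatchError(
            f"estimate of kind {estimate_kind.value!r} cannot be compared "
            f"against a {t.kind.value!r} threshold"
        )
    if t.never_treat or t.value is None:
        return Decision.NO_TREAT
    if estimate > t.value:
        return Decision.TREAT
    if estimate < t.value:
        return Decision.NO_TREAT
    return Decision.INDIFFERENT
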