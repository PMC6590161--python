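"""Conversions between evidence-based treatment-effect and preference
metrics: RRR, ARR, NNT/NNH, odds-ratio inputs, and preference weights.

Two arithmetic modes exist for the absolute risk reduction.  The default
(``exact``) keeps full precision.  The ``paper`` mode first rounds each
risk to one decimal place on the percent scale and subtracts the rounded
operands — the convention of clinical summaries that report, e.g., risks
of 7.1% and 1.3% and an ARR of 5.8% even though the unrounded difference
is 5.74%.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .errors import DomainError

__all__ = [
    "EffectSummary",
    "rrr_from_risks",
    "apply_rrr",
    "arr_from_risks",
    "nnt",
    "nnh",
    "rv_from_trade_ratio",
    "rr_from_odds_ratio",
]


@dataclass(frozen=True)
class EffectSummary:
    """Treatment-effect metrics derived from a pair of event risks.

    All stored on the proportion scale; mutually consistent by
    construction (``rrr = arr/m``, ``nnt = 1/arr``).
    """

    m: float
    m_rx: float
    rrr: float
    arr: float
    nnt: float
    nnh: float | None = None

    @classmethod
    def from_risks(cls, m: float, m_rx: float,
                   h_rx: float | None = None) -> "EffectSummary":
        arr = arr_from_risks(m, m_rx)
        if arr <= 0.0:
            raise DomainError(
                f"treated risk {m_rx:g} >= baseline risk {m:g}: "
                "no absolute risk reduction"
            )
        return cls(
            m=m, m_rx=m_rx,
            rrr=rrr_from_risks(m, m_rx),
            arr=arr,
            nnt=nnt(arr),
            nnh=nnh(h_rx) if h_rx is not None else None,
        )


def rrr_from_risks(m: float, m_rx: float) -> float:
    """Relative risk reduction ``(M - M_rx) / M``.

    Negative values (a harmful treatment) are permitted but flagged with
    a warning.
    """
    if not 0.0 < m <= 1.0:
        raise DomainError(f"baseline risk m={m!r} must be in (0, 1]")
    if not 0.0 <= m_rx <= 1.0:
        raise DomainError(f"treated risk m_rx={m_rx!r} must be in [0, 1]")
    rrr = (m - m_rx) / m
    if rrr < 0.0:
        warnings.warn(
            f"treated risk {m_rx:g} exceeds baseline {m:g}: RRR={rrr:g} "
            "is negative (harmful treatment)",
            UserWarning, stacklevel=2,
        )
    return rrr


def apply_rrr(p: float, rrr: float) -> float:
    """Residual risk after treatment, ``p * (1 - RRR)``.

    RRR = 1 means the outcome is completely preventable; RRR = 0 means
    treatment does not affect the underlying risk.
    """
    if not 0.0 <= p <= 1.0:
        raise DomainError(f"risk p={p!r} outside [0, 1]")
    if rrr > 1.0:
        raise DomainError(f"rrr={rrr!r} above 1 would give a negative risk")
    residual = p * (1.0 - rrr)
    if residual > 1.0:
        raise DomainError(
            f"residual risk {residual:g} > 1 (rrr={rrr:g} too negative "
            f"for p={p:g})"
        )
    return residual


def arr_from_risks(m: float, m_rx: float, mode: str = "exact") -> float:
    """Absolute risk reduction ``M - M_rx`` (proportion scale).

    ``mode="paper"`` rounds each operand to one decimal on the percent
    scale before subtracting, matching how clinical reports quote ARR
    from already-rounded risks.
    """
    if mode not in ("exact", "paper"):
        raise DomainError(f"unknown arithmetic mode {mode!r}")
    if mode == "paper":
        return (round(m * 100.0, 1) - round(m_rx * 100.0, 1)) / 100.0
    return m - m_rx


def nnt(arr: float) -> float:
    """Number needed to treat, 1/ARR."""
    if arr <= 0.0:
        raise DomainError(f"arr={arr!r} must be > 0 (no benefit)")
    return 1.0 / arr


def nnh(h_rx: float) -> float:
    """Number needed to harm, 1/H_rx."""
    if h_rx <= 0.0:
        raise DomainError(f"h_rx={h_rx!r} must be > 0 (no harm)")
    return 1.0 / h_rx


def rv_from_trade_ratio(k: float) -> float:
    """Preference weight from a 'times worse' trade ratio.

    A decision-maker who considers the disease outcome ``k`` times worse
    than the treatment harm (equivalently accepts ``k`` harms to avoid
    one outcome) weights the harm at ``RV_H = 1/k``.  Full precision;
    round only for display.
    """
    if k <= 0.0 or not math.isfinite(k):
        raise DomainError(f"trade ratio k={k!r} must be a positive number")
    return 1.0 / k


def rr_from_odds_ratio(odds_ratio: float, m: float) -> float:
    """Convert an odds ratio to a risk ratio at baseline risk ``m``.

    Convenience for trial summaries reported as OR: the standard
    relation ``RR = OR / (1 - m + m*OR)``.  The corresponding RRR is
    ``1 - RR``.
    """
    if odds_ratio <= 0.0:
        raise DomainError(f"odds_ratio={odds_ratio!r} must be > 0")
    if not 0.0 <= m < 1.0:
        raise DomainError(f"baseline risk m={m!r} must be in [0, 1)")
    return odds_ratio / (1.0 - m + m * odds_ratio)
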