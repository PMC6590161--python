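"""One-way sensitivity sweeps: threshold-vs-parameter curves.

Sweeps produce tables, not pictures: the source of truth is a long-format
table (parameter value, series label, threshold, never-treat flag); a PNG
or SVG rendering is an optional view of that table.

The canonical use is the anticoagulation trade-off: the outcome-risk
threshold Mt = RV_H * H_rx / RRR swept over the treatment-harm (bleeding)
risk, one curve per preference weight RV_H.  For a fixed treatment
efficacy the curves are straight lines through the origin with slope
RV_H / RRR, ordered by RV_H.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import DomainError
from .thresholds import (
    ThresholdKind,
    ThresholdResult,
    classic_threshold,
    nnt_nnh_threshold,
    outcome_threshold,
)

__all__ = [
    "SweepResult",
    "sweep_outcome_threshold",
    "sweep_probability_threshold",
    "plot_sweep",
    "DEFAULT_HARM_GRID",
    "DEFAULT_RV_VALUES",
]

# shipped reproduction grid: bleeding risk 0..10% by 0.5%, covering the
# 4.8% major-bleeding risk of the worked example
DEFAULT_HARM_GRID: tuple[float, ...] = tuple(round(0.005 * i, 4)
                                             for i in range(21))
# preference weights from equal weighting down to strong outcome aversion
DEFAULT_RV_VALUES: tuple[float, ...] = (1.0, 0.75, 0.5, 0.25, 0.05)


@dataclass(frozen=True)
class SweepResult:
    """Threshold values over a parameter grid, one series per label."""

    parameter: str
    grid: tuple[float, ...]
    series: dict[str, list[ThresholdResult]]

    def __post_init__(self) -> None:
        for label, values in self.series.items():
            if len(values) != len(self.grid):
                raise DomainError(
                    f"series {label!r} has {len(values)} entries for a "
                    f"grid of {len(self.grid)}"
                )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: param_name, param_value, series_label,
        threshold, never_treat."""
        rows = [
            {
                "param_name": self.parameter,
                "param_value": x,
                "series_label": label,
                "threshold": t.value,
                "never_treat": t.never_treat,
            }
            for label, values in self.series.items()
            for x, t in zip(self.grid, values)
        ]
        return pd.DataFrame(
            rows,
            columns=["param_name", "param_value", "series_label",
                     "threshold", "never_treat"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def sweep_outcome_threshold(
    h_rx_grid: Sequence[float],
    rv_values: Sequence[float] = DEFAULT_RV_VALUES,
    rrr: float = 0.812,
) -> SweepResult:
    """Outcome-risk threshold over a grid of treatment-harm risks, one
    series per preference weight.

    Points whose parameters fall outside the closed form's domain are
    recorded as never-treat entries rather than aborting the sweep.
    """
    if len(h_rx_grid) == 0 or len(rv_values) == 0:
        raise DomainError("h_rx_grid and rv_values must be nonempty")
    series: dict[str, list[ThresholdResult]] = {}
    for rv in rv_values:
        label = f"{rv:g}"
        points: list[ThresholdResult] = []
        for h_rx in h_rx_grid:
            try:
                points.append(outcome_threshold(rv, h_rx, rrr))
            except DomainError as exc:
                points.append(ThresholdResult(
                    kind=ThresholdKind.OUTCOME_RISK, value=None,
                    never_treat=True,
                    inputs={"rv_harm": rv, "harm_rx": h_rx, "rrr": rrr},
                    message=str(exc),
                ))
        series[label] = points
    return SweepResult(parameter="h_rx", grid=tuple(h_rx_grid),
                       series=series)


def sweep_probability_threshold(
    ratio_grid: Sequence[float],
    rv: float = 1.0,
) -> SweepResult:
    """Disease-probability threshold over a grid of summary ratios,
    comparing the two classical definitions on the same axis.

    For each ratio ``r`` the ``benefit_harm`` series treats it as the
    net benefit-to-harm ratio B/H and evaluates ``1 / (1 + r)``; the
    ``nnt_nnh`` series treats it as the NNT/NNH ratio, whose threshold
    is the ratio itself (weighted by ``rv``), reported as never-treat
    above 1.
    """
    if len(ratio_grid) == 0:
        raise DomainError("ratio_grid must be nonempty")
    bh_series: list[ThresholdResult] = []
    nnt_series: list[ThresholdResult] = []
    for r in ratio_grid:
        if r <= 0.0:
            raise DomainError(f"ratio {r!r} must be > 0")
        bh_series.append(classic_threshold(r, 1.0))
        nnt_series.append(nnt_nnh_threshold(r, 1.0, rv))
    return SweepResult(
        parameter="ratio",
        grid=tuple(ratio_grid),
        series={"benefit_harm": bh_series, "nnt_nnh": nnt_series},
    )


def plot_sweep(sweep: SweepResult, path, *, percent: bool = True) -> None:
    """Render a sweep as line curves (optional view of the table).

    Requires matplotlib (the ``plot`` extra).  Never-treat points are
    omitted from the curves.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scale = 100.0 if percent else 1.0
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, values in sweep.series.items():
        xs = [x for x, t in zip(sweep.grid, values) if t.valid]
        ys = [t.value * scale for t in values if t.valid]
        ax.plot([x * scale for x in xs], ys, marker="o", ms=3, label=label)
    unit = "%" if percent else ""
    ax.set_xlabel(f"{sweep.parameter} {unit}".strip())
    ax.set_ylabel(f"threshold {unit}".strip())
    ax.legend(title="series")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
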