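"""Incremental cost-effectiveness analytics.

ICER, incremental net monetary benefit (iNMB), base-case and
completion-rate scenario runs, and the cumulative cost decomposition by
category.  All internal arithmetic is full precision; rounding to the
published presentation style (costs in $M to 1 dp, QALYs to 1 dp) happens
only in :meth:`CEAResult.summary`.

iNMB = WTP x dQALY - dCost; the strategy is cost-effective at a
willingness-to-pay threshold exactly when iNMB > 0.  Dominance cases
(cheaper and more effective, or dearer and less effective) are reported
with flags rather than signed ICERs, which are not interpretable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import NamedTuple, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cohort_engine import CohortTrace, run_strategy_pair
from .parameters import ModelSettings, ParameterSet, ValidationError

__all__ = [
    "ICER_WELL_DEFINED",
    "ICER_DOMINANT",
    "ICER_DOMINATED",
    "ICER_UNDEFINED",
    "ICERResult",
    "CEAResult",
    "compute_icer",
    "compute_inmb",
    "run_base_case",
    "run_completion_scenarios",
    "cost_decomposition",
]

ICER_WELL_DEFINED = "well_defined"
ICER_DOMINANT = "dominant"      # cheaper and more effective
ICER_DOMINATED = "dominated"    # dearer and less effective
ICER_UNDEFINED = "undefined"    # zero QALY difference


class ICERResult(NamedTuple):
    value: Optional[float]
    status: str


def compute_icer(delta_cost: float, delta_qaly: float) -> ICERResult:
    """Incremental cost-effectiveness ratio dCost/dQALY with dominance flags.

    Returns an explicit ``undefined`` marker when ``delta_qaly == 0`` rather
    than dividing by zero; ``dominant``/``dominated`` flags replace
    uninterpretable negative ratios.
    """
    if delta_qaly == 0:
        return ICERResult(None, ICER_UNDEFINED)
    if delta_qaly > 0 and delta_cost < 0:
        return ICERResult(None, ICER_DOMINANT)
    if delta_qaly < 0 and delta_cost > 0:
        return ICERResult(None, ICER_DOMINATED)
    return ICERResult(delta_cost / delta_qaly, ICER_WELL_DEFINED)


def compute_inmb(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    """Incremental net monetary benefit: WTP x dQALY - dCost."""
    if wtp < 0:
        raise ValidationError(f"willingness-to-pay must be nonnegative, got {wtp!r}")
    return wtp * delta_qaly - delta_cost


@dataclass(frozen=True)
class CEAResult:
    """Totals and increments of a control-vs-intervention comparison.

    Costs are $AU for the whole cohort; QALYs are cohort totals.  Increments
    are intervention minus control.
    """

    strategy_control: str
    strategy_intervention: str
    cost_control: float
    cost_intervention: float
    qaly_control: float
    qaly_intervention: float
    wtp: float
    completion_rate: float
    cohort_size: int

    @property
    def delta_cost(self) -> float:
        return self.cost_intervention - self.cost_control

    @property
    def delta_qaly(self) -> float:
        return self.qaly_intervention - self.qaly_control

    @property
    def icer(self) -> ICERResult:
        return compute_icer(self.delta_cost, self.delta_qaly)

    @property
    def inmb(self) -> float:
        return compute_inmb(self.delta_cost, self.delta_qaly, self.wtp)

    def summary(self) -> dict[str, object]:
        """Presentation-style dict: cohort costs in $M (1 dp), QALYs (1 dp)."""
        icer = self.icer
        return {
            "control": self.strategy_control,
            "intervention": self.strategy_intervention,
            "completion_rate": self.completion_rate,
            "cohort_size": self.cohort_size,
            "cost_control_millions": round(self.cost_control / 1e6, 1),
            "cost_intervention_millions": round(self.cost_intervention / 1e6, 1),
            "incremental_cost_millions": round(self.delta_cost / 1e6, 2),
            "qaly_control": round(self.qaly_control, 1),
            "qaly_intervention": round(self.qaly_intervention, 1),
            "incremental_qalys": round(self.delta_qaly, 1),
            "icer_per_qaly": None if icer.value is None else round(icer.value),
            "icer_status": icer.status,
            "inmb": round(self.inmb),
            "wtp_per_qaly": self.wtp,
        }

    def to_json(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def run_base_case(
    params: ParameterSet,
    settings: ModelSettings,
    completion_rate: Optional[float] = None,
) -> CEAResult:
    """Run the strategy pair and aggregate into a :class:`CEAResult`.

    ``completion_rate`` overrides the settings value (used for scenario
    analysis); costs and QALYs are discounted totals for the configured
    cohort.
    """
    if completion_rate is not None:
        settings = replace(settings, completion_rate=completion_rate)
    control, intervention = run_strategy_pair(params, settings)
    return CEAResult(
        strategy_control=control.strategy_name,
        strategy_intervention=intervention.strategy_name,
        cost_control=control.total_cost(),
        cost_intervention=intervention.total_cost(),
        qaly_control=control.total_qalys(),
        qaly_intervention=intervention.total_qalys(),
        wtp=settings.wtp_threshold,
        completion_rate=settings.completion_rate,
        cohort_size=settings.cohort_size,
    )


def run_completion_scenarios(
    params: ParameterSet, settings: ModelSettings, completion_rates: Sequence[float]
) -> pd.DataFrame:
    """One :class:`CEAResult` row per completion-rate scenario."""
    rows = []
    for rate in completion_rates:
        res = run_base_case(params, settings, completion_rate=rate)
        icer = res.icer
        rows.append(
            {
                "completion_rate": rate,
                "delta_cost": res.delta_cost,
                "delta_qaly": res.delta_qaly,
                "icer": icer.value,
                "icer_status": icer.status,
                "inmb": res.inmb,
            }
        )
    return pd.DataFrame(rows)


# cost decomposition mirrors the published cumulative-cost figure:
# admissions split by cause; program and stable-management costs combined.
_DECOMP_CATEGORIES = {
    "cardiac_admission": ("cardiac_admission",),
    "noncardiac_admission": ("noncardiac_admission",),
    "rehab_and_stable_management": ("program", "stable_management"),
}


def cost_decomposition(
    trace_pair: tuple[CohortTrace, CohortTrace], *, discounted: bool = True
) -> pd.DataFrame:
    """Cumulative per-cycle cost by category and strategy.

    Returns a tidy frame with columns ``cycle``, ``strategy``, ``category``,
    ``cumulative_cost``; the three categories partition total cost, so at the
    final cycle they sum to each strategy's total.
    """
    control, intervention = trace_pair
    if control.n_cycles != intervention.n_cycles:
        raise ValidationError(
            f"traces have mismatched horizons: {control.n_cycles} vs {intervention.n_cycles}"
        )
    frames = []
    for trace in trace_pair:
        for label, parts in _DECOMP_CATEGORIES.items():
            series = sum(trace.cumulative_cost(p, discounted=discounted) for p in parts)
            frames.append(
                pd.DataFrame(
                    {
                        "cycle": np.arange(trace.n_cycles),
                        "strategy": trace.strategy_name,
                        "category": label,
                        "cumulative_cost": series,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
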