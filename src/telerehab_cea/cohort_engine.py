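"""Deterministic Markov cohort engine.

Four health states — stable cardiac disease, cardiac-related hospitalisation,
non-cardiac-related hospitalisation, dead — advanced in monthly cycles.  The
cohort starts fully in the stable state; hospital states last exactly one
cycle and resolve to stable or dead; dead is absorbing.

Reward conventions (documented in docs/methods.md):

* Rewards for cycle ``t`` accrue on the state occupied at the start of the
  cycle, i.e. after ``t`` transitions; there are ``horizon_cycles`` reward
  points ``t = 0 .. T-1``.
* The program cost is charged once, per patient, at cycle 0 (undiscounted,
  since the cycle-0 discount factor is 1).
* Stable-management cost is charged per person-month of stable occupancy;
  admission costs are event costs charged on entry into a hospital state.
  Because hospital stays last one cycle, hospital occupancy at a cycle
  equals the inflow during the preceding transition.
* QALYs accrue as occupancy x state utility x (cycle length / 12).
* Discounting multiplies cycle-``t`` accruals by ``(1 + r)**(-t/12)``.
* The cardiac-hospitalisation probability of both arms decays by a fixed
  relative amount annually (default 10%/year), stepping at 12-cycle
  boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .parameters import (
    MONTHS_PER_YEAR,
    ModelSettings,
    ParameterSet,
    StrategySpec,
    TransitionParameterSet,
    ValidationError,
    annual_to_monthly,
    monthly_to_annual,
)

__all__ = [
    "STATES",
    "COST_CATEGORIES",
    "CohortTrace",
    "cardiac_hosp_probability",
    "build_transition_matrix",
    "run_cohort",
    "run_strategy_pair",
    "mix_traces",
    "make_strategies",
    "write_trace_csv",
]

STATES = ("stable", "cardiac_hosp", "noncardiac_hosp", "dead")
STABLE, CARDIAC_HOSP, NONCARDIAC_HOSP, DEAD = range(4)

COST_CATEGORIES = ("program", "stable_management", "cardiac_admission", "noncardiac_admission")


def cardiac_hosp_probability(
    p1_monthly: float,
    annual_decay: float,
    cycle_index: int,
    *,
    cycle_length_months: float = 1.0,
    on_annual_scale: bool = True,
) -> float:
    """Monthly cardiac-hospitalisation probability at a given cycle.

    The base monthly probability is decayed by ``(1 - annual_decay)`` per
    completed model year.  With ``on_annual_scale`` the multiplier acts on
    the annual probability before conversion back to monthly (the default);
    otherwise it scales the monthly probability directly.  The two differ by
    well under 1% for the probabilities involved here.
    """
    years = int(cycle_index * cycle_length_months // MONTHS_PER_YEAR)
    factor = (1.0 - annual_decay) ** years
    if on_annual_scale:
        return annual_to_monthly(monthly_to_annual(p1_monthly) * factor)
    return p1_monthly * factor


def build_transition_matrix(
    transitions: TransitionParameterSet,
    arm_p1_monthly: float,
    cycle_index: int,
    *,
    cycle_length_months: float = 1.0,
    decay_on_annual_scale: bool = True,
) -> np.ndarray:
    """Row-stochastic 4x4 matrix for one cycle of one strategy arm.

    Rows/columns follow :data:`STATES`.  Structural zeros: no direct
    hospital-to-hospital transitions; dead is absorbing.
    """
    p1 = cardiac_hosp_probability(
        arm_p1_monthly,
        transitions.annual_cardiac_hosp_decay,
        cycle_index,
        cycle_length_months=cycle_length_months,
        on_annual_scale=decay_on_annual_scale,
    )
    p2 = transitions.p_noncardiac_hosp.mean
    p3 = transitions.p_death_cardiac_hosp.mean
    p4 = transitions.p_death_noncardiac_hosp.mean
    p5 = transitions.p_death_stable.mean
    stay = 1.0 - p1 - p2 - p5
    if stay < 0:
        raise ValidationError(
            f"stable-state exit probabilities exceed 1 at cycle {cycle_index} "
            f"(p1={p1:g}, p2={p2:g}, p5={p5:g})"
        )
    return np.array(
        [
            [stay, p1, p2, p5],
            [1.0 - p3, 0.0, 0.0, p3],
            [1.0 - p4, 0.0, 0.0, p4],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


@dataclass
class CohortTrace:
    """Per-cycle record of one strategy's cohort run.

    ``occupancy`` has shape ``(horizon_cycles + 1, 4)``: row ``t`` is the
    state distribution after ``t`` transitions.  Cost arrays (one per
    category in :data:`COST_CATEGORIES`) and QALY arrays have length
    ``horizon_cycles``; entry ``t`` is the accrual of cycle ``t``.
    """

    strategy_name: str
    occupancy: np.ndarray
    cost_undiscounted: dict[str, np.ndarray]
    cost_discounted: dict[str, np.ndarray]
    qaly_undiscounted: np.ndarray
    qaly_discounted: np.ndarray

    @property
    def n_cycles(self) -> int:
        return len(self.qaly_discounted)

    def total_cost(self, *, discounted: bool = True) -> float:
        costs = self.cost_discounted if discounted else self.cost_undiscounted
        return float(sum(arr.sum() for arr in costs.values()))

    def total_cost_by_category(self, *, discounted: bool = True) -> dict[str, float]:
        costs = self.cost_discounted if discounted else self.cost_undiscounted
        return {cat: float(arr.sum()) for cat, arr in costs.items()}

    def total_qalys(self, *, discounted: bool = True) -> float:
        arr = self.qaly_discounted if discounted else self.qaly_undiscounted
        return float(arr.sum())

    def cumulative_cost(self, category: str, *, discounted: bool = True) -> np.ndarray:
        costs = self.cost_discounted if discounted else self.cost_undiscounted
        return np.cumsum(costs[category])

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table of the trace.

        One row per cycle per state (occupancy) and per cycle per cost
        category (costs), with per-cycle QALY accruals on a ``total`` row.
        """
        rows: list[dict[str, object]] = []
        T = self.n_cycles
        for t in range(T + 1):
            for s, state in enumerate(STATES):
                rows.append({"cycle": t, "state": state, "occupancy": self.occupancy[t, s]})
        for t in range(T):
            for cat in COST_CATEGORIES:
                rows.append(
                    {
                        "cycle": t,
                        "cost_category": cat,
                        "cost_undiscounted": self.cost_undiscounted[cat][t],
                        "cost_discounted": self.cost_discounted[cat][t],
                    }
                )
            rows.append(
                {
                    "cycle": t,
                    "qaly_undiscounted": self.qaly_undiscounted[t],
                    "qaly_discounted": self.qaly_discounted[t],
                }
            )
        cols = [
            "cycle", "state", "occupancy", "cost_category",
            "cost_undiscounted", "cost_discounted",
            "qaly_undiscounted", "qaly_discounted",
        ]
        return pd.DataFrame(rows, columns=cols)


def write_trace_csv(trace: CohortTrace, path: Union[str, Path]) -> None:
    trace.to_frame().to_csv(path, index=False)


def _year_matrices(
    params: ParameterSet, p1_monthly: float, settings: ModelSettings
) -> list[np.ndarray]:
    """One transition matrix per model year (the only within-run variation
    is the annual decay of the cardiac-hospitalisation probability)."""
    n_years = int(
        np.ceil(settings.horizon_cycles * settings.cycle_length_months / MONTHS_PER_YEAR)
    )
    return [
        build_transition_matrix(
            params.transitions,
            p1_monthly,
            year * MONTHS_PER_YEAR,
            cycle_length_months=settings.cycle_length_months,
            decay_on_annual_scale=settings.decay_on_annual_scale,
        )
        for year in range(max(n_years, 1))
    ]


def _run_single(
    params: ParameterSet,
    p1_monthly: float,
    program_cost: float,
    settings: ModelSettings,
    name: str,
) -> CohortTrace:
    T = settings.horizon_cycles
    cl = settings.cycle_length_months
    matrices = _year_matrices(params, p1_monthly, settings)

    x = np.zeros((T + 1, 4))
    x[0, STABLE] = settings.cohort_size
    for t in range(T):
        year = int(t * cl // MONTHS_PER_YEAR)
        x[t + 1] = x[t] @ matrices[year]

    cycles = np.arange(T)
    disc = (1.0 + settings.annual_discount_rate) ** (-(cycles * cl) / MONTHS_PER_YEAR)

    occ_events = x[:T]  # start-of-cycle occupancy; hospital occupancy == inflow
    if settings.half_cycle_correction:
        occ_rewards = 0.5 * (x[:T] + x[1 : T + 1])
    else:
        occ_rewards = occ_events

    u = np.array(
        [
            params.utilities.u_stable.mean,
            params.utilities.u_cardiac_hosp.mean,
            params.utilities.u_noncardiac_hosp.mean,
            params.utilities.u_dead,
        ]
    )
    qaly_und = (occ_rewards @ u) * (cl / MONTHS_PER_YEAR)

    cost_und = {
        "program": np.zeros(T),
        "stable_management": occ_rewards[:, STABLE]
        * params.costs.c_stable_monthly.mean
        * cl,
        "cardiac_admission": occ_events[:, CARDIAC_HOSP]
        * params.costs.c_cardiac_admission.mean,
        "noncardiac_admission": occ_events[:, NONCARDIAC_HOSP]
        * params.costs.c_noncardiac_admission.mean,
    }
    cost_und["program"][0] = settings.cohort_size * program_cost

    return CohortTrace(
        strategy_name=name,
        occupancy=x,
        cost_undiscounted=cost_und,
        cost_discounted={cat: arr * disc for cat, arr in cost_und.items()},
        qaly_undiscounted=qaly_und,
        qaly_discounted=qaly_und * disc,
    )


def mix_traces(weighted: Sequence[tuple[float, CohortTrace]], name: str) -> CohortTrace:
    """Occupancy-weighted combination of traces (the cohort process is
    linear in the occupancy vector, so the mixture is exact)."""
    weights = [w for w, _ in weighted]
    traces = [tr for _, tr in weighted]
    if not traces:
        raise ValidationError("mix_traces needs at least one trace")
    if len({tr.n_cycles for tr in traces}) != 1:
        raise ValidationError("traces to mix must share a horizon")

    def comb(arrays: Iterable[np.ndarray]) -> np.ndarray:
        return sum(w * a for w, a in zip(weights, arrays))

    return CohortTrace(
        strategy_name=name,
        occupancy=comb(tr.occupancy for tr in traces),
        cost_undiscounted={
            cat: comb(tr.cost_undiscounted[cat] for tr in traces) for cat in COST_CATEGORIES
        },
        cost_discounted={
            cat: comb(tr.cost_discounted[cat] for tr in traces) for cat in COST_CATEGORIES
        },
        qaly_undiscounted=comb(tr.qaly_undiscounted for tr in traces),
        qaly_discounted=comb(tr.qaly_discounted for tr in traces),
    )


def run_cohort(
    params: ParameterSet, strategy: StrategySpec, settings: ModelSettings
) -> CohortTrace:
    """Run the deterministic cohort model for one strategy.

    With ``completion_rate < 1`` the cohort is a two-part mixture: completers
    follow the strategy's cardiac-hospitalisation probability, non-completers
    follow the control probability; everyone incurs the strategy's program
    cost.
    """
    c = strategy.completion_rate
    completer = _run_single(
        params, strategy.p_cardiac_hosp.mean, strategy.program_cost, settings, strategy.name
    )
    if c == 1.0:
        return completer
    noncompleter = _run_single(
        params,
        params.transitions.p_cardiac_hosp_control.mean,
        strategy.program_cost,
        settings,
        strategy.name + " (non-completer)",
    )
    return mix_traces([(c, completer), (1.0 - c, noncompleter)], strategy.name)


def make_strategies(
    params: ParameterSet, settings: ModelSettings
) -> tuple[StrategySpec, StrategySpec]:
    """The model's two comparators: centre-based control and hybrid
    telerehabilitation intervention."""
    control = StrategySpec(
        name="centre_based",
        program_cost=params.costs.c_program_control,
        p_cardiac_hosp=params.transitions.p_cardiac_hosp_control,
        completion_rate=1.0,
    )
    intervention = StrategySpec(
        name="telerehab",
        program_cost=params.costs.c_program_intervention.mean,
        p_cardiac_hosp=params.transitions.p_cardiac_hosp_intervention,
        completion_rate=settings.completion_rate,
    )
    return control, intervention


def run_strategy_pair(
    params: ParameterSet, settings: ModelSettings
) -> tuple[CohortTrace, CohortTrace]:
    """Run both strategies; returns (control trace, intervention trace)."""
    control, intervention = make_strategies(params, settings)
    return run_cohort(params, control, settings), run_cohort(params, intervention, settings)
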