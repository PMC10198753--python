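"""Packaged inputs, randomised parameter generation, and a microsimulation
oracle.

The packaged parameter file carries the published base-case inputs (monthly
transition probabilities, utilities, 2022 $AU costs, program-cost
derivations, model settings).  ``random_parameter_set`` draws structurally
valid parameter sets for property testing.  ``microsimulate`` is an
individual-level Monte Carlo implementation of the same decision problem:
it shares only the transition matrices and reward definitions with the
cohort engine, not its matrix-propagation code path, so it serves as an
independent oracle for the cohort expectations.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np

from .cohort_engine import MONTHS_PER_YEAR, _year_matrices
from .parameters import (
    CostParameterSet,
    ModelSettings,
    ParameterSet,
    StrategySpec,
    TransitionParameterSet,
    UncertainValue,
    UtilityParameterSet,
    ValidationError,
    load_parameters,
)

__all__ = [
    "packaged_parameters",
    "packaged_parameter_path",
    "random_parameter_set",
    "PatientPath",
    "MicrosimResult",
    "microsimulate",
]


def packaged_parameter_path():
    """Path-like handle on the installed base-case parameter file."""
    return resources.files("telerehab_cea").joinpath("data/telerehab3.yaml")


def packaged_parameters() -> tuple[ParameterSet, ModelSettings]:
    """Load the packaged base-case parameter set and model settings."""
    with resources.as_file(packaged_parameter_path()) as path:
        return load_parameters(path)


# default bounds for random parameter generation: event probabilities kept
# small enough that the stable self-loop stays positive; utilities bounded
# away from 0/1 so beta moments remain feasible.
_DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "event_probability": (0.0005, 0.08),
    "death_probability": (0.0001, 0.05),
    "utility": (0.3, 0.97),
    "monthly_cost": (20.0, 500.0),
    "admission_cost": (500.0, 20_000.0),
    "program_cost": (500.0, 10_000.0),
}


def random_parameter_set(
    rng: np.random.Generator,
    bounds: Optional[dict[str, tuple[float, float]]] = None,
) -> ParameterSet:
    """A structurally valid random parameter set for property tests.

    Probabilities, utilities and costs are drawn uniformly within ``bounds``
    (see the module defaults); SEMs are set to a modest fraction of each
    mean, capped so that beta moments stay feasible.
    """
    b = dict(_DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    for key, (lo, hi) in b.items():
        if not 0 <= lo <= hi:
            raise ValidationError(f"infeasible bounds for {key}: ({lo}, {hi})")
    if 2 * b["event_probability"][1] + b["death_probability"][1] >= 1.0:
        raise ValidationError("bounds allow stable-state exits to exceed 1")

    def u(lo_hi: tuple[float, float]) -> float:
        return float(rng.uniform(*lo_hi))

    def beta_uv(mean: float) -> UncertainValue:
        cap = 0.5 * np.sqrt(mean * (1.0 - mean))
        sem = min(0.1 * mean, cap)
        return UncertainValue(mean=mean, sem=sem, family="beta")

    def gamma_uv(mean: float) -> UncertainValue:
        return UncertainValue(mean=mean, sem=0.15 * mean, family="gamma")

    transitions = TransitionParameterSet(
        p_cardiac_hosp_intervention=beta_uv(u(b["event_probability"])),
        p_cardiac_hosp_control=beta_uv(u(b["event_probability"])),
        p_noncardiac_hosp=beta_uv(u(b["event_probability"])),
        p_death_cardiac_hosp=beta_uv(u(b["death_probability"])),
        p_death_noncardiac_hosp=beta_uv(u(b["death_probability"])),
        p_death_stable=beta_uv(u(b["death_probability"])),
        annual_cardiac_hosp_decay=float(rng.uniform(0.0, 0.2)),
    )
    utilities = UtilityParameterSet(
        u_stable=beta_uv(u(b["utility"])),
        u_cardiac_hosp=beta_uv(u(b["utility"])),
        u_noncardiac_hosp=beta_uv(u(b["utility"])),
    )
    session_cost = 235.94
    costs = CostParameterSet(
        c_stable_monthly=gamma_uv(u(b["monthly_cost"])),
        c_cardiac_admission=gamma_uv(u(b["admission_cost"])),
        c_noncardiac_admission=gamma_uv(u(b["admission_cost"])),
        c_program_intervention=gamma_uv(u(b["program_cost"])),
        sessions_per_week=gamma_uv(float(rng.uniform(0.5, 3.0))),
        program_weeks=gamma_uv(float(rng.uniform(4.0, 12.0))),
        session_cost=session_cost,
    )
    return ParameterSet(transitions=transitions, utilities=utilities, costs=costs)


@dataclass(frozen=True)
class PatientPath:
    """One simulated individual: visited states and accrued rewards."""

    states: tuple[tuple[int, int], ...]  # (cycle, state index) pairs
    cost_discounted: float
    qalys_discounted: float


@dataclass(frozen=True)
class MicrosimResult:
    """Monte Carlo means and standard errors, per patient."""

    n_patients: int
    mean_cost: float
    se_cost: float
    mean_qaly: float
    se_qaly: float
    states: Optional[np.ndarray] = None  # (horizon+1, n) int8, when recorded

    def paths(self) -> list[PatientPath]:
        if self.states is None:
            raise ValidationError("run microsimulate(record_states=True) to keep paths")
        out = []
        for j in range(self.states.shape[1]):
            out.append(
                PatientPath(
                    states=tuple(enumerate(int(s) for s in self.states[:, j])),
                    cost_discounted=float("nan"),
                    qalys_discounted=float("nan"),
                )
            )
        return out


def _simulate_arm(
    params: ParameterSet,
    p1_monthly: float,
    program_cost: float,
    settings: ModelSettings,
    n: int,
    rng: np.random.Generator,
    record_states: bool,
) -> tuple[np.ndarray, np.ndarray, Optional[np.ndarray]]:
    """Per-patient discounted (cost, qaly) arrays for one sub-cohort."""
    T = settings.horizon_cycles
    cl = settings.cycle_length_months
    cum = [m.cumsum(axis=1) for m in _year_matrices(params, p1_monthly, settings)]

    u = np.array(
        [
            params.utilities.u_stable.mean,
            params.utilities.u_cardiac_hosp.mean,
            params.utilities.u_noncardiac_hosp.mean,
            params.utilities.u_dead,
        ]
    )
    # per-cycle occupancy cost by state: stable management per month;
    # hospital occupancy equals admission (one-cycle stays), so the
    # admission cost is charged as an occupancy cost of the hospital states.
    state_cost = np.array(
        [
            params.costs.c_stable_monthly.mean * cl,
            params.costs.c_cardiac_admission.mean,
            params.costs.c_noncardiac_admission.mean,
            0.0,
        ]
    )

    states = np.zeros(n, dtype=np.int8)  # everyone starts stable
    history = np.zeros((T + 1, n), dtype=np.int8) if record_states else None
    cost = np.full(n, float(program_cost))
    qaly = np.zeros(n)
    for t in range(T):
        disc = settings.discount_factor(t)
        qaly += u[states] * (cl / MONTHS_PER_YEAR) * disc
        cost += state_cost[states] * disc
        year = int(t * cl // MONTHS_PER_YEAR)
        r = rng.random(n)
        states = (r[:, None] > cum[year][states]).sum(axis=1).astype(np.int8)
        if history is not None:
            history[t + 1] = states
    return cost, qaly, history


def microsimulate(
    params: ParameterSet,
    strategy: StrategySpec,
    settings: ModelSettings,
    n_patients: int,
    rng: np.random.Generator,
    *,
    record_states: bool = False,
) -> MicrosimResult:
    """Individual-level Monte Carlo estimate of per-patient cost and QALYs.

    Each patient-cycle transition is a categorical draw from the same
    transition matrix the cohort engine uses; rewards and discounting follow
    the same conventions.  Completion mixtures are simulated as completer /
    non-completer subpopulations in exact proportion.  Returns per-patient
    means with Monte Carlo standard errors.
    """
    if n_patients < 1:
        raise ValidationError("n_patients must be >= 1")
    if settings.half_cycle_correction:
        raise NotImplementedError("the microsimulation oracle assumes no half-cycle correction")

    c = strategy.completion_rate
    n_completers = int(round(c * n_patients))
    groups = []
    if n_completers > 0:
        groups.append((strategy.p_cardiac_hosp.mean, n_completers))
    if n_patients - n_completers > 0:
        groups.append((params.transitions.p_cardiac_hosp_control.mean, n_patients - n_completers))

    costs, qalys, histories = [], [], []
    for p1, n_sub in groups:
        cost, qaly, hist = _simulate_arm(
            params, p1, strategy.program_cost, settings, n_sub, rng, record_states
        )
        costs.append(cost)
        qalys.append(qaly)
        if hist is not None:
            histories.append(hist)
    cost = np.concatenate(costs)
    qaly = np.concatenate(qalys)
    return MicrosimResult(
        n_patients=n_patients,
        mean_cost=float(cost.mean()),
        se_cost=float(cost.std(ddof=1) / np.sqrt(n_patients)) if n_patients > 1 else 0.0,
        mean_qaly=float(qaly.mean()),
        se_qaly=float(qaly.std(ddof=1) / np.sqrt(n_patients)) if n_patients > 1 else 0.0,
        states=np.concatenate(histories, axis=1) if histories else None,
    )
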