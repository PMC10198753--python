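"""Model inputs and parameter algebra for the telerehabilitation model.

This module is the single source of truth for everything the Markov cohort
engine consumes: monthly transition probabilities, health-state utilities,
costs (2022 $AU), the derived rehabilitation program costs, and the
method-of-moments parameterisations used by the probabilistic sensitivity
analysis.  Parameter files are flat YAML (JSON is valid YAML and therefore
also accepted) with units spelled out in the key names so that annual and
monthly probabilities cannot be confused.

Conventions
-----------
* All probabilities stored on parameter sets are *monthly* (one model cycle).
  Annual probabilities quoted by data sources are converted with the
  constant-hazard rule ``1 - (1 - p)**(1/12)``.
* All costs are 2022 Australian dollars.  No currency conversion or
  inflation machinery is provided; that happened upstream of the inputs.
* An :class:`UncertainValue` with ``sem == 0`` or ``family == "fixed"`` is
  excluded from PSA sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Mapping, Optional, Union

import yaml

__all__ = [
    "ValidationError",
    "SchemaError",
    "InfeasibleMomentsError",
    "DegenerateDistributionError",
    "UncertainValue",
    "TransitionParameterSet",
    "UtilityParameterSet",
    "CostParameterSet",
    "ParameterSet",
    "StrategySpec",
    "ModelSettings",
    "annual_to_monthly",
    "monthly_to_annual",
    "control_program_cost",
    "beta_from_moments",
    "gamma_from_moments",
    "load_parameters",
    "save_parameters",
]

MONTHS_PER_YEAR = 12


class ValidationError(ValueError):
    """An input violates a model invariant (range, sign, feasibility)."""


class SchemaError(ValidationError):
    """A parameter file is malformed: missing, unknown or ill-typed keys."""


class InfeasibleMomentsError(ValidationError):
    """Mean/SEM pair is incompatible with the requested distribution family."""


class DegenerateDistributionError(ValidationError):
    """SEM of zero: the value is fixed and has no sampling distribution."""


# ---------------------------------------------------------------------------
# probability-scale conversions
# ---------------------------------------------------------------------------

def annual_to_monthly(p_annual: float) -> float:
    """Convert an annual probability to a monthly one at constant hazard.

    Uses ``1 - (1 - p)**(1/12)``, the standard decision-model convention,
    rather than division by 12 (which overstates monthly risk for large
    annual probabilities and does not reproduce the published annual/monthly
    pairs).
    """
    if not 0.0 <= p_annual <= 1.0:
        raise ValidationError(f"annual probability must be in [0, 1], got {p_annual!r}")
    return 1.0 - (1.0 - p_annual) ** (1.0 / MONTHS_PER_YEAR)


def monthly_to_annual(p_monthly: float) -> float:
    """Inverse of :func:`annual_to_monthly`: ``1 - (1 - p)**12``."""
    if not 0.0 <= p_monthly <= 1.0:
        raise ValidationError(f"monthly probability must be in [0, 1], got {p_monthly!r}")
    return 1.0 - (1.0 - p_monthly) ** MONTHS_PER_YEAR


def control_program_cost(session_cost: float, sessions_per_week: float, weeks: float) -> float:
    """Per-patient cost of a completed centre-based program: C x N x D.

    ``C`` is the cost of one rehabilitation session (price weight x national
    efficient price), ``N`` the mean number of sessions per week and ``D``
    the program duration in weeks.
    """
    if session_cost < 0 or sessions_per_week < 0 or weeks < 0:
        raise ValidationError("program cost inputs must be nonnegative")
    return session_cost * sessions_per_week * weeks


# ---------------------------------------------------------------------------
# method-of-moments distribution parameterisations
# ---------------------------------------------------------------------------

def beta_from_moments(mean: float, sem: float) -> tuple[float, float]:
    """Beta shape parameters (alpha, beta) matching a mean and standard error.

    With ``nu = mean*(1-mean)/sem**2 - 1``::

        alpha = mean * nu          beta = (1 - mean) * nu

    Feasibility requires ``sem**2 < mean*(1-mean)``.
    """
    if not 0.0 < mean < 1.0:
        raise ValidationError(f"beta mean must lie strictly in (0, 1), got {mean!r}")
    if sem < 0:
        raise ValidationError(f"sem must be nonnegative, got {sem!r}")
    if sem == 0:
        raise DegenerateDistributionError("sem = 0: treat the parameter as fixed")
    var = sem * sem
    if var >= mean * (1.0 - mean):
        raise InfeasibleMomentsError(
            f"sem^2 = {var:g} >= mean*(1-mean) = {mean * (1 - mean):g}: "
            "no beta distribution has these moments"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_from_moments(mean: float, sem: float) -> tuple[float, float]:
    """Gamma (shape k, scale theta) matching a mean and standard error.

    ``k = (mean/sem)**2`` and ``theta = sem**2/mean`` give ``k*theta = mean``
    and ``sqrt(k)*theta = sem`` exactly.
    """
    if mean <= 0 or sem <= 0:
        raise ValidationError(f"gamma moments must be positive, got mean={mean!r}, sem={sem!r}")
    return (mean / sem) ** 2, sem * sem / mean


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

_FAMILIES = ("beta", "gamma", "fixed")


@dataclass(frozen=True)
class UncertainValue:
    """A model input with a point estimate and a sampling distribution.

    ``family`` names the distribution assigned for probabilistic sensitivity
    analysis: ``beta`` for probabilities and utilities, ``gamma`` for costs,
    ``fixed`` for quantities that are never sampled.
    """

    mean: float
    sem: float = 0.0
    family: str = "fixed"

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValidationError(f"unknown distribution family {self.family!r}")
        if self.mean < 0:
            raise ValidationError(f"mean must be nonnegative, got {self.mean!r}")
        if self.sem < 0:
            raise ValidationError(f"sem must be nonnegative, got {self.sem!r}")
        if self.family == "beta":
            if not 0.0 <= self.mean <= 1.0:
                raise ValidationError(f"beta-distributed mean must be in [0, 1], got {self.mean!r}")
            if self.sem > 0 and self.sem**2 >= self.mean * (1.0 - self.mean):
                raise InfeasibleMomentsError(
                    f"beta moments infeasible: mean={self.mean}, sem={self.sem}"
                )

    @property
    def is_sampled(self) -> bool:
        """True when PSA draws this parameter from a distribution."""
        return self.family != "fixed" and self.sem > 0

    def distribution_params(self) -> tuple[float, float]:
        """(alpha, beta) or (shape, scale) for the assigned family."""
        if self.family == "beta":
            return beta_from_moments(self.mean, self.sem)
        if self.family == "gamma":
            return gamma_from_moments(self.mean, self.sem)
        raise DegenerateDistributionError("fixed values have no distribution")


def _check_probability(name: str, value: UncertainValue) -> None:
    if not 0.0 <= value.mean <= 1.0:
        raise ValidationError(f"{name} must be a probability in [0, 1], got {value.mean!r}")


@dataclass(frozen=True)
class TransitionParameterSet:
    """Monthly transition probabilities of the four-state model.

    The cardiac-hospitalisation probability is arm specific (intervention vs
    control).  ``annual_cardiac_hosp_decay`` is the assumed annual relative
    reduction of the cardiac-hospitalisation risk after rehabilitation
    (default 10% per year), applied to both arms.
    """

    p_cardiac_hosp_intervention: UncertainValue
    p_cardiac_hosp_control: UncertainValue
    p_noncardiac_hosp: UncertainValue
    p_death_cardiac_hosp: UncertainValue
    p_death_noncardiac_hosp: UncertainValue
    p_death_stable: UncertainValue
    annual_cardiac_hosp_decay: float = 0.10

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, UncertainValue):
                _check_probability(f.name, v)
        if not 0.0 <= self.annual_cardiac_hosp_decay <= 1.0:
            raise ValidationError(
                f"annual decay must be in [0, 1], got {self.annual_cardiac_hosp_decay!r}"
            )
        for arm in ("p_cardiac_hosp_intervention", "p_cardiac_hosp_control"):
            p1 = getattr(self, arm).mean
            total = p1 + self.p_noncardiac_hosp.mean + self.p_death_stable.mean
            if total >= 1.0:
                raise ValidationError(
                    f"stable-state exit probabilities sum to {total:g} >= 1 for {arm}; "
                    "the stable self-loop would be negative"
                )


@dataclass(frozen=True)
class UtilityParameterSet:
    """Health-state utility weights (QALY weights per year of occupancy)."""

    u_stable: UncertainValue
    u_cardiac_hosp: UncertainValue
    u_noncardiac_hosp: UncertainValue
    u_dead: float = 0.0

    def __post_init__(self) -> None:
        for name in ("u_stable", "u_cardiac_hosp", "u_noncardiac_hosp"):
            v = getattr(self, name)
            if not 0.0 <= v.mean <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v.mean!r}")
        if self.u_dead != 0.0:
            raise ValidationError("the dead state has utility 0 by definition")


@dataclass(frozen=True)
class CostParameterSet:
    """Costs in 2022 $AU.

    ``session_cost`` is the price of one centre-based rehabilitation session,
    derived as ``price_weight x nep`` (the activity-based-funding price
    weight for a cardiac rehabilitation clinic times the national efficient
    price).  The control program cost is the product C x N x D of session
    cost, sessions per week and program weeks; N and D carry their own
    uncertainty so the product can be re-sampled component-wise in PSA.
    """

    c_stable_monthly: UncertainValue
    c_cardiac_admission: UncertainValue
    c_noncardiac_admission: UncertainValue
    c_program_intervention: UncertainValue
    sessions_per_week: UncertainValue
    program_weeks: UncertainValue
    session_cost: float = 235.94
    price_weight: float = 0.0407
    nep: float = 5797.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            mean = v.mean if isinstance(v, UncertainValue) else v
            if mean < 0:
                raise ValidationError(f"cost {f.name} must be nonnegative, got {mean!r}")
        derived = self.price_weight * self.nep
        if abs(self.session_cost - derived) > 0.01:  # agree to the cent
            raise ValidationError(
                f"session_cost {self.session_cost} inconsistent with "
                f"price_weight x nep = {derived:.4f}"
            )

    @property
    def c_program_control(self) -> float:
        """Per-patient control program cost C x N x D ($AU)."""
        return control_program_cost(
            self.session_cost, self.sessions_per_week.mean, self.program_weeks.mean
        )


@dataclass(frozen=True)
class ParameterSet:
    """Everything a single model run needs: transitions, utilities, costs."""

    transitions: TransitionParameterSet
    utilities: UtilityParameterSet
    costs: CostParameterSet


@dataclass(frozen=True)
class StrategySpec:
    """One arm of the comparison.

    ``completion_rate`` is the fraction of the cohort that completes the
    program and receives its cardiac-hospitalisation risk; non-completers
    revert to the control risk but still incur the strategy's program cost.
    The control strategy has completion 1.0 by construction.
    """

    name: str
    program_cost: float
    p_cardiac_hosp: UncertainValue
    completion_rate: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.completion_rate <= 1.0:
            raise ValidationError(
                f"completion_rate must be in [0, 1], got {self.completion_rate!r}"
            )
        if self.program_cost < 0:
            raise ValidationError("program_cost must be nonnegative")


@dataclass(frozen=True)
class ModelSettings:
    """Run configuration: horizon, discounting, threshold, cohort, completion.

    ``half_cycle_correction`` and ``decay_on_annual_scale`` expose modelling
    conventions that published analyses rarely state; defaults match the
    common decision-tree-software behaviour (no half-cycle correction; the
    annual hazard decay applied on the annual scale before monthly
    conversion).
    """

    horizon_cycles: int = 60
    cycle_length_months: float = 1.0
    annual_discount_rate: float = 0.05
    wtp_threshold: float = 28_000.0
    cohort_size: int = 1_000
    completion_rate: float = 0.8
    random_seed: Optional[int] = None
    half_cycle_correction: bool = False
    decay_on_annual_scale: bool = True

    def __post_init__(self) -> None:
        if self.horizon_cycles < 1:
            raise ValidationError("horizon_cycles must be >= 1")
        if self.cycle_length_months <= 0:
            raise ValidationError("cycle_length_months must be positive")
        if not 0.0 <= self.annual_discount_rate < 1.0:
            raise ValidationError("annual_discount_rate must be in [0, 1)")
        if self.wtp_threshold <= 0:
            raise ValidationError("wtp_threshold must be positive")
        if self.cohort_size < 1:
            raise ValidationError("cohort_size must be >= 1")
        if not 0.0 <= self.completion_rate <= 1.0:
            raise ValidationError("completion_rate must be in [0, 1]")

    def discount_factor(self, cycle: int) -> float:
        """Present-value factor (1 + r)**(-t/12) for a cycle index t."""
        years = cycle * self.cycle_length_months / MONTHS_PER_YEAR
        return (1.0 + self.annual_discount_rate) ** (-years)


# ---------------------------------------------------------------------------
# parameter file I/O
# ---------------------------------------------------------------------------

# flat-key schema: (attribute path, kind).  kind "uv" = UncertainValue mapping,
# "scalar" = bare number, "settings" = ModelSettings field.
_UV_KEYS: dict[str, tuple[str, str]] = {
    "p_cardiac_hosp_intervention_monthly": ("transitions", "p_cardiac_hosp_intervention"),
    "p_cardiac_hosp_control_monthly": ("transitions", "p_cardiac_hosp_control"),
    "p_noncardiac_hosp_monthly": ("transitions", "p_noncardiac_hosp"),
    "p_death_cardiac_hosp_monthly": ("transitions", "p_death_cardiac_hosp"),
    "p_death_noncardiac_hosp_monthly": ("transitions", "p_death_noncardiac_hosp"),
    "p_death_stable_monthly": ("transitions", "p_death_stable"),
    "u_stable_per_year": ("utilities", "u_stable"),
    "u_cardiac_hosp_per_year": ("utilities", "u_cardiac_hosp"),
    "u_noncardiac_hosp_per_year": ("utilities", "u_noncardiac_hosp"),
    "c_stable_monthly_aud": ("costs", "c_stable_monthly"),
    "c_cardiac_per_admission_aud": ("costs", "c_cardiac_admission"),
    "c_noncardiac_per_admission_aud": ("costs", "c_noncardiac_admission"),
    "c_program_intervention_per_patient_aud": ("costs", "c_program_intervention"),
    "sessions_per_week": ("costs", "sessions_per_week"),
    "program_weeks": ("costs", "program_weeks"),
}
_SCALAR_KEYS: dict[str, tuple[str, str]] = {
    "annual_cardiac_hosp_decay": ("transitions", "annual_cardiac_hosp_decay"),
    "session_cost_aud": ("costs", "session_cost"),
    "price_weight": ("costs", "price_weight"),
    "nep_aud": ("costs", "nep"),
}
_SETTINGS_KEYS: dict[str, str] = {
    "horizon_cycles": "horizon_cycles",
    "cycle_length_months": "cycle_length_months",
    "annual_discount_rate": "annual_discount_rate",
    "wtp_threshold_aud_per_qaly": "wtp_threshold",
    "cohort_size": "cohort_size",
    "completion_rate": "completion_rate",
    "random_seed": "random_seed",
    "half_cycle_correction": "half_cycle_correction",
    "decay_on_annual_scale": "decay_on_annual_scale",
}
_OPTIONAL_KEYS = {
    "random_seed", "half_cycle_correction", "decay_on_annual_scale",
    "cycle_length_months",
}


def _parse_uncertain(key: str, raw: object) -> UncertainValue:
    if isinstance(raw, (int, float)):
        return UncertainValue(mean=float(raw))
    if not isinstance(raw, Mapping):
        raise SchemaError(f"{key}: expected a number or a mean/sem/family mapping")
    unknown = set(raw) - {"mean", "sem", "family"}
    if unknown:
        raise SchemaError(f"{key}: unknown field(s) {sorted(unknown)}")
    if "mean" not in raw:
        raise SchemaError(f"{key}: missing required field 'mean'")
    try:
        return UncertainValue(
            mean=float(raw["mean"]),
            sem=float(raw.get("sem", 0.0)),
            family=str(raw.get("family", "fixed")),
        )
    except ValidationError as exc:
        raise SchemaError(f"{key}: {exc}") from exc


def load_parameters(path: Union[str, Path]) -> tuple[ParameterSet, ModelSettings]:
    """Read a flat YAML/JSON parameter file and validate every invariant.

    Unknown keys are rejected; missing required keys raise a
    :class:`SchemaError` naming the key.
    """
    with open(path, "r") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise SchemaError(f"{path}: parameter file must be a mapping at top level")

    known = set(_UV_KEYS) | set(_SCALAR_KEYS) | set(_SETTINGS_KEYS)
    unknown = set(doc) - known
    if unknown:
        raise SchemaError(f"unknown key(s): {sorted(unknown)}")
    missing = (known - _OPTIONAL_KEYS) - set(doc)
    if missing:
        raise SchemaError(f"missing required key(s): {sorted(missing)}")

    groups: dict[str, dict[str, object]] = {"transitions": {}, "utilities": {}, "costs": {}}
    for key, (group, attr) in _UV_KEYS.items():
        groups[group][attr] = _parse_uncertain(key, doc[key])
    for key, (group, attr) in _SCALAR_KEYS.items():
        val = doc[key]
        if not isinstance(val, (int, float)) or isinstance(val, bool):
            raise SchemaError(f"{key}: expected a number, got {val!r}")
        groups[group][attr] = float(val)

    settings_kwargs: dict[str, object] = {}
    for key, attr in _SETTINGS_KEYS.items():
        if key in doc:
            settings_kwargs[attr] = doc[key]
    try:
        params = ParameterSet(
            transitions=TransitionParameterSet(**groups["transitions"]),
            utilities=UtilityParameterSet(**groups["utilities"]),
            costs=CostParameterSet(**groups["costs"]),
        )
        settings = ModelSettings(**settings_kwargs)
    except SchemaError:
        raise
    except ValidationError as exc:
        raise SchemaError(str(exc)) from exc
    return params, settings


def _dump_uncertain(v: UncertainValue) -> object:
    if v.family == "fixed" and v.sem == 0:
        return v.mean
    return {"mean": v.mean, "sem": v.sem, "family": v.family}


def save_parameters(
    params: ParameterSet, settings: ModelSettings, path: Union[str, Path]
) -> None:
    """Write the flat YAML dialect read by :func:`load_parameters`."""
    doc: dict[str, object] = {}
    for key, (group, attr) in _UV_KEYS.items():
        doc[key] = _dump_uncertain(getattr(getattr(params, group), attr))
    for key, (group, attr) in _SCALAR_KEYS.items():
        doc[key] = getattr(getattr(params, group), attr)
    for key, attr in _SETTINGS_KEYS.items():
        doc[key] = getattr(settings, attr)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
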