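"""Probabilistic sensitivity analysis.

Every uncertain parameter is assigned a distribution by the method of
moments — beta for probabilities and utilities, gamma for costs — and the
deterministic cohort model is re-run per Monte Carlo draw (second-order
uncertainty only).  Cost-effectiveness uncertainty is summarised through the
incremental net monetary benefit at the configured willingness-to-pay
threshold.

Sampling conventions:

* Parameters are drawn independently; no correlation structure is imposed.
  In particular the two arms' cardiac-hospitalisation probabilities are
  independent betas, so a draw may invert the effect direction (no
  truncation is applied).
* The control program cost is rebuilt per draw as C x N x D with the session
  cost C fixed and N (sessions/week) and D (weeks) gamma-distributed;
  alternatively a single gamma on the product is available
  (``control_cost_sampling="aggregate"``).
* The completion rate and the annual hazard decay are scenario settings,
  not sampled quantities.
* Reproducibility: a root ``SeedSequence`` is spawned into one independent
  substream per draw, so results do not depend on evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cea_analysis import compute_inmb
from .cohort_engine import run_strategy_pair
from .parameters import (
    ModelSettings,
    ParameterSet,
    UncertainValue,
    ValidationError,
    beta_from_moments,
    gamma_from_moments,
)

__all__ = [
    "PSASummary",
    "PSAResult",
    "sample_value",
    "sample_parameters",
    "run_psa",
    "ceac",
    "plot_psa_scatter",
]


def sample_value(value: UncertainValue, rng: np.random.Generator) -> float:
    """One draw from an :class:`UncertainValue`'s assigned distribution.

    Fixed values (``family == "fixed"`` or ``sem == 0``) are returned
    unchanged.
    """
    if not value.is_sampled:
        return value.mean
    if value.family == "beta":
        a, b = beta_from_moments(value.mean, value.sem)
        return float(rng.beta(a, b))
    shape, scale = gamma_from_moments(value.mean, value.sem)
    return float(rng.gamma(shape, scale))


def _resampled(value: UncertainValue, rng: np.random.Generator) -> UncertainValue:
    if not value.is_sampled:
        return value
    return replace(value, mean=sample_value(value, rng))


def sample_parameters(
    base: ParameterSet,
    rng: np.random.Generator,
    *,
    control_cost_sampling: str = "components",
) -> ParameterSet:
    """Draw a full parameter set for one PSA iteration.

    The returned set keeps each parameter's SEM and family (so it satisfies
    the same invariants as the base set) with the mean replaced by a draw.
    With ``control_cost_sampling="aggregate"`` the control program cost is
    drawn as a single gamma on the product C x N x D, with the product's
    standard error derived from the independent N and D moments; the draw is
    stored by adjusting the sampled sessions-per-week so that the derived
    product matches it.
    """
    if control_cost_sampling not in ("components", "aggregate"):
        raise ValidationError(
            f"control_cost_sampling must be 'components' or 'aggregate', "
            f"got {control_cost_sampling!r}"
        )
    tr, ut, co = base.transitions, base.utilities, base.costs

    transitions = replace(
        tr,
        p_cardiac_hosp_intervention=_resampled(tr.p_cardiac_hosp_intervention, rng),
        p_cardiac_hosp_control=_resampled(tr.p_cardiac_hosp_control, rng),
        p_noncardiac_hosp=_resampled(tr.p_noncardiac_hosp, rng),
        p_death_cardiac_hosp=_resampled(tr.p_death_cardiac_hosp, rng),
        p_death_noncardiac_hosp=_resampled(tr.p_death_noncardiac_hosp, rng),
        p_death_stable=_resampled(tr.p_death_stable, rng),
    )
    utilities = replace(
        ut,
        u_stable=_resampled(ut.u_stable, rng),
        u_cardiac_hosp=_resampled(ut.u_cardiac_hosp, rng),
        u_noncardiac_hosp=_resampled(ut.u_noncardiac_hosp, rng),
    )

    if control_cost_sampling == "components":
        spw = _resampled(co.sessions_per_week, rng)
        weeks = _resampled(co.program_weeks, rng)
    else:
        mean_n, sd_n = co.sessions_per_week.mean, co.sessions_per_week.sem
        mean_d, sd_d = co.program_weeks.mean, co.program_weeks.sem
        product_mean = co.session_cost * mean_n * mean_d
        product_sd = co.session_cost * np.sqrt(
            mean_n**2 * sd_d**2 + mean_d**2 * sd_n**2 + sd_n**2 * sd_d**2
        )
        if product_sd > 0:
            total = rng.gamma(*gamma_from_moments(product_mean, product_sd))
            spw = replace(co.sessions_per_week, mean=total / (co.session_cost * mean_d))
        else:
            spw = co.sessions_per_week
        weeks = co.program_weeks

    costs = replace(
        co,
        c_stable_monthly=_resampled(co.c_stable_monthly, rng),
        c_cardiac_admission=_resampled(co.c_cardiac_admission, rng),
        c_noncardiac_admission=_resampled(co.c_noncardiac_admission, rng),
        c_program_intervention=_resampled(co.c_program_intervention, rng),
        sessions_per_week=spw,
        program_weeks=weeks,
    )
    return ParameterSet(transitions=transitions, utilities=utilities, costs=costs)


@dataclass(frozen=True)
class PSASummary:
    """Decision-uncertainty summary over the PSA draws.

    ``p_cost_effective`` is the fraction of draws with positive iNMB at the
    configured threshold; ``p_cost_saving`` the fraction with negative
    incremental cost; ``p_effective`` the fraction with positive incremental
    QALYs.  Extremes bracket every draw.
    """

    n_draws: int
    seed: Optional[int]
    wtp: float
    completion_rate: float
    p_cost_effective: float
    p_cost_saving: float
    p_effective: float
    delta_cost_min: float
    delta_cost_max: float
    delta_qaly_min: float
    delta_qaly_max: float
    inmb_min: float
    inmb_max: float

    def as_dict(self) -> dict[str, object]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class PSAResult:
    summary: PSASummary
    draws: pd.DataFrame


_DRAW_COLUMNS = {
    "p_cardiac_hosp_intervention": ("transitions", "p_cardiac_hosp_intervention"),
    "p_cardiac_hosp_control": ("transitions", "p_cardiac_hosp_control"),
    "p_noncardiac_hosp": ("transitions", "p_noncardiac_hosp"),
    "p_death_cardiac_hosp": ("transitions", "p_death_cardiac_hosp"),
    "p_death_noncardiac_hosp": ("transitions", "p_death_noncardiac_hosp"),
    "p_death_stable": ("transitions", "p_death_stable"),
    "u_stable": ("utilities", "u_stable"),
    "u_cardiac_hosp": ("utilities", "u_cardiac_hosp"),
    "u_noncardiac_hosp": ("utilities", "u_noncardiac_hosp"),
    "c_stable_monthly": ("costs", "c_stable_monthly"),
    "c_cardiac_admission": ("costs", "c_cardiac_admission"),
    "c_noncardiac_admission": ("costs", "c_noncardiac_admission"),
    "sessions_per_week": ("costs", "sessions_per_week"),
    "program_weeks": ("costs", "program_weeks"),
    "c_program_intervention": ("costs", "c_program_intervention"),
}


def run_psa(
    params: ParameterSet,
    settings: ModelSettings,
    n_draws: int = 10_000,
    seed: Optional[int] = None,
    *,
    completion_rate: Optional[float] = None,
    control_cost_sampling: str = "components",
) -> PSAResult:
    """Monte Carlo PSA: sample, re-run the strategy pair, summarise.

    Returns the per-draw table (sampled parameters plus incremental cost,
    QALYs and iNMB for the configured cohort) and the :class:`PSASummary`.
    Fully reproducible given ``seed``.
    """
    if n_draws < 1:
        raise ValidationError("n_draws must be >= 1")
    if completion_rate is not None:
        settings = replace(settings, completion_rate=completion_rate)
    substreams = np.random.SeedSequence(seed).spawn(n_draws)

    records: list[dict[str, float]] = []
    for i, ss in enumerate(substreams):
        rng = np.random.default_rng(ss)
        drawn = sample_parameters(params, rng, control_cost_sampling=control_cost_sampling)
        control, intervention = run_strategy_pair(drawn, settings)
        delta_cost = intervention.total_cost() - control.total_cost()
        delta_qaly = intervention.total_qalys() - control.total_qalys()
        rec: dict[str, float] = {"draw_id": i}
        for col, (group, attr) in _DRAW_COLUMNS.items():
            rec[col] = getattr(getattr(drawn, group), attr).mean
        rec["c_program_control"] = drawn.costs.c_program_control
        rec["delta_cost"] = delta_cost
        rec["delta_qaly"] = delta_qaly
        rec["inmb"] = compute_inmb(delta_cost, delta_qaly, settings.wtp_threshold)
        records.append(rec)

    draws = pd.DataFrame.from_records(records)
    summary = PSASummary(
        n_draws=n_draws,
        seed=seed,
        wtp=settings.wtp_threshold,
        completion_rate=settings.completion_rate,
        p_cost_effective=float((draws["inmb"] > 0).mean()),
        p_cost_saving=float((draws["delta_cost"] < 0).mean()),
        p_effective=float((draws["delta_qaly"] > 0).mean()),
        delta_cost_min=float(draws["delta_cost"].min()),
        delta_cost_max=float(draws["delta_cost"].max()),
        delta_qaly_min=float(draws["delta_qaly"].min()),
        delta_qaly_max=float(draws["delta_qaly"].max()),
        inmb_min=float(draws["inmb"].min()),
        inmb_max=float(draws["inmb"].max()),
    )
    return PSAResult(summary=summary, draws=draws)


def ceac(draws: pd.DataFrame, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve: P(iNMB > 0) per WTP value.

    At WTP 0 this is the probability of cost saving; as WTP grows it tends
    to the probability of a QALY gain.
    """
    if len(draws) == 0:
        raise ValidationError("CEAC needs a nonempty draw table")
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ValidationError("CEAC needs a nonempty WTP grid")
    dc = draws["delta_cost"].to_numpy()
    dq = draws["delta_qaly"].to_numpy()
    probs = [(wtp * dq - dc > 0).mean() for wtp in grid]
    return pd.DataFrame({"wtp": grid, "p_cost_effective": probs})


def plot_psa_scatter(draws: pd.DataFrame, out_dir: Union[str, Path]) -> list[Path]:
    """Scatter plots of incremental cost, QALYs and iNMB across draws."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panels = [
        ("delta_cost", "Incremental cost ($AU)", "incremental_cost.png"),
        ("delta_qaly", "Incremental QALYs", "incremental_qalys.png"),
        ("inmb", "Incremental net monetary benefit ($AU)", "inmb.png"),
    ]
    paths = []
    for col, label, fname in panels:
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.scatter(draws["draw_id"], draws[col], s=2, alpha=0.4)
        ax.axhline(draws[col].mean(), lw=1.5)
        ax.axhline(0.0, color="k", lw=0.8, ls="--")
        ax.set_xlabel("PSA iteration")
        ax.set_ylabel(label)
        fig.tight_layout()
        path = out / fname
        fig.savefig(path, dpi=150)
        plt.close(fig)
        paths.append(path)
    return paths
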