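"""Cohort engine: transition-matrix structure, hazard decay, reward
accrual, conservation, mixture linearity and long-run behaviour."""

from dataclasses import replace

import numpy as np
import pytest

from telerehab_cea import (
    ModelSettings,
    ParameterSet,
    StrategySpec,
    UncertainValue,
    ValidationError,
    annual_to_monthly,
    build_transition_matrix,
    mix_traces,
    monthly_to_annual,
    random_parameter_set,
    run_cohort,
    run_strategy_pair,
)
from telerehab_cea.cohort_engine import CARDIAC_HOSP, DEAD, NONCARDIAC_HOSP, STABLE


def _fixed(mean: float) -> UncertainValue:
    return UncertainValue(mean=mean, sem=0.0, family="fixed")


def _zero_event_params(params: ParameterSet, u_stable: float = 1.0) -> ParameterSet:
    """All event probabilities zero: the cohort stays stable forever."""
    tr = replace(
        params.transitions,
        p_cardiac_hosp_intervention=_fixed(0.0),
        p_cardiac_hosp_control=_fixed(0.0),
        p_noncardiac_hosp=_fixed(0.0),
        p_death_cardiac_hosp=_fixed(0.0),
        p_death_noncardiac_hosp=_fixed(0.0),
        p_death_stable=_fixed(0.0),
    )
    ut = replace(params.utilities, u_stable=_fixed(u_stable))
    return replace(params, transitions=tr, utilities=ut)


class TestTransitionMatrix:
    def test_control_base_cycle(self, params):
        m = build_transition_matrix(params.transitions, 0.0214, 0)
        assert m[STABLE, CARDIAC_HOSP] == pytest.approx(0.0214, abs=1e-12)
        assert m[STABLE, NONCARDIAC_HOSP] == 0.038
        assert m[STABLE, DEAD] == 0.0018
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)

    def test_structure(self, params):
        m = build_transition_matrix(params.transitions, 0.0089, 7)
        # hospital states resolve within one cycle: no hosp->hosp moves
        assert m[CARDIAC_HOSP, CARDIAC_HOSP] == 0.0
        assert m[CARDIAC_HOSP, NONCARDIAC_HOSP] == 0.0
        assert m[NONCARDIAC_HOSP, CARDIAC_HOSP] == 0.0
        assert m[NONCARDIAC_HOSP, NONCARDIAC_HOSP] == 0.0
        assert np.array_equal(m[DEAD], [0.0, 0.0, 0.0, 1.0])
        assert np.all((m >= 0) & (m <= 1))

    def test_zero_events_identity_dynamics(self, params):
        """With every event probability zero the chain is identity in
        effect: stable and dead self-loop, and the (unreachable) hospital
        states resolve to stable with certainty."""
        tr = _zero_event_params(params).transitions
        m = build_transition_matrix(tr, 0.0, 0)
        assert np.array_equal(m[STABLE], [1.0, 0.0, 0.0, 0.0])
        assert np.array_equal(m[DEAD], [0.0, 0.0, 0.0, 1.0])
        assert m[CARDIAC_HOSP, STABLE] == 1.0
        assert m[NONCARDIAC_HOSP, STABLE] == 1.0

    def test_annual_decay_steps_at_year_boundaries(self, params):
        tr = params.transitions
        m0 = build_transition_matrix(tr, 0.0089, 0)
        m11 = build_transition_matrix(tr, 0.0089, 11)
        m12 = build_transition_matrix(tr, 0.0089, 12)
        assert m11[STABLE, CARDIAC_HOSP] == m0[STABLE, CARDIAC_HOSP]
        expected = annual_to_monthly(0.9 * monthly_to_annual(0.0089))
        assert m12[STABLE, CARDIAC_HOSP] == pytest.approx(expected, rel=1e-12)
        assert m12[STABLE, CARDIAC_HOSP] < m0[STABLE, CARDIAC_HOSP]

    def test_decay_on_monthly_scale_variant(self, params):
        m24 = build_transition_matrix(
            params.transitions, 0.0214, 24, decay_on_annual_scale=False
        )
        assert m24[STABLE, CARDIAC_HOSP] == pytest.approx(0.0214 * 0.81, rel=1e-12)

    def test_inconsistent_probabilities_rejected(self, params):
        tr = replace(params.transitions, p_noncardiac_hosp=_fixed(0.5))
        with pytest.raises(ValidationError):
            build_transition_matrix(tr, 0.6, 0)


class TestRunCohort:
    def test_zero_event_closed_form(self, params, settings):
        """No events, no discounting, u=1: 5,000 QALYs and program +
        stable-management cost exactly."""
        p = _zero_event_params(params, u_stable=1.0)
        s = replace(settings, annual_discount_rate=0.0)
        strategy = StrategySpec(
            name="idle", program_cost=1000.0, p_cardiac_hosp=_fixed(0.0)
        )
        trace = run_cohort(p, strategy, s)
        assert trace.total_qalys() == pytest.approx(5_000.0, abs=1e-9)
        expected_cost = 1000.0 * 1000 + 60 * 1000 * p.costs.c_stable_monthly.mean
        assert trace.total_cost() == pytest.approx(expected_cost, rel=1e-12)
        assert np.all(trace.occupancy[:, STABLE] == 1000.0)

    def test_program_cost_charged_once_undiscounted(self, params, settings):
        control, _ = run_strategy_pair(params, settings)
        program = control.cost_discounted["program"]
        assert program[0] == pytest.approx(
            settings.cohort_size * params.costs.c_program_control, rel=1e-12
        )
        assert np.all(program[1:] == 0.0)

    @pytest.mark.parametrize("seed", range(12))
    def test_conservation_and_monotone_deaths(self, params, settings, seed):
        rng = np.random.default_rng(seed)
        p = random_parameter_set(rng)
        for trace in run_strategy_pair(p, settings):
            totals = trace.occupancy.sum(axis=1)
            assert np.allclose(totals, settings.cohort_size, atol=1e-9)
            assert np.all(np.diff(trace.occupancy[:, DEAD]) >= -1e-12)
            assert np.all(trace.occupancy >= -1e-12)

    def test_discounted_never_exceeds_undiscounted(self, params, settings):
        _, trace = run_strategy_pair(params, settings)
        for cat in trace.cost_discounted:
            assert np.all(trace.cost_discounted[cat] <= trace.cost_undiscounted[cat] + 1e-12)
        assert np.all(trace.qaly_discounted <= trace.qaly_undiscounted + 1e-12)

    def test_zero_discount_rate_equality(self, params, settings):
        s = replace(settings, annual_discount_rate=0.0)
        trace, _ = run_strategy_pair(params, s)
        assert trace.total_cost() == trace.total_cost(discounted=False)
        assert trace.total_qalys() == trace.total_qalys(discounted=False)

    def test_categories_partition_total_cost(self, params, settings):
        trace, _ = run_strategy_pair(params, settings)
        by_cat = trace.total_cost_by_category()
        assert sum(by_cat.values()) == pytest.approx(trace.total_cost(), rel=1e-12)


class TestCompletionMixture:
    def test_full_completion_is_pure_cohort(self, params, settings):
        s = replace(settings, completion_rate=1.0)
        _, intervention = run_strategy_pair(params, s)
        pure = run_cohort(
            params,
            StrategySpec(
                name="pure",
                program_cost=params.costs.c_program_intervention.mean,
                p_cardiac_hosp=params.transitions.p_cardiac_hosp_intervention,
            ),
            s,
        )
        assert np.array_equal(intervention.occupancy, pure.occupancy)
        assert intervention.total_cost() == pure.total_cost()

    def test_zero_completion_has_control_dynamics(self, params, settings):
        s = replace(settings, completion_rate=0.0)
        control, intervention = run_strategy_pair(params, s)
        assert np.allclose(intervention.occupancy, control.occupancy, atol=1e-12)
        # but the intervention program cost is still incurred
        delta = intervention.total_cost() - control.total_cost()
        expected = settings.cohort_size * (
            params.costs.c_program_intervention.mean - params.costs.c_program_control
        )
        assert delta == pytest.approx(expected, rel=1e-12)

    def test_mixture_linearity_exact(self, params, settings):
        """The mixture cohort equals the weighted sum of completer and
        non-completer cohorts (the process is linear in occupancy)."""
        _, intervention = run_strategy_pair(params, settings)
        program = params.costs.c_program_intervention.mean
        completer = run_cohort(
            params,
            StrategySpec(
                name="completer",
                program_cost=program,
                p_cardiac_hosp=params.transitions.p_cardiac_hosp_intervention,
            ),
            settings,
        )
        noncompleter = run_cohort(
            params,
            StrategySpec(
                name="noncompleter",
                program_cost=program,
                p_cardiac_hosp=params.transitions.p_cardiac_hosp_control,
            ),
            settings,
        )
        mixed = mix_traces([(0.8, completer), (0.2, noncompleter)], "mix")
        assert np.allclose(intervention.occupancy, mixed.occupancy, rtol=0, atol=1e-9)
        assert intervention.total_cost() == pytest.approx(mixed.total_cost(), rel=1e-14)
        assert intervention.total_qalys() == pytest.approx(mixed.total_qalys(), rel=1e-14)


def test_long_run_occupancy_matches_stationary_distribution(params):
    """With deaths and decay disabled the alive states form an ergodic
    3-state chain; engine occupancy converges to its analytic stationary
    distribution (leading eigenvector)."""
    tr = replace(
        params.transitions,
        p_death_cardiac_hosp=_fixed(0.0),
        p_death_noncardiac_hosp=_fixed(0.0),
        p_death_stable=_fixed(0.0),
        annual_cardiac_hosp_decay=0.0,
    )
    p = replace(params, transitions=tr)
    s = ModelSettings(horizon_cycles=1200, annual_discount_rate=0.0, cohort_size=1)
    strategy = StrategySpec(
        name="ctrl", program_cost=0.0, p_cardiac_hosp=p.transitions.p_cardiac_hosp_control
    )
    trace = run_cohort(p, strategy, s)

    m = build_transition_matrix(tr, 0.0214, 0)
    eigvals, eigvecs = np.linalg.eig(m.T)
    lead = np.argmin(np.abs(eigvals - 1.0))
    stationary = np.real(eigvecs[:, lead])
    stationary = stationary / stationary.sum()
    assert np.allclose(trace.occupancy[-1], stationary, atol=1e-9)
    assert trace.occupancy[-1, DEAD] == 0.0


def test_trace_frame_tidy_columns(params, settings):
    trace, _ = run_strategy_pair(params, settings)
    frame = trace.to_frame()
    assert list(frame.columns) == [
        "cycle", "state", "occupancy", "cost_category",
        "cost_undiscounted", "cost_discounted",
        "qaly_undiscounted", "qaly_discounted",
    ]
    occ = frame.dropna(subset=["state"])
    assert len(occ) == (settings.horizon_cycles + 1) * 4
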