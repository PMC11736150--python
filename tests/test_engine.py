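import numpy as np
import pytest

from waitsim import (
    BudgetConstraint,
    GroupScheme,
    HazardParams,
    OutcomeSummary,
    PatientStatus,
    PopulationParams,
    ScenarioSpec,
    aggregate_replicates,
    assign_wait_times,
    classify_cohort,
    cumulative_incidence,
    reference_scheme,
    run_scenario,
    sample_cohort,
    simulate_cohort,
    weekly_event_prob,
    weibull_scale_from_risk,
)
from waitsim.engine import simulate_assigned, _event_uniforms_fn
from waitsim.errors import DomainError
from waitsim.risk_population import Cohort


def constant_cohort(n, p_death, p_hosp, p_urgent, seed=0):
    params = PopulationParams(n_patients=n, seed=seed)
    base = sample_cohort(params)
    return Cohort(
        patient_id=base.patient_id,
        u_latent=base.u_latent,
        p_death12=np.full(n, p_death, dtype=float),
        p_hosp12=np.full(n, p_hosp, dtype=float),
        p_urgent_given_hosp=np.full(n, p_urgent, dtype=float),
        params=params,
    )


def reference_assignment(cohort, seed=0):
    scheme = reference_scheme()
    labels = classify_cohort(cohort, scheme)
    return assign_wait_times(labels, scheme, BudgetConstraint(), seed=seed)


class TestNullAndDegenerateCases:
    def test_zero_risks_all_elective_at_assigned_week(self):
        cohort = constant_cohort(500, 0.0, 0.0, 0.0)
        assignment = reference_assignment(cohort)
        res = simulate_assigned(cohort, assignment, HazardParams(), _event_uniforms_fn(0, 0))
        assert np.all(res.status == PatientStatus.TREATED_ELECTIVE)
        assert np.array_equal(res.exit_week, assignment.assigned_wait_weeks)
        summary = res.summarize()
        assert summary.mortality_pct == 0.0
        assert summary.hospitalization_pct == 0.0
        assert summary.urgent_pct == 0.0

    def test_patient_state_inspection(self):
        cohort = constant_cohort(10, 0.0, 0.0, 0.0)
        assignment = reference_assignment(cohort)
        res = simulate_assigned(cohort, assignment, HazardParams(), _event_uniforms_fn(0, 0))
        state = res.patient_state(0)
        assert state.status == PatientStatus.TREATED_ELECTIVE
        assert state.exit_week == assignment.assigned_wait_weeks[0]
        assert not state.ever_hospitalized


class TestClosedFormOracles:
    def test_homogeneous_memoryless_mortality(self):
        # constant weekly death probability q, wait w, no hospitalization:
        # P(death) = 1 - (1 - q)^w, independent oracle from first principles
        n, p12, w = 50_000, 0.10, 10
        cohort = constant_cohort(n, p12, 0.0, 0.0, seed=21)
        hazards = HazardParams(shape_death=1.0, shape_hosp=1.0)
        assignment = reference_assignment(cohort, seed=21)
        assignment.assigned_wait_weeks[:] = w
        res = simulate_assigned(cohort, assignment, hazards, _event_uniforms_fn(21, 0))
        q = 1.0 - (1.0 - p12) ** (1.0 / 12.0)
        expected = 1.0 - (1.0 - q) ** w
        observed = np.mean(res.status == PatientStatus.DEAD)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) < 3 * se

    def test_heterogeneous_cumulative_incidence_oracle(self):
        # urgent conversion off, mixed waits, heterogeneous risks: simulated
        # mortality/hospitalization match E_i[1 - exp(-lam_i w_i^k)]
        n = 20_000
        params = PopulationParams(n_patients=n, seed=31)
        cohort = sample_cohort(params)
        scheme = GroupScheme(sizes=(0.3, 0.3, 0.4), waits_prioritized=(3, 5))
        labels = classify_cohort(cohort, scheme)
        assignment = assign_wait_times(labels, scheme, seed=31)
        hazards = HazardParams(mult_urgent=1e-12)  # effectively no conversion
        res = simulate_assigned(cohort, assignment, hazards, _event_uniforms_fn(31, 0))

        w = assignment.assigned_wait_weeks.astype(float)
        lam_d = weibull_scale_from_risk(cohort.p_death12, 1.5)
        exp_mort = float(np.mean(cumulative_incidence(lam_d, 1.5, w)))
        obs_mort = float(np.mean(res.status == PatientStatus.DEAD))
        se = np.sqrt(exp_mort * (1 - exp_mort) / n)
        # deaths truncate hospitalization but nothing truncates death here
        assert abs(obs_mort - exp_mort) < 3 * se

    def test_week_one_event_probability(self):
        # single-week wait: P(death) = q_1 exactly in expectation
        n, p12 = 40_000, 0.3
        cohort = constant_cohort(n, p12, 0.0, 0.0, seed=41)
        assignment = reference_assignment(cohort, seed=41)
        assignment.assigned_wait_weeks[:] = 1
        hazards = HazardParams(shape_death=2.0)
        res = simulate_assigned(cohort, assignment, hazards, _event_uniforms_fn(41, 0))
        lam = weibull_scale_from_risk(p12, 2.0)
        expected = weekly_event_prob(lam, 2.0, 1)
        observed = np.mean(res.status == PatientStatus.DEAD)
        assert abs(observed - expected) < 3 * np.sqrt(expected * (1 - expected) / n)


class TestConservationAndDeterminism:
    @pytest.mark.parametrize("seed", [0, 5, 17])
    def test_closed_cohort_conservation(self, seed):
        spec = ScenarioSpec(
            population=PopulationParams(n_patients=3000, seed=seed),
            scheme=GroupScheme(sizes=(0.3, 0.3, 0.4), waits_prioritized=(3, 5)),
            n_replicates=1,
            seed=seed,
        )
        s = simulate_cohort(spec)
        assert s.n_deaths + s.n_urgent + s.n_elective == s.n_patients

    def test_simulate_cohort_deterministic(self):
        spec = ScenarioSpec(
            population=PopulationParams(n_patients=2000, seed=3),
            n_replicates=1,
            seed=3,
        )
        a = simulate_cohort(spec)
        b = simulate_cohort(spec)
        assert a.mortality_pct == b.mortality_pct
        assert a.urgent_pct == b.urgent_pct

    def test_crn_scenarios_share_randomness(self):
        # Same seed, different schemes: cohorts are identical so outcome
        # differences come only from the assigned waits.
        pop = PopulationParams(n_patients=2000, seed=13)
        a = sample_cohort(pop, replicate=0)
        b = sample_cohort(pop, replicate=0)
        assert np.array_equal(a.p_death12, b.p_death12)

    def test_exit_weeks_bounded_by_assignment(self):
        spec = ScenarioSpec(
            population=PopulationParams(n_patients=1000, seed=8), n_replicates=1, seed=8
        )
        cohort = sample_cohort(spec.population)
        assignment = reference_assignment(cohort, seed=8)
        res = simulate_assigned(cohort, assignment, spec.hazards, _event_uniforms_fn(8, 0))
        assert np.all(res.exit_week >= 1)
        assert np.all(res.exit_week <= assignment.assigned_wait_weeks)


class TestAggregateReplicates:
    def _summary(self, m, h, u, wait=12.5):
        return OutcomeSummary(
            mortality_pct=m,
            hospitalization_pct=h,
            urgent_pct=u,
            mean_realized_wait=wait,
            per_group_waits={"low": wait},
            n_patients=100,
            n_deaths=1,
            n_urgent=2,
            n_elective=97,
        )

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            aggregate_replicates([])

    def test_single_replicate_passthrough_se_flagged(self):
        s = self._summary(3.0, 30.0, 15.0)
        agg = aggregate_replicates([s])
        assert agg.mortality_pct == 3.0
        assert agg.monte_carlo_se is None

    def test_identical_replicates_zero_se(self):
        agg = aggregate_replicates([self._summary(3.0, 30.0, 15.0)] * 5)
        assert agg.mortality_pct == 3.0
        assert agg.monte_carlo_se["mortality_pct"] == 0.0

    def test_mean_and_se_match_direct_formulas(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(3.6, 0.2, size=100)
        summaries = [self._summary(v, 30.0, 15.0) for v in vals]
        agg = aggregate_replicates(summaries)
        assert agg.mortality_pct == pytest.approx(vals.mean())
        assert agg.monte_carlo_se["mortality_pct"] == pytest.approx(
            vals.std(ddof=1) / np.sqrt(100)
        )
        assert agg.n_replicates == 100

    def test_run_scenario_aggregates(self):
        spec = ScenarioSpec(
            population=PopulationParams(n_patients=500, seed=2), n_replicates=3, seed=2
        )
        agg = run_scenario(spec)
        assert agg.n_replicates == 3
        assert agg.n_patients == 1500
        assert agg.monte_carlo_se is not None
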