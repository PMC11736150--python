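import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from waitsim import (
    BudgetConstraint,
    GroupScheme,
    PopulationParams,
    assign_wait_times,
    classify_cohort,
    reference_scheme,
    sample_cohort,
    solve_low_risk_wait,
)
from waitsim.errors import ConfigurationError, InfeasibleSchemeError
from waitsim.prioritization import OrderingViolationWarning


class TestSolveLowRiskWait:
    def test_main_best_corner_rounds_to_25_weeks(self):
        w = solve_low_risk_wait((0.30, 0.30, 0.40), (3, 5))
        assert w == pytest.approx(25.25)
        assert round(w) == 25

    def test_equal_thirds_gives_29_5(self):
        assert solve_low_risk_wait((1 / 3, 1 / 3, 1 / 3), (3, 5)) == pytest.approx(29.5)

    def test_two_group_gives_16_6(self):
        w = solve_low_risk_wait((0.30, 0.70), (3,))
        assert round(w, 1) == 16.6
        assert w == pytest.approx(116 / 7)

    def test_benchmark_scheme_gives_16(self):
        assert solve_low_risk_wait((0.20, 0.10, 0.70), (3, 7)) == pytest.approx(16.0)

    def test_single_group_collapses_to_target(self):
        assert solve_low_risk_wait((1.0,), ()) == pytest.approx(12.5)

    def test_infeasible_raises(self):
        with pytest.raises(InfeasibleSchemeError):
            solve_low_risk_wait((0.9, 0.1), (14,))

    def test_ordering_violation_warns_but_returns(self):
        # half the cohort at 13 weeks leaves the "low" tier at 12 < 13
        with pytest.warns(OrderingViolationWarning):
            w = solve_low_risk_wait((0.50, 0.50), (13,))
        assert w == pytest.approx(12.0)

    def test_custom_target(self):
        c = BudgetConstraint(target_mean_wait=10.0)
        assert solve_low_risk_wait((0.5, 0.5), (4,), c) == pytest.approx(16.0)

    @given(
        w_high=st.floats(1.0, 6.0),
        delta=st.floats(0.01, 1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_linear_and_decreasing_in_prioritized_wait(self, w_high, delta):
        sizes = (0.2, 0.8)
        a = solve_low_risk_wait(sizes, (w_high,), warn=False)
        b = solve_low_risk_wait(sizes, (w_high + delta,), warn=False)
        assert b < a
        # linearity: slope equals -p_high / p_low
        assert (b - a) / delta == pytest.approx(-0.2 / 0.8)


class TestGroupScheme:
    def test_sizes_must_sum_to_one(self):
        with pytest.raises(ConfigurationError, match="sum to 1"):
            GroupScheme(sizes=(0.5, 0.4), waits_prioritized=(3,))

    def test_wait_count_must_match(self):
        with pytest.raises(ConfigurationError):
            GroupScheme(sizes=(0.3, 0.3, 0.4), waits_prioritized=(3,))

    def test_group_names(self):
        assert GroupScheme(sizes=(0.3, 0.3, 0.4), waits_prioritized=(3, 5)).group_names == (
            "high",
            "medium",
            "low",
        )
        assert GroupScheme(sizes=(0.3, 0.7), waits_prioritized=(3,)).group_names == ("high", "low")
        assert reference_scheme().group_names == ("low",)


class TestClassifyCohort:
    def test_exact_partition_on_100(self):
        cohort = sample_cohort(PopulationParams(n_patients=100, seed=2))
        scheme = GroupScheme(sizes=(0.05, 0.05, 0.90), waits_prioritized=(3, 5))
        labels = classify_cohort(cohort, scheme)
        assert np.sum(labels == "high") == 5
        assert np.sum(labels == "medium") == 5
        assert np.sum(labels == "low") == 90

    def test_ties_broken_by_patient_id(self):
        cohort = sample_cohort(PopulationParams(n_patients=10, mean_death12=0.0, seed=0))
        scheme = GroupScheme(
            sizes=(0.3, 0.7), waits_prioritized=(3,), classifier_outcome="death"
        )
        labels = classify_cohort(cohort, scheme)  # all risks equal (zero)
        assert np.sum(labels == "high") == 3
        # lowest patient_ids win the high tier on ties
        assert set(cohort.patient_id[labels == "high"]) == {0, 1, 2}

    def test_sort_oracle_separates_groups(self):
        cohort = sample_cohort(PopulationParams(n_patients=1000, seed=3))
        scheme = GroupScheme(sizes=(0.30, 0.30, 0.40), waits_prioritized=(3, 5))
        labels = classify_cohort(cohort, scheme)
        high = cohort.u_latent[labels == "high"]
        med = cohort.u_latent[labels == "medium"]
        low = cohort.u_latent[labels == "low"]
        assert high.min() >= med.max()
        assert med.min() >= low.max()

    def test_partition_counts_within_one_of_fractions(self):
        cohort = sample_cohort(PopulationParams(n_patients=997, seed=4))
        scheme = GroupScheme(sizes=(0.15, 0.25, 0.60), waits_prioritized=(3, 5))
        labels = classify_cohort(cohort, scheme)
        for name, frac in zip(("high", "medium", "low"), scheme.sizes):
            assert abs(np.sum(labels == name) - 997 * frac) <= 1

    def test_margin_classifier(self):
        cohort = sample_cohort(PopulationParams(n_patients=200, seed=5))
        scheme = GroupScheme(
            sizes=(0.10, 0.90), waits_prioritized=(3,), classifier_outcome="hosp"
        )
        labels = classify_cohort(cohort, scheme)
        high_risk = cohort.p_hosp12[labels == "high"]
        low_risk = cohort.p_hosp12[labels == "low"]
        assert high_risk.min() >= low_risk.max()


class TestAssignWaitTimes:
    def _assignment(self, sizes, waits, n=1000, seed=0, constraint=BudgetConstraint()):
        cohort = sample_cohort(PopulationParams(n_patients=n, seed=seed))
        scheme = GroupScheme(sizes=sizes, waits_prioritized=waits)
        labels = classify_cohort(cohort, scheme)
        return assign_wait_times(labels, scheme, constraint, seed=seed)

    def test_integer_low_wait_assigned_verbatim(self):
        a = self._assignment((0.20, 0.10, 0.70), (3, 7), n=1000)
        low = a.assigned_wait_weeks[a.group == "low"]
        assert a.solved_low_wait == pytest.approx(16.0)
        assert np.all(low == 16)

    def test_fractional_low_wait_mixes_adjacent_weeks(self):
        a = self._assignment((0.30, 0.30, 0.40), (3, 5), n=1000)
        low = a.assigned_wait_weeks[a.group == "low"]
        assert set(np.unique(low)) == {25, 26}
        # 25.25 -> 25% of the low tier bumped to 26 weeks
        assert np.sum(low == 26) == round(0.25 * len(low))

    def test_reference_mixes_12_and_13_evenly(self):
        cohort = sample_cohort(PopulationParams(n_patients=2000, seed=1))
        scheme = reference_scheme()
        labels = classify_cohort(cohort, scheme)
        a = assign_wait_times(labels, scheme, seed=1)
        assert set(np.unique(a.assigned_wait_weeks)) == {12, 13}
        assert np.sum(a.assigned_wait_weeks == 13) == 1000

    @pytest.mark.parametrize("sizes,waits", [
        ((0.30, 0.30, 0.40), (3, 5)),
        ((1 / 3, 1 / 3, 1 / 3), (3, 5)),
        ((0.30, 0.70), (3,)),
        ((0.05, 0.05, 0.90), (5, 9)),
        ((1.0,), ()),
    ])
    def test_budget_conserved_within_half_week_over_n(self, sizes, waits):
        n = 977  # deliberately awkward
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OrderingViolationWarning)
            a = self._assignment(sizes, waits, n=n, seed=9)
        assert abs(a.assigned_wait_weeks.mean() - 12.5) <= 0.5 / n + 1e-12

    def test_propagates_infeasibility(self):
        with pytest.raises(InfeasibleSchemeError):
            self._assignment((0.9, 0.1), (14,))

    def test_all_waits_positive(self):
        a = self._assignment((0.30, 0.30, 0.40), (3, 5), n=203)
        assert np.all(a.assigned_wait_weeks >= 1)

    def test_deterministic_given_seed(self):
        a = self._assignment((0.30, 0.30, 0.40), (3, 5), seed=5)
        b = self._assignment((0.30, 0.30, 0.40), (3, 5), seed=5)
        assert np.array_equal(a.assigned_wait_weeks, b.assigned_wait_weeks)
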