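"""Weekly-cycle closed-cohort waitlist simulation.

Each week every waiting patient faces, in order: a death trial, a
hospitalization trial, an urgent-conversion trial (only in a week with a
hospitalization), and finally an elective exit if the week equals the
assigned wait. The order is conservative — death precludes same-week
treatment. The cohort is closed: deaths + urgent + elective exits account
for every patient once the list empties.

All trials draw from counter-based uniform streams keyed by
(seed, replicate, week), so two scenarios run with the same seed share
their randomness and differ only through the assigned waits.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import _rng
from .errors import ConfigurationError, DomainError
from .hazards import HazardParams, urgent_conversion_prob, weibull_scale_from_risk
from .prioritization import (
    BudgetConstraint,
    GroupScheme,
    WaitAssignment,
    assign_wait_times,
    classify_cohort,
    reference_scheme,
)
from .risk_population import Cohort, PopulationParams, sample_cohort


class PatientStatus(enum.IntEnum):
    WAITING = 0
    DEAD = 1
    TREATED_ELECTIVE = 2
    TREATED_URGENT = 3


@dataclass(frozen=True)
class PatientState:
    """Terminal state of one simulated patient (for inspection/debugging)."""

    status: PatientStatus
    weeks_waited: int
    ever_hospitalized: bool
    exit_week: int | None


@dataclass(frozen=True)
class ScenarioSpec:
    """Everything needed to run one scenario end to end."""

    population: PopulationParams
    hazards: HazardParams = HazardParams()
    scheme: GroupScheme | None = None  # None -> first-come-first-served reference
    constraint: BudgetConstraint = BudgetConstraint()
    n_replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ConfigurationError(f"n_replicates must be >= 1, got {self.n_replicates!r}")

    def resolved_scheme(self) -> GroupScheme:
        return self.scheme if self.scheme is not None else reference_scheme()


@dataclass
class OutcomeSummary:
    """Headline tallies for one replicate or an aggregate of replicates."""

    mortality_pct: float
    hospitalization_pct: float
    urgent_pct: float
    mean_realized_wait: float
    per_group_waits: dict[str, float]
    n_patients: int
    n_deaths: int = 0
    n_urgent: int = 0
    n_elective: int = 0
    n_replicates: int = 1
    monte_carlo_se: dict[str, float] | None = None

    def outcome(self, name: str) -> float:
        return {
            "mortality": self.mortality_pct,
            "hospitalization": self.hospitalization_pct,
            "urgent": self.urgent_pct,
        }[name]


UniformsFn = Callable[[int, int], np.ndarray]  # (week, n) -> (n, 3) uniforms


def _event_uniforms_fn(seed: int, replicate: int) -> UniformsFn:
    def fn(week: int, n: int) -> np.ndarray:
        return _rng.event_uniforms(seed, replicate, week, n)

    return fn


@dataclass
class ReplicateResult:
    """Full per-patient outcome arrays for one replicate."""

    status: np.ndarray
    exit_week: np.ndarray
    ever_hospitalized: np.ndarray
    assignment: WaitAssignment = field(repr=False)

    def patient_state(self, i: int) -> PatientState:
        return PatientState(
            status=PatientStatus(int(self.status[i])),
            weeks_waited=int(self.exit_week[i]),
            ever_hospitalized=bool(self.ever_hospitalized[i]),
            exit_week=int(self.exit_week[i]),
        )

    def summarize(self) -> OutcomeSummary:
        n = len(self.status)
        deaths = int(np.sum(self.status == PatientStatus.DEAD))
        urgent = int(np.sum(self.status == PatientStatus.TREATED_URGENT))
        elective = int(np.sum(self.status == PatientStatus.TREATED_ELECTIVE))
        assert deaths + urgent + elective == n, "closed cohort must conserve patients"
        treated = urgent + elective
        per_group = {}
        for name in self.assignment.scheme.group_names:
            mask = self.assignment.group == name
            per_group[name] = float(np.mean(self.assignment.assigned_wait_weeks[mask]))
        return OutcomeSummary(
            mortality_pct=100.0 * deaths / n,
            hospitalization_pct=100.0 * float(np.mean(self.ever_hospitalized)),
            urgent_pct=100.0 * urgent / treated if treated else 0.0,
            mean_realized_wait=float(np.mean(self.exit_week)),
            per_group_waits=per_group,
            n_patients=n,
            n_deaths=deaths,
            n_urgent=urgent,
            n_elective=elective,
        )


def simulate_assigned(
    cohort: Cohort,
    assignment: WaitAssignment,
    hazards: HazardParams,
    uniforms: UniformsFn,
) -> ReplicateResult:
    """Run the weekly cycle for one cohort with waits already assigned."""
    n = len(cohort)
    if len(assignment) != n:
        raise DomainError("assignment length does not match cohort size")
    lam_d = weibull_scale_from_risk(
        cohort.p_death12, hazards.shape_death, hazards.risk_horizon, hazards.mult_death
    )
    lam_h = weibull_scale_from_risk(
        cohort.p_hosp12, hazards.shape_hosp, hazards.risk_horizon, hazards.mult_hosp
    )
    p_conv = urgent_conversion_prob(cohort.p_urgent_given_hosp, hazards.mult_urgent)
    waits = assignment.assigned_wait_weeks

    status = np.full(n, PatientStatus.WAITING, dtype=np.int8)
    exit_week = np.zeros(n, dtype=np.int64)
    ever_hosp = np.zeros(n, dtype=bool)
    waiting = np.ones(n, dtype=bool)

    max_week = int(waits.max())
    kd, kh = hazards.shape_death, hazards.shape_hosp
    for t in range(1, max_week + 1):
        if not waiting.any():
            break
        u = uniforms(t, n)
        tk_d = float(t) ** kd - float(t - 1) ** kd
        tk_h = float(t) ** kh - float(t - 1) ** kh
        q_d = -np.expm1(-lam_d * tk_d)
        q_h = -np.expm1(-lam_h * tk_h)

        die = waiting & (u[:, 0] < q_d)
        status[die] = PatientStatus.DEAD
        exit_week[die] = t
        alive = waiting & ~die

        hosp = alive & (u[:, 1] < q_h)
        ever_hosp |= hosp

        urgent = hosp & (u[:, 2] < p_conv)
        status[urgent] = PatientStatus.TREATED_URGENT
        exit_week[urgent] = t

        elective = alive & ~urgent & (waits == t)
        status[elective] = PatientStatus.TREATED_ELECTIVE
        exit_week[elective] = t

        waiting = alive & ~urgent & ~elective
    assert not waiting.any(), "waitlist must empty by the longest assigned wait"
    return ReplicateResult(
        status=status, exit_week=exit_week, ever_hospitalized=ever_hosp, assignment=assignment
    )


def simulate_cohort(
    spec: ScenarioSpec,
    assignment: WaitAssignment | None = None,
    replicate: int = 0,
    cohort: Cohort | None = None,
    uniforms: UniformsFn | None = None,
) -> OutcomeSummary:
    """Run a single replicate of a scenario and summarize it.

    The cohort is sampled from ``spec.population`` (keyed by replicate) and
    waits are assigned from ``spec.scheme`` unless explicit objects are
    supplied. Deterministic given ``spec.seed``.
    """
    if cohort is None:
        cohort = sample_cohort(spec.population, replicate=replicate)
    if assignment is None:
        scheme = spec.resolved_scheme()
        labels = classify_cohort(cohort, scheme)
        assignment = assign_wait_times(
            labels, scheme, spec.constraint, seed=spec.seed, replicate=replicate
        )
    if uniforms is None:
        uniforms = _event_uniforms_fn(spec.seed, replicate)
    return simulate_assigned(cohort, assignment, spec.hazards, uniforms).summarize()


_AGG_FIELDS = ("mortality_pct", "hospitalization_pct", "urgent_pct", "mean_realized_wait")


def aggregate_replicates(summaries: Sequence[OutcomeSummary]) -> OutcomeSummary:
    """Unweighted means across replicates; Monte-Carlo SE = SD / sqrt(R)."""
    if len(summaries) == 0:
        raise DomainError("aggregate_replicates requires at least one replicate")
    r = len(summaries)
    means = {f: float(np.mean([getattr(s, f) for s in summaries])) for f in _AGG_FIELDS}
    if r > 1:
        se = {
            f: float(np.std([getattr(s, f) for s in summaries], ddof=1) / np.sqrt(r))
            for f in _AGG_FIELDS
        }
    else:
        se = None  # undefined for a single replicate
    group_names = summaries[0].per_group_waits.keys()
    per_group = {
        g: float(np.mean([s.per_group_waits[g] for s in summaries])) for g in group_names
    }
    return OutcomeSummary(
        mortality_pct=means["mortality_pct"],
        hospitalization_pct=means["hospitalization_pct"],
        urgent_pct=means["urgent_pct"],
        mean_realized_wait=means["mean_realized_wait"],
        per_group_waits=per_group,
        n_patients=sum(s.n_patients for s in summaries),
        n_deaths=sum(s.n_deaths for s in summaries),
        n_urgent=sum(s.n_urgent for s in summaries),
        n_elective=sum(s.n_elective for s in summaries),
        n_replicates=r,
        monte_carlo_se=se,
    )


def run_scenario(spec: ScenarioSpec) -> OutcomeSummary:
    """Simulate all replicates of a scenario and aggregate them."""
    summaries = [simulate_cohort(spec, replicate=r) for r in range(spec.n_replicates)]
    return aggregate_replicates(summaries)
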