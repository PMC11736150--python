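"""Calibration of the hazard multipliers against registry-derived targets.

Targets are simple ratios of printed registry counts (deaths / net
referrals, etc.). Fitting is sequential one-dimensional bisection on the
log of each multiplier — hospitalization first, then urgent conversion,
then death — repeated over a small number of outer sweeps. Every model
evaluation re-runs the reference (first-come-first-served) scenario with
common random numbers, so the objective is a deterministic, monotone
function of each multiplier and bisection is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _rng
from .engine import aggregate_replicates, simulate_assigned
from .errors import CalibrationError, ConfigurationError, DomainError
from .hazards import HazardParams
from .prioritization import BudgetConstraint, assign_wait_times, classify_cohort, reference_scheme
from .risk_population import PopulationParams, sample_cohort


@dataclass(frozen=True)
class CalibrationTargets:
    """Percent-scale targets for the reference scenario."""

    mortality_target_pct: float
    hospitalization_target_pct: float
    urgent_share_target_pct: float
    tolerance_pp: float = 0.1

    def __post_init__(self) -> None:
        for name in ("mortality_target_pct", "hospitalization_target_pct", "urgent_share_target_pct"):
            v = getattr(self, name)
            if not (0.0 < v < 100.0):
                raise ConfigurationError(f"{name} must lie in (0, 100), got {v!r}")
        if not self.tolerance_pp > 0:
            raise ConfigurationError(f"tolerance_pp must be > 0, got {self.tolerance_pp!r}")

    def as_dict(self) -> dict[str, float]:
        return {
            "mortality": self.mortality_target_pct,
            "hospitalization": self.hospitalization_target_pct,
            "urgent": self.urgent_share_target_pct,
        }


def registry_targets_from_counts(
    referrals: int,
    removed: int,
    tavis: int,
    deaths: int,
    hospitalized: int,
    unscheduled: int,
    tolerance_pp: float = 0.1,
) -> CalibrationTargets:
    """Turn raw registry counts into percent targets (1-decimal rounding).

    mortality = deaths / (referrals - removed); hospitalization =
    hospitalized / (referrals - removed); urgent share = unscheduled / tavis.
    """
    counts = dict(
        referrals=referrals, removed=removed, tavis=tavis,
        deaths=deaths, hospitalized=hospitalized, unscheduled=unscheduled,
    )
    for name, v in counts.items():
        if v < 0:
            raise DomainError(f"{name} must be non-negative, got {v}")
    if removed >= referrals:
        raise DomainError("removed must be smaller than referrals")
    if unscheduled > tavis:
        raise DomainError("unscheduled cannot exceed total procedures")
    if tavis == 0:
        raise DomainError("tavis must be positive to form the urgent share")
    net = referrals - removed
    return CalibrationTargets(
        mortality_target_pct=round(100.0 * deaths / net, 1),
        hospitalization_target_pct=round(100.0 * hospitalized / net, 1),
        urgent_share_target_pct=round(100.0 * unscheduled / tavis, 1),
        tolerance_pp=tolerance_pp,
    )


@dataclass
class CalibrationResult:
    params: HazardParams
    achieved: dict[str, float]
    targets: CalibrationTargets
    evaluations: int
    sweeps: int
    converged: bool
    history: list[dict] = field(default_factory=list)

    @property
    def residuals(self) -> dict[str, float]:
        t = self.targets.as_dict()
        return {k: self.achieved[k] - t[k] for k in t}


class _ReferenceEvaluator:
    """Cached CRN evaluation of the reference scenario.

    Cohorts, assignments, and every week's uniforms are drawn once; each
    evaluation only re-derives hazards from the candidate multipliers, so
    the achieved-outcome map is a deterministic function of HazardParams.
    """

    def __init__(
        self,
        population: PopulationParams,
        constraint: BudgetConstraint,
        n_replicates: int,
        seed: int,
    ):
        self.n_evaluations = 0
        scheme = reference_scheme()
        self._runs = []
        n = population.n_patients
        for r in range(n_replicates):
            cohort = sample_cohort(population, replicate=r)
            labels = classify_cohort(cohort, scheme)
            assignment = assign_wait_times(labels, scheme, constraint, seed=seed, replicate=r)
            max_week = int(assignment.assigned_wait_weeks.max())
            uni = np.stack(
                [_rng.event_uniforms(seed, r, t, n) for t in range(1, max_week + 1)]
            )
            self._runs.append((cohort, assignment, uni))

    def __call__(self, hazards: HazardParams) -> dict[str, float]:
        self.n_evaluations += 1
        summaries = []
        for cohort, assignment, uni in self._runs:
            fn = lambda week, n, _u=uni: _u[week - 1]
            summaries.append(simulate_assigned(cohort, assignment, hazards, fn).summarize())
        agg = aggregate_replicates(summaries)
        return {
            "mortality": agg.mortality_pct,
            "hospitalization": agg.hospitalization_pct,
            "urgent": agg.urgent_pct,
        }


# (outcome key, multiplier field) in fitting order: hospitalization drives the
# urgent flow and death is weakly coupled to both, so this order minimizes
# cross-talk per sweep.
_FIT_ORDER = (
    ("hospitalization", "mult_hosp"),
    ("urgent", "mult_urgent"),
    ("mortality", "mult_death"),
)


def _bisect_multiplier(
    evaluate, hazards: HazardParams, outcome: str, mult_field: str,
    target: float, tol: float, bounds: tuple[float, float], log_xtol: float = 1e-5,
) -> HazardParams:
    lo, hi = bounds

    def achieved(c: float) -> float:
        return evaluate(hazards.with_multipliers(**{mult_field: c}))[outcome]

    f_lo = achieved(lo) - target
    if f_lo > tol:
        raise CalibrationError(
            f"{outcome} target {target} unreachable: lower multiplier bound {lo} "
            f"already overshoots by {f_lo:.3f} pp"
        )
    f_hi = achieved(hi) - target
    if f_hi < -tol:
        raise CalibrationError(
            f"{outcome} target {target} unreachable: upper multiplier bound {hi} "
            f"still undershoots by {-f_hi:.3f} pp"
        )
    # Run the bisection all the way to the x-tolerance rather than stopping
    # as soon as the residual is inside `tol`: leaving slack in one fit gets
    # amplified by cross-talk from the later fits and can trap the outer
    # sweeps in a limit cycle at small evaluation sizes.
    best_c, best_res = (lo, abs(f_lo)) if abs(f_lo) < abs(f_hi) else (hi, abs(f_hi))
    while math.log(hi / lo) > log_xtol:
        mid = math.sqrt(lo * hi)
        fm = achieved(mid) - target
        if abs(fm) < best_res:
            best_c, best_res = mid, abs(fm)
        if fm == 0.0:
            break
        if fm < 0:
            lo = mid
        else:
            hi = mid
    return hazards.with_multipliers(**{mult_field: best_c})


def calibrate_reference(
    targets: CalibrationTargets,
    population: PopulationParams,
    hazards: HazardParams = HazardParams(),
    constraint: BudgetConstraint = BudgetConstraint(),
    *,
    eval_replicates: int = 20,
    seed: int = 0,
    max_sweeps: int = 5,
    bounds: tuple[float, float] = (0.02, 50.0),
    evaluator: "_ReferenceEvaluator | None" = None,
) -> CalibrationResult:
    """Fit the three hazard multipliers to the reference-scenario targets.

    Raises :class:`CalibrationError` with the residual trace if the targets
    are not met after ``max_sweeps`` outer sweeps, or if a target lies
    outside the reachable range of its multiplier.
    """
    if evaluator is None:
        evaluator = _ReferenceEvaluator(population, constraint, eval_replicates, seed)
    tol = targets.tolerance_pp
    tdict = targets.as_dict()
    history: list[dict] = []
    converged = False
    sweeps_used = 0
    for sweep in range(1, max_sweeps + 1):
        sweeps_used = sweep
        for outcome, mult_field in _FIT_ORDER:
            hazards = _bisect_multiplier(
                evaluator, hazards, outcome, mult_field, tdict[outcome], tol, bounds
            )
            achieved = evaluator(hazards)
            history.append(
                {
                    "sweep": sweep,
                    "parameter": mult_field,
                    "multiplier": getattr(hazards, mult_field),
                    **{f"residual_{k}": achieved[k] - tdict[k] for k in tdict},
                }
            )
        achieved = evaluator(hazards)
        if all(abs(achieved[k] - tdict[k]) <= tol for k in tdict):
            converged = True
            break
    achieved = evaluator(hazards)
    result = CalibrationResult(
        params=hazards,
        achieved=achieved,
        targets=targets,
        evaluations=evaluator.n_evaluations,
        sweeps=sweeps_used,
        converged=converged,
        history=history,
    )
    if not converged:
        trace = "; ".join(
            f"{k}: achieved {achieved[k]:.3f} vs target {tdict[k]:.3f}" for k in tdict
        )
        raise CalibrationError(
            f"calibration did not converge after {sweeps_used} sweeps ({trace})"
        )
    return result
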