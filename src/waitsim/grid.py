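"""Scenario-grid enumeration, CRN execution, and benchmark selection.

The grid crosses high/medium tier sizes with high-tier waits and medium
increments (three-group panels), plus an equal-thirds variant and a
two-group variant. Every combination is compared to the no-prioritization
reference with common random numbers, and the benchmark scheme is the
feasible combination with the best primary outcome subject to a cap on the
solved low-risk wait.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import _rng
from .engine import OutcomeSummary, aggregate_replicates, simulate_assigned
from .errors import ConfigurationError, EmptySelectionError, InfeasibleSchemeError, UndefinedRelativeRiskError
from .hazards import HazardParams
from .prioritization import (
    BudgetConstraint,
    GroupScheme,
    OrderingViolationWarning,
    assign_wait_times,
    classify_cohort,
    reference_scheme,
    solve_low_risk_wait,
)
from .risk_population import PopulationParams, sample_cohort

DEFAULT_SIZES = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30)
DEFAULT_HIGH_WAITS = (3, 4, 5)
DEFAULT_MEDIUM_INCREMENTS = (2, 4, 6)


@dataclass(frozen=True)
class GridSpec:
    high_sizes: tuple[float, ...] = DEFAULT_SIZES
    medium_sizes: tuple[float, ...] = DEFAULT_SIZES
    high_waits: tuple[int, ...] = DEFAULT_HIGH_WAITS
    medium_increments: tuple[int, ...] = DEFAULT_MEDIUM_INCREMENTS
    include_equal_thirds: bool = True
    include_two_group: bool = True
    constraint: BudgetConstraint = BudgetConstraint()
    classifier_outcome: str = "latent"

    def __post_init__(self) -> None:
        for name in ("high_sizes", "medium_sizes"):
            if any(not (0.0 < s < 1.0) for s in getattr(self, name)):
                raise ConfigurationError(f"{name} entries must lie in (0, 1)")
        if any(w <= 0 for w in self.high_waits):
            raise ConfigurationError("high_waits must be positive")
        if any(i <= 0 for i in self.medium_increments):
            raise ConfigurationError("medium_increments must be positive")


@dataclass(frozen=True)
class GridCombo:
    """One enumerated (scheme, waits) combination with its grid coordinates."""

    scenario_id: str
    kind: str  # three_group | equal_thirds | two_group
    sizes: tuple[float, ...]
    waits: tuple[int, ...]
    panel: tuple[int, int | None]  # (high wait, medium increment)
    quadrant: tuple[float, float | None]  # (high size, medium size)

    def scheme(self, classifier_outcome: str = "latent") -> GroupScheme:
        return GroupScheme(
            sizes=self.sizes,
            waits_prioritized=self.waits,
            classifier_outcome=classifier_outcome,  # type: ignore[arg-type]
        )


def enumerate_grid(spec: GridSpec) -> list[GridCombo]:
    """All grid combinations, deduplicated, tagged with panel/quadrant."""
    combos: list[GridCombo] = []
    seen: set[tuple] = set()

    def add(combo: GridCombo) -> None:
        key = (tuple(round(s, 9) for s in combo.sizes), combo.waits)
        if key not in seen:
            seen.add(key)
            combos.append(combo)

    for hw in spec.high_waits:
        for inc in spec.medium_increments:
            mw = hw + inc
            for hs in spec.high_sizes:
                for ms in spec.medium_sizes:
                    low = 1.0 - hs - ms
                    if low <= 0:
                        continue
                    add(
                        GridCombo(
                            scenario_id=f"3g_h{hs:.2f}_m{ms:.2f}_w{hw}_{mw}",
                            kind="three_group",
                            sizes=(hs, ms, low),
                            waits=(hw, mw),
                            panel=(hw, inc),
                            quadrant=(hs, ms),
                        )
                    )
            if spec.include_equal_thirds:
                third = 1.0 / 3.0
                add(
                    GridCombo(
                        scenario_id=f"eq_w{hw}_{mw}",
                        kind="equal_thirds",
                        sizes=(third, third, third),
                        waits=(hw, mw),
                        panel=(hw, inc),
                        quadrant=(third, third),
                    )
                )
        if spec.include_two_group:
            for hs in spec.high_sizes:
                add(
                    GridCombo(
                        scenario_id=f"2g_h{hs:.2f}_w{hw}",
                        kind="two_group",
                        sizes=(hs, 1.0 - hs),
                        waits=(hw,),
                        panel=(hw, None),
                        quadrant=(hs, None),
                    )
                )
    return combos


def relative_risk(scenario_value_pct: float, reference_value_pct: float) -> float:
    """Ratio of outcome percentages, computed on unrounded values."""
    if reference_value_pct <= 0:
        raise UndefinedRelativeRiskError(
            f"relative risk undefined for reference value {reference_value_pct!r}"
        )
    return scenario_value_pct / reference_value_pct


@dataclass
class GridResult:
    """Per-combination outcomes plus the shared reference summary."""

    table: pd.DataFrame
    reference: OutcomeSummary
    spec: GridSpec = field(repr=False)

    def to_csv(self, path, **kwargs) -> None:
        self.table.to_csv(path, index=False, **kwargs)


_OUTCOME_COLS = ("mortality", "hospitalization", "urgent")


def run_grid(
    spec: GridSpec,
    hazards: HazardParams,
    population: PopulationParams,
    *,
    n_replicates: int = 100,
    seed: int = 0,
) -> GridResult:
    """Simulate every grid combination plus the reference under CRN.

    Replicates are the outer loop so each replicate's cohort and event
    uniforms are drawn once and shared by all combinations (and the
    reference). Infeasible combinations are flagged and skipped; rows with
    an ordering violation (solved low wait not above every prioritized
    wait) are simulated but flagged.
    """
    combos = enumerate_grid(spec)
    rows: list[dict] = []
    solved: dict[str, float] = {}
    feasible: dict[str, bool] = {}
    violation: dict[str, bool] = {}
    for combo in combos:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OrderingViolationWarning)
                w_low = solve_low_risk_wait(combo.sizes, combo.waits, spec.constraint)
            solved[combo.scenario_id] = w_low
            feasible[combo.scenario_id] = True
            violation[combo.scenario_id] = bool(combo.waits) and w_low <= max(combo.waits)
        except InfeasibleSchemeError:
            solved[combo.scenario_id] = float("nan")
            feasible[combo.scenario_id] = False
            violation[combo.scenario_id] = False

    per_combo: dict[str, list[OutcomeSummary]] = {c.scenario_id: [] for c in combos}
    ref_summaries: list[OutcomeSummary] = []
    ref_sch = reference_scheme()
    max_week_cap = 1 + int(
        np.ceil(max([w for w in solved.values() if np.isfinite(w)] + [spec.constraint.target_mean_wait]))
    )
    for r in range(n_replicates):
        cohort = sample_cohort(population, replicate=r)
        n = population.n_patients
        uni = [_rng.event_uniforms(seed, r, t, n) for t in range(1, max_week_cap + 1)]

        def uniforms(week: int, _n: int) -> np.ndarray:
            while week > len(uni):  # ordering violations can push past the cap
                uni.append(_rng.event_uniforms(seed, r, len(uni) + 1, n))
            return uni[week - 1]

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OrderingViolationWarning)
            ref_assignment = assign_wait_times(
                classify_cohort(cohort, ref_sch), ref_sch, spec.constraint, seed=seed, replicate=r
            )
            ref_summaries.append(
                simulate_assigned(cohort, ref_assignment, hazards, uniforms).summarize()
            )
            for combo in combos:
                if not feasible[combo.scenario_id]:
                    continue
                scheme = combo.scheme(spec.classifier_outcome)
                labels = classify_cohort(cohort, scheme)
                assignment = assign_wait_times(
                    labels, scheme, spec.constraint, seed=seed, replicate=r
                )
                per_combo[combo.scenario_id].append(
                    simulate_assigned(cohort, assignment, hazards, uniforms).summarize()
                )

    reference = aggregate_replicates(ref_summaries)
    ref_values = {
        "mortality": reference.mortality_pct,
        "hospitalization": reference.hospitalization_pct,
        "urgent": reference.urgent_pct,
    }
    for combo in combos:
        sid = combo.scenario_id
        row: dict = {
            "scenario_id": sid,
            "kind": combo.kind,
            "high_size": combo.quadrant[0],
            "medium_size": combo.quadrant[1],
            "low_size": combo.sizes[-1],
            "high_wait": combo.panel[0],
            "medium_increment": combo.panel[1],
            "medium_wait": combo.waits[1] if len(combo.waits) > 1 else None,
            "solved_low_wait": solved[sid],
            "feasible": feasible[sid],
            "ordering_violation": violation[sid],
        }
        if feasible[sid]:
            agg = aggregate_replicates(per_combo[sid])
            values = {
                "mortality": agg.mortality_pct,
                "hospitalization": agg.hospitalization_pct,
                "urgent": agg.urgent_pct,
            }
            se = agg.monte_carlo_se or {}
            for key, col in zip(
                ("mortality_pct", "hospitalization_pct", "urgent_pct", "mean_realized_wait"),
                ("mortality", "hospitalization", "urgent", "wait"),
            ):
                row[f"{col}_mean" if col == "wait" else key] = getattr(agg, key)
                if key in se:
                    row[f"{key}_se"] = se[key]
            for name in _OUTCOME_COLS:
                row[f"rr_{name}"] = relative_risk(values[name], ref_values[name])
        else:
            for name in ("mortality_pct", "hospitalization_pct", "urgent_pct", "wait_mean"):
                row[name] = float("nan")
            for name in _OUTCOME_COLS:
                row[f"rr_{name}"] = float("nan")
        rows.append(row)
    return GridResult(table=pd.DataFrame(rows), reference=reference, spec=spec)


def select_benchmark(
    result: GridResult,
    max_low_wait: float = 16.0,
    primary_outcome: str = "mortality",
) -> pd.Series:
    """Best feasible row under the low-risk wait cap.

    Minimizes the primary outcome; ties broken by hospitalization, urgent
    share, then smaller solved low wait. Infeasible and ordering-violating
    rows are never selected.
    """
    if primary_outcome not in _OUTCOME_COLS:
        raise ConfigurationError(f"primary_outcome must be one of {_OUTCOME_COLS}")
    t = result.table
    eligible = t[
        t["feasible"] & ~t["ordering_violation"] & (t["solved_low_wait"] <= max_low_wait)
    ]
    if eligible.empty:
        raise EmptySelectionError(
            f"no feasible grid row has a solved low-risk wait <= {max_low_wait}"
        )
    order_cols = {
        "mortality": ["mortality_pct", "hospitalization_pct", "urgent_pct", "solved_low_wait"],
        "hospitalization": ["hospitalization_pct", "mortality_pct", "urgent_pct", "solved_low_wait"],
        "urgent": ["urgent_pct", "mortality_pct", "hospitalization_pct", "solved_low_wait"],
    }[primary_outcome]
    return eligible.sort_values(order_cols, kind="mergesort").iloc[0]
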