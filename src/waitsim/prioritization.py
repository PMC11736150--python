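"""Risk tiers, classification, and budget-constrained wait-time allocation.

Capacity is modelled as a constraint on the cohort-weighted mean assigned
wait: prioritized tiers get fixed integer waits and the non-prioritized
(low-risk) tier absorbs whatever wait keeps the size-weighted mean at the
target (12.5 weeks by default). Because the engine runs on whole weeks and
the solved low-risk wait is generally fractional, low-tier patients are
randomized between the two adjacent integer weeks in the exact proportion
that preserves the budget.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from ._rng import ASSIGN, generator
from .errors import ConfigurationError, InfeasibleSchemeError
from .risk_population import Cohort

GROUP_NAMES_3 = ("high", "medium", "low")
GROUP_NAMES_2 = ("high", "low")

Classifier = Literal["latent", "death", "hosp", "urgent"]


class OrderingViolationWarning(UserWarning):
    """Solved low-risk wait does not exceed every prioritized wait."""


@dataclass(frozen=True)
class BudgetConstraint:
    """Fixed-capacity constraint: size-weighted mean assigned wait in weeks."""

    target_mean_wait: float = 12.5

    def __post_init__(self) -> None:
        if not self.target_mean_wait > 0:
            raise ConfigurationError(
                f"target_mean_wait must be > 0, got {self.target_mean_wait!r}"
            )


@dataclass(frozen=True)
class GroupScheme:
    """Tier sizes (high -> low) and integer waits for the prioritized tiers.

    ``sizes`` has one entry per tier and sums to 1; ``waits_prioritized``
    has one entry per tier except the last (low-risk) tier, whose wait is
    solved from the budget constraint. A single-tier scheme (sizes == (1.0,),
    no prioritized waits) is the first-come-first-served reference.
    """

    sizes: tuple[float, ...]
    waits_prioritized: tuple[int, ...] = ()
    classifier_outcome: Classifier = "latent"

    def __post_init__(self) -> None:
        sizes = tuple(float(s) for s in self.sizes)
        object.__setattr__(self, "sizes", sizes)
        object.__setattr__(self, "waits_prioritized", tuple(self.waits_prioritized))
        if len(sizes) not in (1, 2, 3):
            raise ConfigurationError(f"sizes must have 1-3 entries, got {len(sizes)}")
        if any(s <= 0 for s in sizes):
            raise ConfigurationError(f"sizes must all be > 0, got {sizes}")
        if abs(sum(sizes) - 1.0) > 1e-9:
            raise ConfigurationError(f"sizes must sum to 1 (got {sum(sizes)!r})")
        if len(self.waits_prioritized) != len(sizes) - 1:
            raise ConfigurationError(
                "waits_prioritized must have one entry per tier except the last "
                f"(got {len(self.waits_prioritized)} for {len(sizes)} tiers)"
            )
        if any(w <= 0 for w in self.waits_prioritized):
            raise ConfigurationError(
                f"waits_prioritized must be positive, got {self.waits_prioritized}"
            )
        if self.classifier_outcome not in ("latent", "death", "hosp", "urgent"):
            raise ConfigurationError(
                f"classifier_outcome must be latent/death/hosp/urgent, got {self.classifier_outcome!r}"
            )

    @property
    def n_groups(self) -> int:
        return len(self.sizes)

    @property
    def group_names(self) -> tuple[str, ...]:
        if self.n_groups == 3:
            return GROUP_NAMES_3
        if self.n_groups == 2:
            return GROUP_NAMES_2
        return ("low",)


def reference_scheme() -> GroupScheme:
    """Status-quo scheme: one tier, everyone at the mean wait."""
    return GroupScheme(sizes=(1.0,))


@dataclass
class WaitAssignment:
    """Per-patient tier labels and integer assigned waits."""

    group: np.ndarray  # str labels, one per patient
    assigned_wait_weeks: np.ndarray  # positive ints
    solved_low_wait: float
    scheme: GroupScheme = field(repr=False)
    ordering_violation: bool = False

    def __len__(self) -> int:
        return len(self.group)

    def to_frame(self, patient_id: np.ndarray | None = None) -> pd.DataFrame:
        if patient_id is None:
            patient_id = np.arange(len(self))
        return pd.DataFrame(
            {
                "patient_id": patient_id,
                "group": self.group,
                "assigned_wait_weeks": self.assigned_wait_weeks,
            }
        )


def solve_low_risk_wait(
    sizes: Sequence[float],
    waits_prioritized: Sequence[float],
    constraint: BudgetConstraint = BudgetConstraint(),
    *,
    warn: bool = True,
) -> float:
    """Closed-form low-risk wait satisfying the budget identity.

    w_low = (target - sum_prioritized p_g * w_g) / p_low. Raises
    :class:`InfeasibleSchemeError` when the solution is non-positive; emits
    :class:`OrderingViolationWarning` (but still returns) when the solved
    wait does not exceed every prioritized wait.
    """
    sizes = [float(s) for s in sizes]
    waits = [float(w) for w in waits_prioritized]
    if len(waits) != len(sizes) - 1:
        raise ConfigurationError(
            "need exactly one prioritized wait per tier except the last"
        )
    p_low = sizes[-1]
    spent = sum(p * w for p, w in zip(sizes[:-1], waits))
    w_low = (constraint.target_mean_wait - spent) / p_low
    if w_low <= 0:
        raise InfeasibleSchemeError(
            f"scheme sizes={sizes} waits={waits} leaves non-positive low-risk "
            f"wait {w_low:.3f} under target mean {constraint.target_mean_wait}"
        )
    if warn and waits and w_low <= max(waits):
        warnings.warn(
            f"solved low-risk wait {w_low:.3f} does not exceed the longest "
            f"prioritized wait {max(waits)}",
            OrderingViolationWarning,
            stacklevel=2,
        )
    return w_low


def _group_counts(n: int, sizes: Sequence[float]) -> np.ndarray:
    """Partition n patients into groups matching ``sizes`` within +/- 1."""
    bounds = np.rint(np.cumsum(sizes) * n).astype(int)
    bounds[-1] = n
    return np.diff(np.concatenate(([0], bounds)))


def classify_cohort(cohort: Cohort, scheme: GroupScheme) -> np.ndarray:
    """Label each patient high/medium/low by the scheme's classifier risk.

    The top ``sizes[0]`` fraction by classifier value is high-risk, the next
    ``sizes[1]`` medium (three-tier schemes), the remainder low. Ties are
    broken by ascending patient_id for reproducibility.
    """
    n = len(cohort)
    if n < scheme.n_groups:
        raise ConfigurationError(
            f"cohort of size {n} cannot be split into {scheme.n_groups} groups"
        )
    if scheme.classifier_outcome == "latent":
        key = cohort.u_latent
    else:
        key = cohort.margin_values(scheme.classifier_outcome)
    # lexsort: last key is primary. Descending risk, ascending id on ties.
    order = np.lexsort((cohort.patient_id, -key))
    counts = _group_counts(n, scheme.sizes)
    labels = np.empty(n, dtype=object)
    start = 0
    for name, count in zip(scheme.group_names, counts):
        labels[order[start : start + count]] = name
        start += count
    return labels.astype(str)


def assign_wait_times(
    labels: np.ndarray,
    scheme: GroupScheme,
    constraint: BudgetConstraint = BudgetConstraint(),
    seed: int = 0,
    replicate: int = 0,
) -> WaitAssignment:
    """Assign integer waits so the realized cohort mean hits the budget.

    Prioritized tiers receive their configured wait verbatim. The low tier's
    continuous solved wait w_low is realized by giving exactly
    ``round(n_low * frac(w_low))`` randomly chosen low-tier patients the
    ceiling week and the rest the floor week, which pins the cohort mean to
    the target within 1/(2n) weeks. The low wait is re-solved against the
    realized integer group counts so partition rounding cannot leak into the
    budget.
    """
    n = len(labels)
    waits = np.zeros(n, dtype=np.int64)
    names = scheme.group_names
    counts = {name: int(np.sum(labels == name)) for name in names}

    ordering_violation = False
    spent = 0
    for name, w in zip(names[:-1], scheme.waits_prioritized):
        waits[labels == name] = int(w)
        spent += counts[name] * int(w)
    n_low = counts[names[-1]]
    w_low = (constraint.target_mean_wait * n - spent) / n_low
    if w_low <= 0:
        raise InfeasibleSchemeError(
            f"realized counts leave non-positive low-risk wait {w_low:.3f}"
        )
    if scheme.waits_prioritized and w_low <= max(scheme.waits_prioritized):
        ordering_violation = True
        warnings.warn(
            f"solved low-risk wait {w_low:.3f} does not exceed the longest "
            f"prioritized wait {max(scheme.waits_prioritized)}",
            OrderingViolationWarning,
            stacklevel=2,
        )

    floor_w = int(np.floor(w_low))
    frac = w_low - floor_w
    low_idx = np.flatnonzero(labels == names[-1])
    n_ceil = int(np.rint(n_low * frac))
    low_waits = np.full(n_low, floor_w, dtype=np.int64)
    if n_ceil > 0:
        rng = generator(seed, replicate, ASSIGN)
        bumped = rng.permutation(n_low)[:n_ceil]
        low_waits[bumped] = floor_w + 1
    if floor_w == 0:
        # w_low in (0, 1): floor would assign a zero-week wait; use week 1.
        low_waits = np.maximum(low_waits, 1)
    waits[low_idx] = low_waits
    return WaitAssignment(
        group=np.asarray(labels, dtype=str),
        assigned_wait_weeks=waits,
        solved_low_wait=float(w_low),
        scheme=scheme,
        ordering_violation=ordering_violation,
    )
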