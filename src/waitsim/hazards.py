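"""Weibull time-escalation of 12-week predicted risks.

A patient with predicted risk p12 at the horizon T = 12 weeks is given a
Weibull cumulative hazard H(t) = lambda * t^k with the scale chosen so the
cumulative incidence at T equals p12 (times a calibration multiplier on the
cumulative hazard). Shape k >= 1 makes the weekly event probability
non-decreasing in time waited; k = 1 recovers a memoryless process.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError, DomainError, InfiniteHazardError

RISK_HORIZON_WEEKS = 12.0


@dataclass(frozen=True)
class HazardParams:
    """Weibull shapes plus the calibration multipliers.

    ``mult_death`` / ``mult_hosp`` scale the cumulative hazards of the two
    time-to-event processes; ``mult_urgent`` scales the per-hospitalization
    urgent-conversion probability (clipped at 1).
    """

    shape_death: float = 1.5
    shape_hosp: float = 1.5
    mult_death: float = 1.0
    mult_hosp: float = 1.0
    mult_urgent: float = 1.0
    risk_horizon: float = RISK_HORIZON_WEEKS

    def __post_init__(self) -> None:
        for name in ("shape_death", "shape_hosp"):
            if not getattr(self, name) >= 1.0:
                raise ConfigurationError(
                    f"{name} must be >= 1 (non-decreasing hazard), got {getattr(self, name)!r}"
                )
        for name in ("mult_death", "mult_hosp", "mult_urgent"):
            if not getattr(self, name) > 0.0:
                raise ConfigurationError(f"{name} must be > 0, got {getattr(self, name)!r}")
        if not self.risk_horizon > 0:
            raise ConfigurationError(f"risk_horizon must be > 0, got {self.risk_horizon!r}")

    def with_multipliers(self, mult_death=None, mult_hosp=None, mult_urgent=None) -> "HazardParams":
        return replace(
            self,
            mult_death=self.mult_death if mult_death is None else mult_death,
            mult_hosp=self.mult_hosp if mult_hosp is None else mult_hosp,
            mult_urgent=self.mult_urgent if mult_urgent is None else mult_urgent,
        )


def weibull_scale_from_risk(p12, shape: float, horizon: float = RISK_HORIZON_WEEKS, multiplier: float = 1.0):
    """Weibull rate scale lambda such that 1 - exp(-lambda * T^k) = p12 at c = 1.

    lambda = c * (-ln(1 - p12)) / T^k. Accepts scalars or arrays.
    """
    p = np.asarray(p12, dtype=float)
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise DomainError(f"p12 must lie in [0, 1), got {p12!r}")
    if np.any(p == 1.0):
        raise InfiniteHazardError("p12 = 1 implies an infinite hazard rate")
    lam = multiplier * (-np.log1p(-p)) / horizon**shape
    return lam if lam.shape else float(lam)


def weekly_event_prob(lam, shape: float, week):
    """Probability of an event during week ``week`` given survival so far.

    q_t = 1 - exp(-lambda * (t^k - (t-1)^k)); strictly increasing in t for
    k > 1, constant for k = 1.
    """
    t = np.asarray(week)
    if np.any(t < 1) or np.any(t != np.floor(t)):
        raise DomainError(f"week must be an integer >= 1, got {week!r}")
    t = t.astype(float)
    lam = np.asarray(lam, dtype=float)
    q = -np.expm1(-lam * (t**shape - (t - 1.0) ** shape))
    return q if q.shape else float(q)


def cumulative_incidence(lam, shape: float, weeks):
    """Closed-form cumulative incidence 1 - exp(-lambda * w^k)."""
    w = np.asarray(weeks, dtype=float)
    if np.any(w < 0):
        raise DomainError(f"weeks must be >= 0, got {weeks!r}")
    lam = np.asarray(lam, dtype=float)
    ci = -np.expm1(-lam * w**shape)
    return ci if ci.shape else float(ci)


def urgent_conversion_prob(p_urgent_given_hosp, multiplier: float = 1.0):
    """Per-hospitalization urgent-conversion probability, clipped at 1."""
    p = np.asarray(p_urgent_given_hosp, dtype=float)
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise DomainError("p_urgent_given_hosp must lie in [0, 1]")
    out = np.minimum(1.0, multiplier * p)
    return out if out.shape else float(out)
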