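"""Synthetic cohort generation.

Each patient carries three 12-week predicted risks (death, hospitalization,
urgent-procedure conversion given hospitalization). The three margins are
Beta distributed, parameterized by a mean and a dispersion control, and are
driven comonotonically by a single latent severity quantile per patient: a
sicker patient is sicker on every margin. Dispersion maps to the Beta
concentration as s = 1/dispersion, so a larger dispersion yields a heavier
right tail at a fixed mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Literal

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import COHORT, generator
from .errors import ConfigurationError, DomainError

Outcome = Literal["death", "hosp", "urgent"]

_OUTCOMES: tuple[Outcome, ...] = ("death", "hosp", "urgent")


@dataclass(frozen=True)
class PopulationParams:
    """Marginal means and dispersions of the synthetic risk distribution.

    Means live in [0, 1); a mean of exactly 0 degenerates the margin to a
    point mass at zero (useful for switching an event process off).
    Dispersions are strictly positive; larger values give more right-skewed
    margins. Defaults are implementation choices tuned so the urgent margin
    is the most skewed of the three, not values taken from any registry.
    """

    n_patients: int
    mean_death12: float = 0.035
    mean_hosp12: float = 0.30
    mean_urgent_given_hosp: float = 0.12
    dispersion_death: float = 0.05
    dispersion_hosp: float = 0.5
    dispersion_urgent: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (isinstance(self.n_patients, (int, np.integer)) and self.n_patients >= 1):
            raise ConfigurationError(f"n_patients must be a positive integer, got {self.n_patients!r}")
        for name in ("mean_death12", "mean_hosp12", "mean_urgent_given_hosp"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1), got {v!r}")
        for name in ("dispersion_death", "dispersion_hosp", "dispersion_urgent"):
            v = getattr(self, name)
            if not v > 0.0:
                raise ConfigurationError(f"{name} must be > 0, got {v!r}")

    def margin(self, outcome: Outcome) -> tuple[float, float]:
        """(mean, dispersion) of one margin."""
        if outcome == "death":
            return self.mean_death12, self.dispersion_death
        if outcome == "hosp":
            return self.mean_hosp12, self.dispersion_hosp
        if outcome == "urgent":
            return self.mean_urgent_given_hosp, self.dispersion_urgent
        raise ConfigurationError(f"unknown outcome {outcome!r}")

    def with_seed(self, seed: int) -> "PopulationParams":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class RiskProfile:
    """One patient's latent severity quantile and 12-week predicted risks."""

    patient_id: int
    u_latent: float
    p_death12: float
    p_hosp12: float
    p_urgent_given_hosp: float


@dataclass
class Cohort:
    """A sampled population, stored column-wise for vectorized simulation."""

    patient_id: np.ndarray
    u_latent: np.ndarray
    p_death12: np.ndarray
    p_hosp12: np.ndarray
    p_urgent_given_hosp: np.ndarray
    params: PopulationParams = field(repr=False)

    def __len__(self) -> int:
        return len(self.patient_id)

    @property
    def profiles(self) -> Iterator[RiskProfile]:
        for i in range(len(self)):
            yield RiskProfile(
                patient_id=int(self.patient_id[i]),
                u_latent=float(self.u_latent[i]),
                p_death12=float(self.p_death12[i]),
                p_hosp12=float(self.p_hosp12[i]),
                p_urgent_given_hosp=float(self.p_urgent_given_hosp[i]),
            )

    def margin_values(self, outcome: Outcome) -> np.ndarray:
        return {
            "death": self.p_death12,
            "hosp": self.p_hosp12,
            "urgent": self.p_urgent_given_hosp,
        }[outcome]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "u_latent": self.u_latent,
                "p_death12": self.p_death12,
                "p_hosp12": self.p_hosp12,
                "p_urgent_given_hosp": self.p_urgent_given_hosp,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, params: PopulationParams | None = None) -> "Cohort":
        df = pd.read_csv(path)
        required = ["patient_id", "u_latent", "p_death12", "p_hosp12", "p_urgent_given_hosp"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ConfigurationError(f"cohort CSV is missing columns: {missing}")
        if params is None:
            params = PopulationParams(n_patients=len(df))
        return cls(
            patient_id=df["patient_id"].to_numpy(dtype=np.int64),
            u_latent=df["u_latent"].to_numpy(dtype=float),
            p_death12=df["p_death12"].to_numpy(dtype=float),
            p_hosp12=df["p_hosp12"].to_numpy(dtype=float),
            p_urgent_given_hosp=df["p_urgent_given_hosp"].to_numpy(dtype=float),
            params=params,
        )


def _beta_shapes(mean: float, dispersion: float) -> tuple[float, float]:
    s = 1.0 / dispersion
    return mean * s, (1.0 - mean) * s


def marginal_quantile(params: PopulationParams, outcome: Outcome, u) -> np.ndarray | float:
    """Inverse CDF of one risk margin, evaluated at quantile(s) ``u``.

    Strictly increasing in u for non-degenerate margins; a zero-mean margin
    returns 0 everywhere.
    """
    u_arr = np.asarray(u, dtype=float)
    if np.any(u_arr <= 0.0) or np.any(u_arr >= 1.0):
        raise DomainError(f"quantile u must lie strictly in (0, 1), got {u!r}")
    mean, dispersion = params.margin(outcome)
    if mean == 0.0:
        out = np.zeros_like(u_arr)
        return out if out.shape else 0.0
    a, b = _beta_shapes(mean, dispersion)
    out = stats.beta.ppf(u_arr, a, b)
    return out if out.shape else float(out)


def sample_cohort(params: PopulationParams, replicate: int = 0) -> Cohort:
    """Draw a cohort of ``params.n_patients`` comonotone risk profiles.

    Deterministic given (params.seed, replicate). A single latent uniform
    per patient is pushed through each margin's inverse CDF, so all three
    risks are non-decreasing in the latent severity.
    """
    n = params.n_patients
    rng = generator(params.seed, replicate, COHORT)
    # Clip away exact endpoints so Beta ppf stays inside (0, 1).
    u = np.clip(rng.random(n), 1e-12, 1.0 - 1e-12)
    cols = {}
    for outcome, col in zip(_OUTCOMES, ("p_death12", "p_hosp12", "p_urgent_given_hosp")):
        mean, dispersion = params.margin(outcome)
        if mean == 0.0:
            cols[col] = np.zeros(n)
        else:
            a, b = _beta_shapes(mean, dispersion)
            cols[col] = stats.beta.ppf(u, a, b)
    return Cohort(
        patient_id=np.arange(n, dtype=np.int64),
        u_latent=u,
        params=params,
        **cols,
    )


def risk_percentile_threshold(cohort: Cohort, outcome: Outcome, top_fraction: float) -> float:
    """Empirical risk value separating the top ``top_fraction`` of a cohort.

    Nearest-rank (ceiling) definition of the (1 - top_fraction) empirical
    quantile: at most ``ceil(n * top_fraction)`` patients lie at or above the
    returned threshold when risks are distinct.
    """
    n = len(cohort)
    if n == 0:
        raise DomainError("cohort is empty")
    if not (0.0 < top_fraction < 1.0):
        raise DomainError(f"top_fraction must lie in (0, 1), got {top_fraction!r}")
    values = np.sort(cohort.margin_values(outcome))
    # Nearest-rank (ceiling) rule: the threshold is the smallest value among
    # the top ceil(n * top_fraction) patients, so with distinct risks exactly
    # that many lie at or above it and at most n * top_fraction lie strictly
    # above it.
    k = int(np.ceil(n * top_fraction))
    k = min(max(k, 1), n)
    return float(values[n - k])
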