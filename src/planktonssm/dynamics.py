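"""Deterministic discrete-time Lotka-Volterra process model for lake plankton.

The process couples phytoplankton abundance ``x`` (chlorophyll-a, ug/L) to
zooplankton biomass ``y`` (ug/L dry mass) through one-step updates

    x' = x + psi * x - c * x * y
    y' = y + c * e * x * y - m * y

where ``psi`` is the phytoplankton population growth rate, ``c`` the
consumption (grazing) rate, ``e`` the energy efficiency of the zooplankton
and ``m`` the zooplankton mortality rate, all per sampling interval.
Lake-specific rates are driven by covariates through link functions:
``c`` is linear in standardized water temperature and ``log(psi)`` is linear
in standardized phosphorus load; ``m`` takes one of two levels according to
fish presence.

Abundances are physical quantities, so states are clipped at zero (with a
logged warning) whenever the raw update would go negative; zero is absorbing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "LakeCovariates",
    "StandardizedCovariates",
    "LakeParams",
    "LatentTrajectory",
    "standardize",
    "link_c",
    "link_psi",
    "mortality_for",
    "step",
    "simulate_trajectory",
    "equilibrium",
]


@dataclass(frozen=True)
class LakeCovariates:
    """Per-lake covariates measured once per season.

    ``toc`` is carried by the generator for the correlative layer only; the
    process model itself consumes temperature and phosphorus.
    """

    lake_id: str
    fish_present: bool
    temp_c: float
    tot_p: float
    tot_n: float
    toc: float
    veg_cover: float

    def __post_init__(self) -> None:
        if self.tot_p <= 0:
            raise ValueError(f"lake {self.lake_id}: tot_p must be > 0, got {self.tot_p}")
        if self.tot_n <= 0:
            raise ValueError(f"lake {self.lake_id}: tot_n must be > 0, got {self.tot_n}")
        if not 0.0 <= self.veg_cover <= 100.0:
            raise ValueError(
                f"lake {self.lake_id}: veg_cover must be in [0, 100], got {self.veg_cover}"
            )


@dataclass(frozen=True)
class StandardizedCovariates:
    """Standardized temperature (st) and phosphorus load (sp) for one lake."""

    st: float
    sp: float


@dataclass(frozen=True)
class LakeParams:
    """Demographic rates of one lake, per sampling interval.

    ``e`` is shared across lakes in the hierarchical model but stored here so
    a single lake's dynamics are self-contained.
    """

    c: float
    psi: float
    m: float
    e: float

    def __post_init__(self) -> None:
        if self.psi <= 0:
            raise ValueError(f"psi must be > 0, got {self.psi}")
        if not 0.0 <= self.m <= 1.0:
            raise ValueError(f"m must be in [0, 1], got {self.m}")
        if not 0.0 < self.e <= 1.0:
            raise ValueError(f"e must be in (0, 1], got {self.e}")


@dataclass(frozen=True)
class LatentTrajectory:
    """True (unobserved) plankton states over time for one lake."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
            raise ValueError("x and y must be equal-length 1-d arrays, length >= 1")
        if (x < 0).any() or (y < 0).any():
            raise ValueError("latent states must be non-negative")

    def __len__(self) -> int:
        return len(self.x)


def standardize(values) -> np.ndarray:
    """Center and scale to sample mean 0 and sample sd 1 (n-1 denominator).

    Raises ``ValueError`` on fewer than two values or constant input.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("standardize() needs a 1-d sequence of length >= 2")
    sd = v.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("standardize() undefined for constant input (sd = 0)")
    return (v - v.mean()) / sd


def link_c(alpha_c: float, beta_c: float, st: float) -> float:
    """Consumption rate from standardized temperature: identity link.

    The value may be negative; callers decide whether that is admissible
    (the sampler allows it, the data generator does not).
    """
    return alpha_c + beta_c * st


def link_psi(alpha_psi: float, beta_psi: float, sp: float) -> float:
    """Phytoplankton growth rate from standardized phosphorus load: log link."""
    return math.exp(alpha_psi + beta_psi * sp)


def mortality_for(fish_present: bool, m_fish: float, m_nofish: float) -> float:
    """Two-level zooplankton mortality: one rate with fish, one without."""
    for name, m in (("m_fish", m_fish), ("m_nofish", m_nofish)):
        if not 0.0 <= m <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {m}")
    return m_fish if fish_present else m_nofish


def step(x_t: float, y_t: float, params: LakeParams) -> tuple[float, float]:
    """One time-step update of the predator-prey pair, clipped at zero."""
    if x_t < 0 or y_t < 0:
        raise ValueError(f"abundances must be non-negative, got x={x_t}, y={y_t}")
    x_next = x_t + params.psi * x_t - params.c * x_t * y_t
    y_next = y_t + params.c * params.e * x_t * y_t - params.m * y_t
    if x_next < 0 or y_next < 0:
        logger.warning(
            "step() produced a negative state (x'=%.4g, y'=%.4g); clipping at 0",
            x_next,
            y_next,
        )
        x_next = max(x_next, 0.0)
        y_next = max(y_next, 0.0)
    return x_next, y_next


def simulate_trajectory(
    x1: float, y1: float, params: LakeParams, n_times: int
) -> LatentTrajectory:
    """Iterate :func:`step` from the initial state to a length-``n_times`` path."""
    if n_times < 1:
        raise ValueError(f"n_times must be >= 1, got {n_times}")
    x = np.empty(n_times)
    y = np.empty(n_times)
    x[0], y[0] = x1, y1
    for t in range(1, n_times):
        x[t], y[t] = step(x[t - 1], y[t - 1], params)
    return LatentTrajectory(x=x, y=y)


def equilibrium(params: LakeParams) -> tuple[float, float]:
    """Interior fixed point (x*, y*) = (m / (c e), psi / c).

    x* is where the predator's net change vanishes (its zero-isocline) and
    y* where the prey's does; :func:`step` leaves this point unchanged.
    """
    if params.c <= 0 or params.e <= 0:
        raise ValueError("no interior equilibrium: need c > 0 and e > 0")
    return params.m / (params.c * params.e), params.psi / params.c
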