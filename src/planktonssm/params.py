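"""Containers shared between the generator and the inference machinery."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = ["HyperParams", "ObservationSeries"]


@dataclass
class HyperParams:
    """All estimated quantities of the hierarchical state-space model.

    ``alpha_c``/``beta_c``: intercept and slope of the consumption-rate vs
    standardized-temperature link (identity link). ``alpha_psi``/``beta_psi``:
    intercept and slope of the log growth-rate vs standardized-phosphorus
    link. ``m_fish``/``m_nofish``: zooplankton mortality levels, per time
    step. ``e``: energy efficiency shared across lakes. ``sigma_x``/
    ``sigma_y``: observation-error standard deviations for the phytoplankton
    and zooplankton series. ``x1``/``y1``: per-lake initial latent states
    (None until drawn or estimated).
    """

    alpha_c: float
    beta_c: float
    alpha_psi: float
    beta_psi: float
    m_fish: float
    m_nofish: float
    e: float
    sigma_x: float
    sigma_y: float
    x1: Optional[np.ndarray] = None
    y1: Optional[np.ndarray] = None

    GLOBAL_NAMES = (
        "alpha_c",
        "beta_c",
        "alpha_psi",
        "beta_psi",
        "m_fish",
        "m_nofish",
        "e",
        "sigma_x",
        "sigma_y",
    )

    def globals_vector(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in self.GLOBAL_NAMES], dtype=float)

    @classmethod
    def from_globals_vector(
        cls,
        g: np.ndarray,
        x1: Optional[np.ndarray] = None,
        y1: Optional[np.ndarray] = None,
    ) -> "HyperParams":
        kw = {k: float(v) for k, v in zip(cls.GLOBAL_NAMES, g)}
        return cls(x1=x1, y1=y1, **kw)

    def is_valid(self) -> bool:
        """Support check used by the sampler (violations are rejected)."""
        ok = (
            0.0 <= self.m_fish <= 1.0
            and 0.0 <= self.m_nofish <= 1.0
            and 0.0 < self.e <= 1.0
            and self.sigma_x > 0.0
            and self.sigma_y > 0.0
            and np.isfinite(self.globals_vector()).all()
        )
        for arr in (self.x1, self.y1):
            if arr is not None:
                ok = ok and bool(np.all(np.asarray(arr) > 0))
        return ok

    def copy(self) -> "HyperParams":
        return replace(
            self,
            x1=None if self.x1 is None else np.array(self.x1, dtype=float),
            y1=None if self.y1 is None else np.array(self.y1, dtype=float),
        )

    def to_dict(self) -> dict:
        d = {k: float(getattr(self, k)) for k in self.GLOBAL_NAMES}
        if self.x1 is not None:
            d["x1"] = [float(v) for v in self.x1]
        if self.y1 is not None:
            d["y1"] = [float(v) for v in self.y1]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "HyperParams":
        kw = {k: float(d[k]) for k in cls.GLOBAL_NAMES}
        x1 = np.asarray(d["x1"], dtype=float) if "x1" in d else None
        y1 = np.asarray(d["y1"], dtype=float) if "y1" in d else None
        return cls(x1=x1, y1=y1, **kw)


@dataclass(frozen=True)
class ObservationSeries:
    """Observed chlorophyll-a and zooplankton biomass series for one lake."""

    lake_id: str
    chla: np.ndarray
    zoop: np.ndarray

    def __post_init__(self) -> None:
        chla = np.asarray(self.chla, dtype=float)
        zoop = np.asarray(self.zoop, dtype=float)
        object.__setattr__(self, "chla", chla)
        object.__setattr__(self, "zoop", zoop)
        if chla.shape != zoop.shape or chla.ndim != 1:
            raise ValueError("chla and zoop must be equal-length 1-d arrays")

    def __len__(self) -> int:
        return len(self.chla)
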