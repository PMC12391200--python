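"""Tissue porosity from buoyancy weighings.

Porosity (water volume fraction) follows from weighing a sample in air
(wet), submerged in PBS, and after lyophilization (dry):

    phi_w = (W_wet - W_dry) / (W_wet - W_PBS) * rho_PBS / rho_w

The density-ratio factor (1.005 for PBS) can push valid measurements
marginally above 1; such values are clipped to 1.0 with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .errors import DomainError, ImplausibleWeightsError

__all__ = ["BuoyancyWeights", "porosity", "solid_fraction", "read_weights_csv"]

DENSITY_RATIO_PBS = 1.005


@dataclass(frozen=True)
class BuoyancyWeights:
    """Buoyancy weighing triple in any consistent unit (mg, N, ...)."""

    W_wet: float
    W_PBS: float
    W_dry: float
    density_ratio: float = DENSITY_RATIO_PBS

    def __post_init__(self) -> None:
        if not (self.W_wet > self.W_dry >= 0):
            raise DomainError(
                f"need W_wet > W_dry >= 0, got wet={self.W_wet}, dry={self.W_dry}")
        if not (self.W_wet > self.W_PBS):
            raise DomainError(
                f"need W_wet > W_PBS, got wet={self.W_wet}, PBS={self.W_PBS}")
        if not (self.density_ratio > 0):
            raise DomainError("density_ratio must be positive")


def porosity(w: BuoyancyWeights) -> float:
    """Water volume fraction from a buoyancy weighing triple.

    Scale-invariant in the weights; strictly decreasing in W_dry.
    Raises :class:`ImplausibleWeightsError` outside [0, density_ratio].
    """
    denom = w.W_wet - w.W_PBS
    if denom <= 0:
        raise DomainError("W_wet - W_PBS must be positive")
    phi = (w.W_wet - w.W_dry) / denom * w.density_ratio
    if phi < 0 or phi > w.density_ratio:
        raise ImplausibleWeightsError(
            f"porosity {phi:.4f} outside [0, {w.density_ratio}]")
    if phi > 1.0:
        warnings.warn(
            f"porosity {phi:.4f} marginally above 1; clipping to 1.0",
            stacklevel=2)
        phi = 1.0
    return phi


def solid_fraction(phi_w: float) -> float:
    """Solid volume fraction ``1 - phi_w`` (the FE material parameter)."""
    if not (0.0 <= phi_w <= 1.0):
        raise DomainError(f"phi_w must lie in [0, 1], got {phi_w}")
    return 1.0 - phi_w


def read_weights_csv(path) -> pd.DataFrame:
    """Read a weights CSV and append a ``porosity`` column.

    Expected columns: ``specimen_id, W_wet_mg, W_PBS_mg, W_dry_mg``.
    """
    df = pd.read_csv(path)
    required = {"specimen_id", "W_wet_mg", "W_PBS_mg", "W_dry_mg"}
    missing = required - set(df.columns)
    if missing:
        raise DomainError(f"weights CSV missing columns: {sorted(missing)}")
    df = df.copy()
    df["porosity"] = [
        porosity(BuoyancyWeights(r.W_wet_mg, r.W_PBS_mg, r.W_dry_mg))
        for r in df.itertuples()
    ]
    return df
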