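"""Ideal Donnan osmotic swelling from fixed charge density.

A tissue carrying a fixed charge density ``c_F`` (per volume of
interstitial water) equilibrated against a monovalent salt bath of
concentration ``c_star`` develops an osmotic pressure

    pi = R T ( sqrt(c_F^2 + 4 c_star^2) - 2 c_star )

under ideal conditions (all activity and osmotic coefficients unity).
Deformation changes the water volume and hence concentrates or dilutes
the fixed charges:

    c_F(J) = c_F0 * phi_w0 / (J - 1 + phi_w0)

with ``J`` the volume ratio of the mixture and ``phi_w0`` the reference
porosity, so compression (J < 1) raises the osmotic pressure.

Concentrations are in mM == mol m^-3, pressures in Pa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = ["IonEnvironment", "donnan_pressure", "fcd_deformed",
           "GAS_CONSTANT"]

GAS_CONSTANT = 8.314  # J mol^-1 K^-1


@dataclass(frozen=True)
class IonEnvironment:
    """Bath conditions for Donnan equilibrium.

    ``c_star`` is the NaCl concentration of the bath in mM (each ion
    species at ``c_star``); ``T`` the absolute temperature in K.
    """

    c_star: float = 150.0
    T: float = 298.0
    R: float = GAS_CONSTANT

    def __post_init__(self) -> None:
        if self.c_star < 0:
            raise DomainError("c_star must be non-negative")
        if not (self.T > 0):
            raise DomainError("T must be positive")


def donnan_pressure(c_F, env: IonEnvironment = IonEnvironment()):
    """Ideal Donnan osmotic pressure, Pa, for fixed charge density in mM.

    Zero iff ``c_F`` is zero; strictly increasing in ``c_F`` and
    decreasing in the bath concentration.  In the dilute-bath limit
    (c_star -> 0) reduces to the ideal-osmometer law ``R T c_F``.
    """
    c_F_arr = np.asarray(c_F, dtype=float)
    if np.any(c_F_arr < 0):
        raise DomainError("c_F must be non-negative")
    pi = env.R * env.T * (
        np.sqrt(c_F_arr**2 + 4.0 * env.c_star**2) - 2.0 * env.c_star
    )
    return float(pi) if np.isscalar(c_F) or np.ndim(c_F) == 0 else pi


def fcd_deformed(c_F0, phi_w0: float, J):
    """Fixed charge density after a volume change ``J`` (mM).

    Scales inversely with the current water volume per reference
    volume, ``J - 1 + phi_w0``; raises on pore collapse
    (``J <= 1 - phi_w0``).
    """
    if not (0.0 < phi_w0 < 1.0):
        raise DomainError("phi_w0 must lie in (0, 1)")
    c_F0_arr = np.asarray(c_F0, dtype=float)
    if np.any(c_F0_arr < 0):
        raise DomainError("c_F0 must be non-negative")
    J_arr = np.asarray(J, dtype=float)
    if np.any(J_arr <= 1.0 - phi_w0):
        raise DomainError(
            f"J must exceed 1 - phi_w0 = {1.0 - phi_w0:.4f} (pore collapse)")
    c = c_F0_arr * phi_w0 / (J_arr - 1.0 + phi_w0)
    scalar = np.ndim(c_F0) == 0 and np.ndim(J) == 0
    return float(c) if scalar else c


def osmotic_pressure_deformed(c_F0: float, phi_w0: float, J,
                              env: IonEnvironment = IonEnvironment()):
    """Convenience composition pi(c_F(J)); decreasing in J."""
    return donnan_pressure(fcd_deformed(c_F0, phi_w0, J), env)


def osmotic_modulus(c_F0: float, phi_w0: float, J,
                    env: IonEnvironment = IonEnvironment()):
    """d(pi)/dJ, Pa (negative): tangent used by the FE swelling solver."""
    c = fcd_deformed(c_F0, phi_w0, J)
    c_arr = np.asarray(c, dtype=float)
    J_arr = np.asarray(J, dtype=float)
    dc_dJ = -c_arr / (J_arr - 1.0 + phi_w0)
    dpi_dc = env.R * env.T * c_arr / np.sqrt(c_arr**2 + 4.0 * env.c_star**2)
    out = dpi_dc * dc_dJ
    scalar = np.ndim(J) == 0
    return float(out) if scalar else out
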