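"""Closed-form linear biphasic theory for 1-D confined compression.

A cylindrical tissue sample of thickness ``h`` is laterally confined and
loaded axially; interstitial fluid drains through a porous platen at one
face while the loading probe at the opposite face is impermeable.  The
axial strain field then obeys a consolidation (diffusion) equation with
diffusivity ``c = H_A * k`` where ``H_A`` is the aggregate modulus and
``k`` the hydraulic permeability.  This module provides the classical
series solutions for step/ramped creep and ramp-and-hold stress
relaxation with a single drained face, plus the small algebraic
conversions used throughout the pipeline.

All quantities are SI internally (m, s, Pa, m^4/(N s)); conversions to
reporting units happen only at I/O boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, SeriesConvergenceError

__all__ = [
    "BiphasicMaterial",
    "SpecimenGeometry",
    "LoadProtocol",
    "SeriesControl",
    "young_from_aggregate",
    "aggregate_from_young",
    "creep_strain_step",
    "creep_strain_ramp",
    "relaxation_stress",
    "gel_time",
    "permeability_to_report_units",
    "permeability_from_report_units",
]


@dataclass(frozen=True)
class BiphasicMaterial:
    """Isotropic linear biphasic material.

    Parameters
    ----------
    H_A : float
        Aggregate (confined-compression equilibrium) modulus, Pa.
    k : float
        Hydraulic permeability, m^4 N^-1 s^-1.
    nu : float
        Poisson ratio of the drained solid matrix, in [0, 0.5).
    phi_w0 : float
        Reference porosity (water volume fraction), in (0, 1).
    c_F0 : float
        Reference fixed charge density, mol m^-3 of interstitial water
        (numerically equal to mEq/L).  Zero disables osmotic swelling.
    """

    H_A: float
    k: float
    nu: float = 0.2
    phi_w0: float = 0.8
    c_F0: float = 0.0

    def __post_init__(self) -> None:
        if not (self.H_A > 0):
            raise DomainError(f"H_A must be positive, got {self.H_A}")
        if not (self.k > 0):
            raise DomainError(f"k must be positive, got {self.k}")
        if not (0.0 <= self.nu < 0.5):
            raise DomainError(f"nu must lie in [0, 0.5), got {self.nu}")
        if not (0.0 < self.phi_w0 < 1.0):
            raise DomainError(f"phi_w0 must lie in (0, 1), got {self.phi_w0}")
        if self.c_F0 < 0:
            raise DomainError(f"c_F0 must be non-negative, got {self.c_F0}")

    @property
    def diffusivity(self) -> float:
        """Consolidation diffusivity ``H_A * k`` in m^2/s."""
        return self.H_A * self.k

    @property
    def E(self) -> float:
        """Young's modulus of the drained solid matrix, Pa."""
        return young_from_aggregate(self.H_A, self.nu)

    @property
    def shear_modulus(self) -> float:
        """Shear modulus mu, Pa."""
        return self.E / (2.0 * (1.0 + self.nu))

    @property
    def lame_lambda(self) -> float:
        """First Lame parameter of the drained matrix, Pa."""
        return self.H_A - 2.0 * self.shear_modulus


@dataclass(frozen=True)
class SpecimenGeometry:
    """Cylindrical test-specimen geometry (SI units)."""

    thickness: float
    diameter: float

    def __post_init__(self) -> None:
        if not (self.thickness > 0):
            raise DomainError(f"thickness must be positive, got {self.thickness}")
        if not (self.diameter > 0):
            raise DomainError(f"diameter must be positive, got {self.diameter}")

    @property
    def area(self) -> float:
        """Cross-sectional area pi d^2 / 4, m^2."""
        return math.pi * self.diameter**2 / 4.0


@dataclass(frozen=True)
class LoadProtocol:
    """Relaxation-then-creep confined compression test protocol.

    The sample is compressed to ``offset_strain`` and held for
    ``relax_duration``; the equilibrium load defines the swelling
    pressure.  A further load equal to ``creep_load_fraction`` of the
    equilibrium load is then applied over ``ramp_duration`` and held for
    ``creep_duration``.
    """

    offset_strain: float = 0.10
    relax_duration: float = 3600.0
    creep_load_fraction: float = 0.20
    ramp_duration: float = 300.0
    creep_duration: float = 7200.0
    pbs_replenish_interval: float = 900.0  # metadata only
    offset_ramp_duration: float = 60.0  # ramp used to reach the offset strain

    def __post_init__(self) -> None:
        for name in ("relax_duration", "ramp_duration", "creep_duration",
                     "pbs_replenish_interval", "offset_ramp_duration"):
            if not (getattr(self, name) > 0):
                raise DomainError(f"{name} must be positive")
        if not (0.0 < self.offset_strain < 1.0):
            raise DomainError("offset_strain must lie in (0, 1)")
        if not (0.0 < self.creep_load_fraction < 1.0):
            raise DomainError("creep_load_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class SeriesControl:
    """Truncation control for the eigenfunction series."""

    tol: float = 1e-12
    n_max: int = 200

    def __post_init__(self) -> None:
        if not (self.tol > 0):
            raise DomainError("tol must be positive")
        if self.n_max < 1:
            raise DomainError("n_max must be at least 1")


_DEFAULT_CTL = SeriesControl()


def young_from_aggregate(H_A: float, nu: float) -> float:
    """Young's modulus from the aggregate modulus.

    ``E = H_A (1 + nu)(1 - 2 nu) / (1 - nu)``; equals ``H_A`` at nu = 0
    and is strictly smaller for nu in (0, 0.5).
    """
    if not (H_A > 0):
        raise DomainError(f"H_A must be positive, got {H_A}")
    if not (0.0 <= nu < 0.5):
        raise DomainError(f"nu must lie in [0, 0.5), got {nu}")
    return H_A * (1.0 + nu) * (1.0 - 2.0 * nu) / (1.0 - nu)


def aggregate_from_young(E: float, nu: float) -> float:
    """Inverse of :func:`young_from_aggregate`."""
    if not (E > 0):
        raise DomainError(f"E must be positive, got {E}")
    if not (0.0 <= nu < 0.5):
        raise DomainError(f"nu must lie in [0, 0.5), got {nu}")
    return E * (1.0 - nu) / ((1.0 + nu) * (1.0 - 2.0 * nu))


def gel_time(mat: BiphasicMaterial, h: float) -> float:
    """Characteristic consolidation time ``tau = h^2 / (H_A k)`` in s."""
    if not (h > 0):
        raise DomainError(f"h must be positive, got {h}")
    return h * h / mat.diffusivity


def permeability_to_report_units(k_SI: float) -> float:
    """Convert permeability from m^4/(N s) to units of 1e-4 mm^4/(N s).

    1 m^4 = 1e12 mm^4, so the reported number is ``k_SI * 1e12 / 1e-4``
    = ``k_SI * 1e16``.
    """
    if k_SI < 0:
        raise DomainError("permeability cannot be negative")
    return k_SI * 1.0e16


def permeability_from_report_units(k_report: float) -> float:
    """Inverse of :func:`permeability_to_report_units`."""
    if k_report < 0:
        raise DomainError("permeability cannot be negative")
    return k_report * 1.0e-16


_S_SWITCH = 0.02  # below this the theta-dual expansions are exact to machine precision


def _F_half(s: np.ndarray, ctl: SeriesControl) -> np.ndarray:
    """F(s) = sum_{n>=0} exp(-(n+1/2)^2 s) / (n+1/2)^2, s >= 0.

    F(0) = pi^2/2; Poisson-resummed small-s form ``pi^2/2 - sqrt(pi s)``
    with error O(exp(-pi^2/s)).
    """
    out = np.empty_like(s)
    small = s < _S_SWITCH
    out[small] = math.pi**2 / 2.0 - np.sqrt(math.pi * s[small])
    if np.any(~small):
        sl = s[~small]
        n_terms = int(math.ceil(math.sqrt(-math.log(ctl.tol) / float(sl.min())))) + 2
        if n_terms > ctl.n_max:
            raise SeriesConvergenceError(
                f"creep series needs {n_terms} terms, n_max={ctl.n_max}; "
                "increase n_max")
        m = np.arange(n_terms) + 0.5
        out[~small] = np.einsum(
            "nt,n->t", np.exp(-np.outer(m * m, sl)), m**-2.0)
    return out


def creep_strain_step(
    mat: BiphasicMaterial,
    h: float,
    sigma0: float,
    t,
    ctl: SeriesControl = _DEFAULT_CTL,
):
    """Creep strain under a step load ``sigma0`` applied at t = 0.

    eps(t) = (sigma0/H_A) [1 - 2 sum_n exp(-M_n^2 t c / h^2) / M_n^2],
    M_n = (n + 1/2) pi, with drainage through one face (drainage length
    equal to the full thickness ``h``).

    Parameters
    ----------
    t : float or array_like
        Time(s) since load application, s.  t = 0 returns exactly 0.

    Returns
    -------
    float or ndarray
        Compressive engineering strain (dimensionless), nondecreasing in
        t and bounded by ``sigma0 / H_A``.
    """
    if not (h > 0):
        raise DomainError("h must be positive")
    if sigma0 < 0:
        raise DomainError("sigma0 must be non-negative")
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    if np.any(t_arr < 0):
        raise DomainError("t must be non-negative")

    eps_inf = sigma0 / mat.H_A
    # sum_n exp(-M_n^2 T)/M_n^2 = F(pi^2 T)/pi^2 with M_n = (n+1/2) pi
    s = math.pi**2 * t_arr * mat.diffusivity / (h * h)
    out = eps_inf * (1.0 - (2.0 / math.pi**2) * _F_half(s, ctl))
    out = np.maximum(out, 0.0)
    return float(out[0]) if scalar else out


def _G_half(s: np.ndarray, ctl: SeriesControl) -> np.ndarray:
    """G(s) = sum_{n>=0} exp(-(n+1/2)^2 s) / (n+1/2)^4, s >= 0.

    G(0) = pi^4/6.  For small s the Poisson-resummed (theta-dual)
    expansion ``pi^4/6 - (pi^2/2) s + (2 sqrt(pi)/3) s^{3/2}`` holds with
    error O(exp(-pi^2/s)), which underflows for s < 0.02; elsewhere the
    direct sum converges in a handful of terms.
    """
    out = np.empty_like(s)
    small = s < _S_SWITCH
    ss = s[small]
    out[small] = (
        math.pi**4 / 6.0 - 0.5 * math.pi**2 * ss
        + (2.0 * math.sqrt(math.pi) / 3.0) * ss**1.5
    )
    if np.any(~small):
        sl = s[~small]
        n_terms = int(math.ceil(math.sqrt(-math.log(ctl.tol) / float(sl.min())))) + 2
        if n_terms > ctl.n_max:
            raise SeriesConvergenceError(
                f"series needs {n_terms} terms, n_max={ctl.n_max}"
            )
        m = np.arange(n_terms) + 0.5
        out[~small] = np.einsum(
            "nt,n->t", np.exp(-np.outer(m * m, sl)), m**-4.0
        )
    return out


def _R_int(s: np.ndarray, ctl: SeriesControl) -> np.ndarray:
    """R(s) = sum_{n>=1} exp(-n^2 s) / n^2, s >= 0.

    R(0) = pi^2/6; small-s dual expansion pi^2/6 - sqrt(pi s) + s/2.
    """
    out = np.empty_like(s)
    small = s < _S_SWITCH
    ss = s[small]
    out[small] = math.pi**2 / 6.0 - np.sqrt(math.pi * ss) + 0.5 * ss
    if np.any(~small):
        sl = s[~small]
        n_terms = int(math.ceil(math.sqrt(-math.log(ctl.tol) / float(sl.min())))) + 2
        if n_terms > ctl.n_max:
            raise SeriesConvergenceError(
                f"series needs {n_terms} terms, n_max={ctl.n_max}"
            )
        m = np.arange(1, n_terms + 1, dtype=float)
        out[~small] = np.einsum(
            "nt,n->t", np.exp(-np.outer(m * m, sl)), m**-2.0
        )
    return out


def creep_strain_ramp(
    mat: BiphasicMaterial,
    h: float,
    sigma0: float,
    t_ramp: float,
    t,
    ctl: SeriesControl = _DEFAULT_CTL,
):
    """Creep strain for a load ramped linearly to ``sigma0`` over ``t_ramp``.

    Duhamel superposition of the step solution over a linear load ramp
    gives, with lam_n = M_n^2 c / h^2 and t0 = t_ramp:

    eps(t) = (sigma0/H_A) [ min(t/t0, 1)
             - (2/t0) sum_n (e^{-lam_n (t-t0)_+} - e^{-lam_n t}) / (M_n^2 lam_n) ]

    The mode sum is evaluated through ``Q(x) = (h^2/(c pi^4)) G(pi^2 c x / h^2)``
    so that the result is accurate to machine precision at all times,
    including t -> 0 and t_ramp -> 0 (step limit).
    """
    if not (t_ramp > 0):
        raise DomainError("t_ramp must be positive")
    if not (h > 0):
        raise DomainError("h must be positive")
    if sigma0 < 0:
        raise DomainError("sigma0 must be non-negative")
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    if np.any(t_arr < 0):
        raise DomainError("t must be non-negative")

    c = mat.diffusivity
    h2 = h * h
    eps_inf = sigma0 / mat.H_A
    base = np.where(t_arr <= t_ramp, t_arr / t_ramp, 1.0)

    scale = math.pi**2 * c / h2
    q_hold = _G_half(scale * np.maximum(t_arr - t_ramp, 0.0), ctl)
    q_full = _G_half(scale * t_arr, ctl)
    # S = Q((t-t0)_+) - Q(t) with Q(x) = (h^2/(c pi^4)) G(pi^2 c x/h^2)
    S = (h2 / (c * math.pi**4)) * (q_hold - q_full)
    out = eps_inf * (base - (2.0 / t_ramp) * S)
    # for t >> t_ramp the finite difference of Q cancels catastrophically;
    # the midpoint rule (step solution at t - t_ramp/2) is then exact to
    # O(t_ramp^2) and numerically stable
    late = t_arr > 1e3 * t_ramp
    if np.any(late):
        sF = scale * (t_arr[late] - 0.5 * t_ramp)
        out[late] = eps_inf * (1.0 - (2.0 / math.pi**2) * _F_half(sF, ctl))
    out = np.maximum(out, 0.0)
    return float(out[0]) if scalar else out


def relaxation_stress(
    mat: BiphasicMaterial,
    h: float,
    eps0: float,
    t_ramp: float,
    t,
    ctl: SeriesControl = _DEFAULT_CTL,
):
    """Total stress during ramp-and-hold confined-compression relaxation.

    The surface is displaced at constant rate to a strain ``eps0`` over
    ``t_ramp`` and then held.  With c = H_A k and one drained face the
    classical solution for the ramp phase (t <= t0) is

    sigma = H_A (eps0/t0) [ t + (h^2/c)(1/3 - (2/pi^2) sum_n e^{-n^2 pi^2 c t/h^2}/n^2) ]

    and for the hold phase (t > t0)

    sigma = H_A eps0 + H_A (eps0/t0)(h^2/c)(2/pi^2)
            sum_n (1/n^2)(e^{-n^2 pi^2 c (t-t0)/h^2} - e^{-n^2 pi^2 c t/h^2}).

    Both phases collapse to ``sigma = H_A rate [ t_clip +
    (h^2/c)(2/pi^2)(R((t-t0)_+) - R(t)) ]`` with R(0) = pi^2/6.  Stress
    peaks at t = t0 and relaxes monotonically to ``H_A eps0``.
    """
    if not (0.0 < eps0 < 1.0):
        raise DomainError("eps0 must lie in (0, 1)")
    if not (t_ramp > 0):
        raise DomainError("t_ramp must be positive")
    if not (h > 0):
        raise DomainError("h must be positive")
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    if np.any(t_arr < 0):
        raise DomainError("t must be non-negative")

    c = mat.diffusivity
    h2 = h * h
    rate = eps0 / t_ramp
    t_clip = np.minimum(t_arr, t_ramp)

    scale = math.pi**2 * c / h2
    r_hold = _R_int(scale * np.maximum(t_arr - t_ramp, 0.0), ctl)
    r_full = _R_int(scale * t_arr, ctl)
    sigma = mat.H_A * rate * (
        t_clip + (h2 / c) * (2.0 / math.pi**2) * (r_hold - r_full)
    )
    return float(sigma[0]) if scalar else sigma
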