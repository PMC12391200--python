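"""Classical series solution for unconfined compression of a biphasic
cylinder between smooth impermeable platens.

A cylinder of radius ``a`` is compressed axially between frictionless
impermeable platens while draining radially; the dilatation obeys a
radial diffusion equation with diffusivity ``c = H_A k``.  The transient
characteristic equation is

    J1(alpha) = (1 - nu) / (1 - 2 nu) * alpha * J0(alpha)

and the axial reaction per unit strain relaxes from the instantaneous
(undrained, isochoric) modulus ``3 mu`` to the drained Young's modulus
``E``.  The mode amplitudes are evaluated here by residues of the exact
Laplace-domain solution, so no closed-form coefficient tables are
needed; the t -> 0 and t -> infinity limits provide built-in checks.

Used as the independent oracle for validating the 3-D finite element
solver's reaction force.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq
from scipy.special import j0, j1

from ..biphasic_core import BiphasicMaterial
from ..errors import DomainError

__all__ = ["characteristic_roots", "unconfined_reaction_force",
           "unconfined_step_modulus"]


def characteristic_roots(nu: float, n_roots: int = 60) -> np.ndarray:
    """Positive roots of J1(a) - (1-nu)/(1-2nu) a J0(a) = 0."""
    if not (0.0 <= nu < 0.5):
        raise DomainError("nu must lie in [0, 0.5)")
    beta = (1.0 - nu) / (1.0 - 2.0 * nu)

    def f(x):
        return j1(x) - beta * x * j0(x)

    roots = []
    x = 1e-6
    dx = 0.02
    fx = f(x)
    while len(roots) < n_roots and x < (n_roots + 5) * math.pi:
        x2 = x + dx
        fx2 = f(x2)
        if fx == 0.0:
            roots.append(x)
        elif fx * fx2 < 0:
            roots.append(brentq(f, x, x2, xtol=1e-14))
        x, fx = x2, fx2
    return np.asarray(roots[:n_roots])


def _mode_amplitudes(mat: BiphasicMaterial, n_roots: int):
    """Residue amplitudes C_n of the step response per unit strain:
    sigma_axial(t) = -(E + sum C_n exp(-alpha_n^2 c t / a^2)) eps0."""
    lam, mu = mat.lame_lambda, mat.shear_modulus
    HA = mat.H_A
    alpha = characteristic_roots(mat.nu, n_roots)
    Nn = HA * j0(alpha) - 4.0 * mu * j1(alpha) / alpha
    # x D'(x) at x = i alpha (real-valued)
    xDp = -alpha * ((lam + 2.0 * mu) * j1(alpha)
                    + 2.0 * mu * j0(alpha) / alpha
                    - 4.0 * mu * j1(alpha) / alpha**2)
    Cn = 2.0 * mu * Nn / xDp
    return alpha, Cn


def unconfined_step_modulus(mat: BiphasicMaterial, t_dimless,
                            n_roots: int = 60):
    """Apparent axial modulus sigma/eps0 at dimensionless time
    ``T = c t / a^2`` for a step strain (compression positive).

    Equals ``3 mu`` at T = 0 (up to series truncation) and the drained
    Young's modulus as T -> infinity.
    """
    alpha, Cn = _mode_amplitudes(mat, n_roots)
    T = np.atleast_1d(np.asarray(t_dimless, dtype=float))
    out = mat.E + np.einsum("n,nt->t", Cn, np.exp(-np.outer(alpha**2, T)))
    return out if np.ndim(t_dimless) else float(out[0])


def unconfined_reaction_force(
    mat: BiphasicMaterial,
    radius: float,
    eps0: float,
    t_ramp: float,
    t,
    n_roots: int = 60,
) -> np.ndarray:
    """Axial reaction force (N, compression positive) on a full cylinder
    under a linear strain ramp to ``eps0`` over ``t_ramp`` then hold.

    Duhamel integration of the step response:

    F(t) = pi a^2 (eps0/t0) [ E min(t, t0)
           + sum_n (C_n/lam_n)(e^{-lam_n (t-t0)_+} - e^{-lam_n t}) ]

    with lam_n = alpha_n^2 c / a^2.
    """
    if radius <= 0 or eps0 <= 0 or t_ramp <= 0:
        raise DomainError("radius, eps0 and t_ramp must be positive")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise DomainError("t must be non-negative")
    alpha, Cn = _mode_amplitudes(mat, n_roots)
    c = mat.diffusivity
    lam = alpha**2 * c / radius**2
    hold = np.maximum(t_arr - t_ramp, 0.0)
    series = np.einsum(
        "n,nt->t", Cn / lam,
        np.exp(-np.outer(lam, hold)) - np.exp(-np.outer(lam, t_arr)))
    F = math.pi * radius**2 * (eps0 / t_ramp) * (
        mat.E * np.minimum(t_arr, t_ramp) + series)
    return F if np.ndim(t) else float(F[0])
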