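"""Finite-difference solver for 1-D biphasic confined compression.

Serves as the brute-force oracle for the closed-form series solutions in
:mod:`discbiphasic.biphasic_core` and for curve fitting under arbitrary
piecewise-linear load or displacement histories.

The axial (compressive) strain field ``eps(z, t)`` obeys the
consolidation equation ``eps_t = c eps_zz`` with ``c = H_A k``.  The
face z = 0 is drained (pore pressure zero, so ``eps(0, t) =
sigma(t)/H_A`` with sigma the total applied stress) and the face z = h
is impermeable (``eps_z(h, t) = 0``).  Under stress control sigma(t) is
prescribed; under displacement control the trapezoidal integral of eps
is constrained to the prescribed surface displacement and sigma(t) is an
additional unknown (the reaction stress).

The theta-weighted scheme is unconditionally stable for theta >= 1/2.
A finite-volume boundary-flux recovery makes the discrete fluid balance
exact: cumulative outflow through the drained face equals the change in
layer dilatation to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .biphasic_core import BiphasicMaterial
from .errors import DomainError, SolverError

__all__ = ["Grid1D", "LoadHistory", "ConsolidationResult",
           "solve_consolidation", "convergence_study"]


@dataclass(frozen=True)
class Grid1D:
    """Space-time discretization for the 1-D solver.

    ``init_refine`` geometrically bisects the first step after t = 0 and
    after every history breakpoint that many times, which resolves the
    sqrt(t) transients launched at load kinks without shrinking the
    global step.
    """

    n_z: int = 201
    dt: float = 1.0
    t_end: float = 7200.0
    theta: float = 1.0
    init_refine: int = 0

    def __post_init__(self) -> None:
        if self.n_z < 11:
            raise DomainError("n_z must be at least 11")
        if not (self.dt > 0):
            raise DomainError("dt must be positive")
        if not (self.t_end > 0):
            raise DomainError("t_end must be positive")
        if not (0.5 <= self.theta <= 1.0):
            raise DomainError("theta must lie in [0.5, 1]")
        if not (0 <= self.init_refine <= 60):
            raise DomainError("init_refine must lie in [0, 60]")


@dataclass(frozen=True)
class LoadHistory:
    """Piecewise-linear load (Pa) or displacement (m) history.

    ``kind`` is ``"stress_control"`` or ``"displacement_control"``;
    breakpoint times must be strictly increasing starting at 0.
    """

    kind: str
    breakpoints: tuple

    def __post_init__(self) -> None:
        if self.kind not in ("stress_control", "displacement_control"):
            raise DomainError(f"unknown history kind {self.kind!r}")
        times = np.array([b[0] for b in self.breakpoints], dtype=float)
        values = np.array([b[1] for b in self.breakpoints], dtype=float)
        if len(times) < 1 or times[0] != 0.0:
            raise DomainError("breakpoints must start at t = 0")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise DomainError("breakpoint times must be strictly increasing")
        if not np.all(np.isfinite(values)):
            raise DomainError("breakpoint values must be finite")
        object.__setattr__(self, "breakpoints",
                           tuple((float(t), float(v)) for t, v in self.breakpoints))

    def value(self, t) -> np.ndarray:
        times = np.array([b[0] for b in self.breakpoints])
        values = np.array([b[1] for b in self.breakpoints])
        return np.interp(t, times, values)

    @property
    def t_max(self) -> float:
        return self.breakpoints[-1][0]

    @classmethod
    def step(cls, kind: str, value: float, t_end: float) -> "LoadHistory":
        """A true step at t = 0 held until ``t_end``."""
        return cls(kind, ((0.0, value), (t_end, value)))

    @classmethod
    def ramp_hold(cls, kind: str, value: float, t_ramp: float,
                  t_end: float) -> "LoadHistory":
        return cls(kind, ((0.0, 0.0), (t_ramp, value), (t_end, value)))


@dataclass
class ConsolidationResult:
    """Time series output of :func:`solve_consolidation` (SI units)."""

    z: np.ndarray          # node coordinates, m
    times: np.ndarray      # output times, s
    displacement: np.ndarray   # surface displacement (compression +), m
    sigma: np.ndarray      # total stress (applied or reaction), Pa
    pressure: np.ndarray   # pore pressure, shape (n_t, n_z), Pa
    strain: np.ndarray     # compressive strain field, shape (n_t, n_z)
    cumulative_outflow: np.ndarray  # fluid volume out per unit area, m

    @property
    def dilatation(self) -> np.ndarray:
        """Layer-integrated strain (trapezoid), m; equals displacement."""
        return np.trapezoid(self.strain, self.z, axis=1)


def _time_grid(grid: Grid1D, history: LoadHistory) -> np.ndarray:
    """Uniform step times plus geometric refinement after each history
    breakpoint (and t = 0) when ``grid.init_refine`` > 0."""
    n_steps = max(1, int(round(grid.t_end / grid.dt)))
    dt = grid.t_end / n_steps
    times = np.linspace(0.0, grid.t_end, n_steps + 1)
    if grid.init_refine > 0:
        kinks = [0.0] + [t for t, _ in history.breakpoints
                         if 0.0 < t < grid.t_end]
        extra = []
        for tb in kinks:
            extra.extend(tb + dt * 0.5**j
                         for j in range(1, grid.init_refine + 1))
            if tb > 0:  # snap the kink itself onto the grid
                extra.append(tb)
        times = np.unique(np.concatenate([times, np.array(extra)]))
        times = times[(times >= 0.0) & (times <= grid.t_end)]
    return times


def _laplacian(n_z: int, dz: float) -> sp.csr_matrix:
    """Second-difference operator on eps_1..eps_{n-1} (row i omits the
    Dirichlet node 0 coupling, handled via RHS); mirror at the top."""
    m = n_z - 1
    main = -2.0 * np.ones(m)
    lower = np.ones(m - 1)
    upper = np.ones(m - 1)
    A = sp.diags([lower, main, upper], [-1, 0, 1], format="lil")
    # impermeable top: eps_zz ~ 2 (eps_{N-2} - eps_{N-1}) / dz^2
    A[m - 1, m - 2] = 2.0
    A[m - 1, m - 1] = -2.0
    return (A / dz**2).tocsr()


def solve_consolidation(
    mat: BiphasicMaterial,
    h: float,
    history: LoadHistory,
    grid: Grid1D,
) -> ConsolidationResult:
    """Integrate 1-D biphasic consolidation under the given history.

    Returns surface displacement, total (applied or reaction) stress,
    the pore-pressure profile and the exact discrete cumulative outflow.
    """
    if not (h > 0):
        raise DomainError("h must be positive")
    if history.t_max < grid.t_end:
        raise DomainError("history does not cover [0, t_end]")

    n_z = grid.n_z
    dz = h / (n_z - 1)
    c = mat.diffusivity
    theta = grid.theta
    times = _time_grid(grid, history)
    n_steps = len(times) - 1

    L = _laplacian(n_z, dz)
    m = n_z - 1
    I = sp.identity(m, format="csr")
    w = np.full(n_z, dz)
    w[0] = w[-1] = dz / 2.0  # trapezoid weights

    eps = np.zeros((n_steps + 1, n_z))
    sigma = np.zeros(n_steps + 1)
    outflow = np.zeros(n_steps + 1)
    coup = c / dz**2

    stress_control = history.kind == "stress_control"
    lu_cache: dict = {}
    if stress_control:
        sig_t = history.value(times)
        sigma[:] = sig_t
        # undrained instantaneous response to a nonzero initial stress:
        # interior strain 0, drained-face strain sigma/H_A
        eps[0, 0] = sig_t[0] / mat.H_A
        for nstep in range(n_steps):
            dt = times[nstep + 1] - times[nstep]
            key = round(dt, 12)
            if key not in lu_cache:
                A = (I - theta * dt * c * L).tocsc()
                lu_cache[key] = (splu(A), I + (1.0 - theta) * dt * c * L)
            lu, B = lu_cache[key]
            e0_old = sig_t[nstep] / mat.H_A
            e0_new = sig_t[nstep + 1] / mat.H_A
            rhs = B @ eps[nstep, 1:]
            rhs[0] += dt * coup * (theta * e0_new + (1.0 - theta) * e0_old)
            new = lu.solve(rhs)
            if not np.all(np.isfinite(new)):
                raise SolverError(f"non-finite solution at step {nstep + 1}")
            eps[nstep + 1, 1:] = new
            eps[nstep + 1, 0] = e0_new
    else:
        u_t = history.value(times)
        if abs(u_t[0]) > 0:
            raise DomainError(
                "displacement-control histories must start at 0; model an "
                "initial jump as a fast ramp instead")
        # unknowns x = [eps_1 .. eps_{N-1}, s] with s = sigma / H_A = eps_0
        # theta-scheme rows + trapezoid constraint row
        for nstep in range(n_steps):
            dt = times[nstep + 1] - times[nstep]
            key = round(dt, 12)
            if key not in lu_cache:
                A11 = (I - theta * dt * c * L).tolil()
                col = np.zeros((m, 1))
                col[0, 0] = -theta * dt * coup
                A = sp.bmat(
                    [[A11, sp.lil_matrix(col)],
                     [sp.lil_matrix(w[1:][None, :]), sp.lil_matrix([[w[0]]])]],
                    format="csc",
                )
                lu_cache[key] = (splu(A), I + (1.0 - theta) * dt * c * L)
            lu, B = lu_cache[key]
            s_old = eps[nstep, 0]
            rhs = np.empty(m + 1)
            rhs[:m] = B @ eps[nstep, 1:]
            rhs[0] += dt * coup * (1.0 - theta) * s_old
            rhs[m] = u_t[nstep + 1]
            x = lu.solve(rhs)
            if not np.all(np.isfinite(x)):
                raise SolverError(f"non-finite solution at step {nstep + 1}")
            eps[nstep + 1, 1:] = x[:m]
            eps[nstep + 1, 0] = x[m]
            sigma[nstep + 1] = mat.H_A * x[m]

    # exact discrete boundary-flux recovery (finite-volume balance of the
    # half cell at the drained node):
    #   q_out = c (eps_0 - eps_1)/dz + (dz/2) d(eps_0)/dt
    q = c * (eps[:, 0] - eps[:, 1]) / dz
    dts = np.diff(times)
    d_eps0 = np.diff(eps[:, 0]) / dts
    for nstep in range(n_steps):
        q_th = theta * q[nstep + 1] + (1.0 - theta) * q[nstep]
        outflow[nstep + 1] = outflow[nstep] + dts[nstep] * (
            q_th + (dz / 2.0) * d_eps0[nstep]
        )

    displacement = eps @ w
    pressure = sigma[:, None] - mat.H_A * eps
    return ConsolidationResult(
        z=np.linspace(0.0, h, n_z),
        times=times,
        displacement=displacement,
        sigma=sigma,
        pressure=pressure,
        strain=eps,
        cumulative_outflow=outflow,
    )


def convergence_study(
    mat: BiphasicMaterial,
    h: float,
    history: LoadHistory,
    grids: Sequence[Grid1D],
) -> float:
    """Observed order of accuracy from a sequence of nested grids.

    The last grid is the reference; errors of the coarser grids in the
    displacement trace (sup norm at the coarsest common output times)
    are fit against the varying resolution (dz if n_z varies, else dt).
    """
    if len(grids) < 3:
        raise DomainError("need at least 3 grids")
    results = [solve_consolidation(mat, h, history, g) for g in grids]
    ref = results[-1]
    t_common = results[0].times
    u_ref = np.interp(t_common, ref.times, ref.displacement)
    errs, res = [], []
    for g, r in zip(grids[:-1], results[:-1]):
        u = np.interp(t_common, r.times, r.displacement)
        errs.append(np.max(np.abs(u - u_ref)))
        if grids[0].n_z != grids[1].n_z:
            res.append(h / (g.n_z - 1))
        else:
            res.append(g.dt)
    errs = np.array(errs)
    res = np.array(res)
    if np.any(errs <= 0):
        raise SolverError("degenerate error sequence in convergence study")
    p = np.polyfit(np.log(res), np.log(errs), 1)
    return float(p[0])
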