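"""Quasi-static u-p biphasic finite element solver.

Equal-order trilinear displacement/pressure interpolation, backward
Euler in time.  Per time step the symmetric indefinite block system

    [ K + K_osm   -G ] [u]   [ f + f_osm       ]
    [ -G^T     -dt H ] [p] = [ -G^T u_old      ]

is solved, where K is the drained elastic stiffness, G the
divergence/pressure coupling, H the Darcy permeability matrix and the
osmotic terms implement Donnan swelling as a volume-ratio-dependent
isotropic stress ``-pi(J) I`` (small-strain J = 1 + div u), linearized
once per step (modified Newton).

Small first time steps during the load ramp suppress the early-time
pressure oscillation to which equal-order interpolation is prone; an
oscillation metric (fraction of negative nodal pressure magnitude) is
reported and a warning advises a smaller first step when it is large.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from ..biphasic_core import BiphasicMaterial  # noqa: F401 (documented material type)
from ..donnan_swelling import (IonEnvironment, osmotic_modulus,
                               osmotic_pressure_deformed)
from ..errors import DomainError, SolverError
from .hexa import SHAPES_GP, batched_geometry
from .mesh import DiscMesh, REGION_CODES

__all__ = ["CompressionProtocol", "FEResult", "solve_biphasic"]


@dataclass(frozen=True)
class CompressionProtocol:
    """Ramped axial compression protocol for the disc model."""

    axial_strain: float = 0.10
    ramp_duration: float = 10_000.0
    hold_until: float = 400_000.0
    n_ramp_steps: int = 16
    n_hold_steps: int = 40
    first_step_fraction: float = 1.0 / 200.0

    def times(self) -> np.ndarray:
        """Step times: a small first step that doubles every other step
        (so factorizations are reused), hitting the ramp end and the
        final time exactly."""
        if self.axial_strain < 0 or self.ramp_duration <= 0:
            raise DomainError("invalid protocol")
        t0 = self.first_step_fraction * self.ramp_duration
        times = [0.0]
        dt = t0

        def advance(until: float, dt: float, cap: float) -> float:
            k = 0
            while times[-1] < until - 1e-9 * until:
                step = min(dt, until - times[-1])
                times.append(times[-1] + step)
                k += 1
                if k % 2 == 0 and dt < cap:
                    dt *= 2.0
            return dt

        dt = advance(self.ramp_duration, dt,
                     cap=self.ramp_duration / 4.0)
        if self.hold_until > self.ramp_duration:
            advance(self.hold_until, dt,
                    cap=(self.hold_until - self.ramp_duration)
                    / max(self.n_hold_steps / 2.0, 2.0))
        return np.asarray(times)

    def strain_at(self, t: float) -> float:
        return self.axial_strain * min(t / self.ramp_duration, 1.0)


@dataclass
class FEResult:
    """Transient field solution (SI units: m, Pa, s, m/s)."""

    mesh: DiscMesh
    times: np.ndarray                 # (T,)
    displacement: np.ndarray          # (T, N, 3) m
    pressure: np.ndarray              # (T, N) Pa
    reaction_force: np.ndarray        # (T,) N, axial on the top face
    oscillation_metric: float
    swelling: bool
    materials: dict
    ramp_end: float = 0.0             # s, end of the loading ramp

    def displacement_at(self, t: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.times - t)))
        return self.displacement[i]


def _assemble_patterns(mesh: DiscMesh):
    """Index arrays for COO assembly of the (3N, 3N), (3N, N), (N, N)
    and divergence blocks."""
    elems = mesh.elements
    E = len(elems)
    udof = (3 * elems[:, :, None] + np.arange(3)[None, None, :]).reshape(E, 24)
    rows_K = np.repeat(udof, 24, axis=1).ravel()
    cols_K = np.tile(udof, (1, 24)).ravel()
    rows_G = np.repeat(udof, 8, axis=1).ravel()
    cols_G = np.tile(elems, (1, 24)).ravel()
    rows_H = np.repeat(elems, 8, axis=1).ravel()
    cols_H = np.tile(elems, (1, 8)).ravel()
    return udof, (rows_K, cols_K), (rows_G, cols_G), (rows_H, cols_H)


class _System:
    """Precomputed element matrices and assembly helpers."""

    def __init__(self, mesh: DiscMesh, materials: dict,
                 env: IonEnvironment):
        self.mesh = mesh
        self.env = env
        coords = mesh.element_coords
        self.detJ, self.grads = batched_geometry(coords)  # (E,8), (E,8,8,3)
        self.E = mesh.n_elements
        self.N = mesh.n_nodes

        lam = np.empty(self.E)
        mu = np.empty(self.E)
        kperm = np.empty(self.E)
        cf0 = np.empty(self.E)
        phi0 = np.empty(self.E)
        self.materials = {}
        for name, code in REGION_CODES.items():
            m = materials.get(name)
            idx = mesh.region_labels == code
            if np.any(idx):
                if m is None:
                    raise DomainError(f"no material supplied for region {name}")
                lam[idx] = m.lame_lambda
                mu[idx] = m.shear_modulus
                kperm[idx] = m.k
                cf0[idx] = m.c_F0
                phi0[idx] = m.phi_w0
                self.materials[name] = m
        self.kperm = kperm
        self.cf0 = cf0
        self.phi0 = phi0

        g = self.grads       # (E, g, a, i)
        w = self.detJ        # (E, g)
        # elastic stiffness: lam div-div + mu (grad + grad^T) contraction
        divN = g             # dN_a/dx_i doubles as the div operator entries
        K_div = np.einsum("eg,egai,egbj->eaibj", w, divN, divN)
        K_mu1 = np.einsum("eg,egaj,egbi->eaibj", w, g, g)
        K_mu2 = np.einsum("eg,egak,egbk,ij->eaibj", w, g, g, np.eye(3))
        self.Ke = (lam[:, None, None, None, None] * K_div
                   + mu[:, None, None, None, None] * (K_mu1 + K_mu2)
                   ).reshape(self.E, 24, 24)
        # div-div pattern reused for the osmotic tangent (unit coefficient)
        self.Me_div = K_div.reshape(self.E, 24, 24)
        # coupling: int dN_a/dx_i * N_b
        self.Ge = np.einsum("eg,egai,gb->eaib", w, g, SHAPES_GP
                            ).reshape(self.E, 24, 8)
        # permeability: int k grad N_a . grad N_b
        self.He = kperm[:, None, None] * np.einsum(
            "eg,egak,egbk->eab", w, g, g)

        (self.udof, self.idx_K, self.idx_G, self.idx_H) = \
            _assemble_patterns(mesh)

        self.K = sp.coo_matrix(
            (self.Ke.ravel(), self.idx_K), shape=(3 * self.N, 3 * self.N)
        ).tocsr()
        self.G = sp.coo_matrix(
            (self.Ge.ravel(), self.idx_G), shape=(3 * self.N, self.N)
        ).tocsr()
        self.H = sp.coo_matrix(
            (self.He.ravel(), self.idx_H), shape=(self.N, self.N)
        ).tocsr()

    # -- osmotic terms -----------------------------------------------------
    def div_u_gauss(self, u: np.ndarray) -> np.ndarray:
        ue = u.reshape(-1, 3)[self.mesh.elements]      # (E, 8, 3)
        return np.einsum("egai,eai->eg", self.grads, ue)

    def _pi_fields(self, J: np.ndarray, with_tangent: bool):
        """Osmotic pressure (and tangent) at the Gauss points, grouped by
        the distinct (FCD, porosity) parameter pairs (one per region)."""
        pi_g = np.zeros_like(J)
        dpi_g = np.zeros_like(J) if with_tangent else None
        pairs = {(c, f) for c, f in zip(self.cf0, self.phi0) if c > 0}
        for c, f in pairs:
            sel = (self.cf0 == c) & (self.phi0 == f)
            pi_g[sel] = osmotic_pressure_deformed(c, f, J[sel], self.env)
            if with_tangent:
                dpi_g[sel] = osmotic_modulus(c, f, J[sel], self.env)
        return pi_g, dpi_g

    def osmotic(self, u: np.ndarray):
        """Assembled osmotic force vector and div-div tangent matrix."""
        J = 1.0 + self.div_u_gauss(u)                  # (E, g)
        pi_g, dpi_g = self._pi_fields(J, with_tangent=True)
        # f_osm[a i] = int (pi - pi' div u) dN_a/dx_i  (linearized RHS)
        coeff = pi_g - dpi_g * (J - 1.0)
        fe = np.einsum("eg,eg,egai->eai", self.detJ, coeff, self.grads
                       ).reshape(self.E, 24)
        f = np.zeros(3 * self.N)
        np.add.at(f, self.udof.ravel(), fe.ravel())
        # K_osm = -pi'(J) div-div, elementwise mean tangent
        tangent = -np.einsum("eg,eg->e", self.detJ, dpi_g) / \
            self.detJ.sum(axis=1)
        Ke = tangent[:, None, None] * self.Me_div
        K_osm = sp.coo_matrix((Ke.ravel(), self.idx_K),
                              shape=(3 * self.N, 3 * self.N)).tocsr()
        return f, K_osm

    def osmotic_force(self, u: np.ndarray) -> np.ndarray:
        """Exact (non-linearized) osmotic force vector at state u."""
        J = 1.0 + self.div_u_gauss(u)
        pi_g, _ = self._pi_fields(J, with_tangent=False)
        fe = np.einsum("eg,eg,egai->eai", self.detJ, pi_g, self.grads
                       ).reshape(self.E, 24)
        f = np.zeros(3 * self.N)
        np.add.at(f, self.udof.ravel(), fe.ravel())
        return f


def _dirichlet_maps(mesh: DiscMesh, pin_inplane: bool = True,
                    drained_set: str = "drained"):
    """Constrained displacement dofs (symmetry, bottom axial, top axial)
    and drained pressure nodes."""
    N = mesh.n_nodes
    sets = mesh.boundary_sets
    fixed = {}
    for n in sets["symmetry"]:
        fixed[3 * n + 1] = 0.0
    for n in sets["bottom"]:
        fixed[3 * n + 2] = 0.0
    top = sets["top"]
    top_dofs = 3 * top + 2
    if pin_inplane:
        bot = sets["bottom"]
        xy = mesh.nodes[bot][:, :2]
        pin = bot[int(np.argmin(np.abs(xy[:, 0]) + np.abs(xy[:, 1])))]
        fixed[3 * pin + 0] = 0.0
    drained = sets[drained_set]
    return fixed, top, top_dofs, drained


def solve_biphasic(
    mesh: DiscMesh,
    materials: dict,
    protocol: CompressionProtocol = CompressionProtocol(),
    swelling: bool = False,
    env: IonEnvironment = IonEnvironment(),
    newton_tol: float = 1e-6,
    max_newton: int = 12,
    drained_set: str = "drained",
) -> FEResult:
    """Run the ramp-and-hold compression on a meshed half disc.

    ``materials`` maps region names to :class:`BiphasicMaterial`.  With
    ``swelling`` on, a free-swelling equilibration solve precedes the
    ramp and the Donnan stress rides on every subsequent step; the
    prescribed top-surface displacement is then applied relative to the
    swollen configuration.
    """
    sysm = _System(mesh, materials, env)
    if swelling and np.all(sysm.cf0 == 0):
        raise DomainError("swelling requested but all FCDs are zero")
    fixed, top, top_dofs, drained = _dirichlet_maps(
        mesh, drained_set=drained_set)

    N = mesh.n_nodes
    ndof_u, ndof_p = 3 * N, N
    height = mesh.nodes[:, 2].max() - mesh.nodes[:, 2].min()

    u = np.zeros(ndof_u)
    p = np.zeros(ndof_p)

    # ---- free-swelling pre-equilibration (drained, static) ----
    u_swell_top = np.zeros(len(top))
    if swelling:
        u = _solve_free_swelling(sysm, fixed, newton_tol, max_newton)
        u_swell_top = u[top_dofs].copy()

    times = protocol.times()
    T = len(times)
    disp_out = np.zeros((T, N, 3))
    pres_out = np.zeros((T, N))
    reaction = np.zeros(T)
    disp_out[0] = u.reshape(N, 3)

    # constrained dof bookkeeping for the coupled system
    all_dofs = ndof_u + ndof_p
    con_idx = np.array(sorted(fixed), dtype=np.int64)
    con_idx = np.concatenate([con_idx, top_dofs,
                              ndof_u + np.asarray(drained, dtype=np.int64)])
    con_vals_static = np.concatenate([
        np.array([fixed[d] for d in sorted(fixed)]),
        np.zeros(len(top_dofs)),      # filled per step
        np.zeros(len(drained)),
    ])
    n_static = len(fixed)
    free = np.setdiff1d(np.arange(all_dofs), con_idx)

    lu_cache: dict = {}
    neg_metric = 0.0

    for it in range(1, T):
        dt = times[it] - times[it - 1]
        delta = protocol.strain_at(times[it]) * height
        con_vals = con_vals_static.copy()
        con_vals[n_static:n_static + len(top_dofs)] = u_swell_top - delta

        u_old = u.copy()
        if swelling:
            f_osm, K_osm = sysm.osmotic(u)
            A = _block_system(sysm.K + K_osm, sysm.G, sysm.H, dt)
            lu = splu(_reduce(A, free).tocsc())
        else:
            f_osm = np.zeros(ndof_u)
            key = round(dt, 9)
            if key not in lu_cache:
                A = _block_system(sysm.K, sysm.G, sysm.H, dt)
                lu_cache[key] = (splu(_reduce(A, free).tocsc()),
                                 A)
            lu, A = lu_cache[key]

        du_prev = np.inf
        for newton in range(max_newton):
            b = np.zeros(all_dofs)
            b[:ndof_u] = f_osm
            b[ndof_u:] = -(sysm.G.T @ u_old)
            x = np.concatenate([u, p])
            x[con_idx] = con_vals
            rhs = b[free] - (A @ _lift(con_idx, con_vals, all_dofs))[free]
            sol = lu.solve(rhs)
            if not np.all(np.isfinite(sol)):
                raise SolverError(f"non-finite FE solution at t={times[it]:.3g}")
            x_new = _lift(con_idx, con_vals, all_dofs)
            x_new[free] = sol
            du = np.linalg.norm(x_new[:ndof_u] - x[:ndof_u])
            scale = np.linalg.norm(x_new[:ndof_u]) + 1e-30
            u = x_new[:ndof_u]
            p = x_new[ndof_u:]
            if not swelling:
                break
            rel = du / scale
            if rel < newton_tol or rel > 0.5 * du_prev:
                # converged, or stalled at the linear-solver noise floor
                break
            du_prev = rel
            f_osm = sysm.osmotic(u)[0]  # refresh RHS, keep step tangent
        else:
            warnings.warn(f"swelling iteration hit max_newton at t={times[it]:.3g}")

        disp_out[it] = u.reshape(N, 3)
        pres_out[it] = p
        # reaction on the top face from the momentum residual
        res = (sysm.K @ u) - (sysm.G @ p)
        if swelling:
            res -= sysm.osmotic_force(u)
        reaction[it] = -res[top_dofs].sum()  # + = compressive
        pmax = np.abs(p).max() + 1e-30
        neg_metric = max(neg_metric, float(np.sum(p < -0.05 * pmax) / N))

    if neg_metric > 0.2:
        warnings.warn(
            f"pressure oscillation metric {neg_metric:.2f}; consider a "
            "smaller first time step")

    return FEResult(mesh=mesh, times=times, displacement=disp_out,
                    pressure=pres_out, reaction_force=reaction,
                    oscillation_metric=neg_metric, swelling=swelling,
                    materials=sysm.materials,
                    ramp_end=protocol.ramp_duration)


def _block_system(K, G, H, dt) -> sp.csr_matrix:
    return sp.bmat([[K, -G], [-G.T, -dt * H]], format="csr")


def _reduce(A: sp.csr_matrix, free: np.ndarray) -> sp.csr_matrix:
    return A[free][:, free]


def _lift(con_idx, con_vals, n) -> np.ndarray:
    x = np.zeros(n)
    x[con_idx] = con_vals
    return x


def _solve_free_swelling(sysm: _System, fixed: dict, tol: float,
                         max_newton: int) -> np.ndarray:
    """Static drained equilibrium K u = f_osm(u) under the symmetry /
    bottom constraints only (top free)."""
    N = sysm.N
    con_idx = np.array(sorted(fixed), dtype=np.int64)
    con_vals = np.array([fixed[d] for d in con_idx])
    free = np.setdiff1d(np.arange(3 * N), con_idx)
    u = np.zeros(3 * N)
    for _ in range(max_newton):
        f_osm, K_osm = sysm.osmotic(u)
        A = (sysm.K + K_osm).tocsr()
        rhs = f_osm[free] - (A @ _lift(con_idx, con_vals, 3 * N))[free]
        sol = splu(_reduce(A, free).tocsc()).solve(rhs)
        if not np.all(np.isfinite(sol)):
            raise SolverError("free-swelling solve diverged")
        u_new = _lift(con_idx, con_vals, 3 * N)
        u_new[free] = sol
        change = np.linalg.norm(u_new - u) / (np.linalg.norm(u_new) + 1e-30)
        u = u_new
        if change < tol:
            return u
    warnings.warn("free-swelling equilibration did not fully converge")
    return u
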