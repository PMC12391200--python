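"""Field post-processing: stresses, Darcy flux, peak tables, VTK export."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ..errors import DomainError
from .hexa import center_gradients
from .mesh import DiscMesh, REGION_CODES
from .solver import FEResult

__all__ = ["von_mises", "fluid_flux", "element_stress", "lagrange_strain",
           "peak_table", "write_vtk"]


def von_mises(stress: np.ndarray) -> np.ndarray:
    """Von Mises invariant of symmetric stress tensors (..., 3, 3).

    sqrt(3/2 s:s) with s the deviator; zero for hydrostatic states,
    |sigma| for uniaxial stress.
    """
    stress = np.asarray(stress, dtype=float)
    if stress.shape[-2:] != (3, 3):
        raise DomainError("stress must have shape (..., 3, 3)")
    tr = np.trace(stress, axis1=-2, axis2=-1)
    dev = stress - tr[..., None, None] / 3.0 * np.eye(3)
    return np.sqrt(1.5 * np.einsum("...ij,...ij->...", dev, dev))


def _displacement_gradients(mesh: DiscMesh, u: np.ndarray) -> np.ndarray:
    """H_ij = du_i/dx_j at element centres -> (E, 3, 3)."""
    grads = center_gradients(mesh.element_coords)      # (E, 8, 3)
    ue = u.reshape(-1, 3)[mesh.elements]               # (E, 8, 3)
    return np.einsum("eai,eaj->eij", ue, grads)


def element_stress(mesh: DiscMesh, materials: dict, u: np.ndarray
                   ) -> np.ndarray:
    """Effective (solid, drained) small-strain stress per element centre."""
    H = _displacement_gradients(mesh, u)
    eps = 0.5 * (H + np.transpose(H, (0, 2, 1)))
    lam = np.empty(mesh.n_elements)
    mu = np.empty(mesh.n_elements)
    for name, code in REGION_CODES.items():
        sel = mesh.region_labels == code
        if np.any(sel):
            m = materials[name]
            lam[sel] = m.lame_lambda
            mu[sel] = m.shear_modulus
    tr = np.trace(eps, axis1=1, axis2=2)
    return (lam * tr)[:, None, None] * np.eye(3) + 2.0 * mu[:, None, None] * eps


def lagrange_strain(mesh: DiscMesh, u: np.ndarray) -> np.ndarray:
    """Green-Lagrange strain E = (H + H^T + H^T H)/2 at element centres."""
    H = _displacement_gradients(mesh, u)
    return 0.5 * (H + np.transpose(H, (0, 2, 1))
                  + np.einsum("eki,ekj->eij", H, H))


def fluid_flux(mesh: DiscMesh, k_per_region: dict, p: np.ndarray
               ) -> np.ndarray:
    """Darcy flux w = -k grad(p) at element centres -> (E, 3), m/s."""
    grads = center_gradients(mesh.element_coords)
    pe = p[mesh.elements]                              # (E, 8)
    gp = np.einsum("ea,eaj->ej", pe, grads)
    k = np.empty(mesh.n_elements)
    for name, code in REGION_CODES.items():
        sel = mesh.region_labels == code
        if np.any(sel):
            k[sel] = k_per_region[name] if not hasattr(
                k_per_region[name], "k") else k_per_region[name].k
    return -k[:, None] * gp


def peak_table(result: FEResult, times: dict | None = None) -> pd.DataFrame:
    """Region x time table of peak outcome magnitudes (reporting units).

    ``times`` maps labels to solution times; defaults to end-of-ramp and
    the final (near-equilibrium) time.  Columns: von Mises stress (MPa),
    fluid pressure (kPa), fluid flux (mm/s), and the signed
    anterior-posterior / inferior-superior Lagrange strains of largest
    magnitude.
    """
    mesh = result.mesh
    if times is None:
        times = {"end_of_ramp": _ramp_end(result),
                 "near_equilibrium": float(result.times[-1])}
    rows = []
    for label, t in times.items():
        if t < result.times[0] - 1e-9 or t > result.times[-1] + 1e-9:
            raise DomainError(f"requested time {t} outside solution span")
        i = int(np.argmin(np.abs(result.times - t)))
        u = result.displacement[i].ravel()
        p = result.pressure[i]
        stress = element_stress(mesh, result.materials, u)
        vm = von_mises(stress)
        flux = fluid_flux(mesh, result.materials, p)
        flux_mag = np.linalg.norm(flux, axis=1)
        E = lagrange_strain(mesh, u)
        p_el = np.abs(p[mesh.elements]).max(axis=1)
        for name, code in REGION_CODES.items():
            sel = mesh.region_labels == code
            if not np.any(sel):
                continue
            e_ap = E[sel, 0, 0]
            e_is = E[sel, 2, 2]
            rows.append({
                "time_label": label,
                "time_s": float(result.times[i]),
                "region": name,
                "von_mises_MPa": float(vm[sel].max() / 1e6),
                "pressure_kPa": float(p_el[sel].max() / 1e3),
                "flux_mm_s": float(flux_mag[sel].max() * 1e3),
                "strain_AP": float(e_ap[np.argmax(np.abs(e_ap))]),
                "strain_IS": float(e_is[np.argmax(np.abs(e_is))]),
            })
    return pd.DataFrame(rows)


def _ramp_end(result: FEResult) -> float:
    if result.ramp_end > 0:
        return float(result.ramp_end)
    return float(result.times[len(result.times) // 2])


def write_vtk(path: Path, result: FEResult, time_index: int) -> None:
    """Legacy-ASCII VTK unstructured-grid snapshot of one output time."""
    mesh = result.mesh
    u = result.displacement[time_index]
    p = result.pressure[time_index]
    stress = element_stress(mesh, result.materials, u.ravel())
    vm = von_mises(stress)
    flux = fluid_flux(mesh, result.materials, p)

    lines = ["# vtk DataFile Version 3.0",
             f"biphasic disc t={result.times[time_index]:.6g}s",
             "ASCII", "DATASET UNSTRUCTURED_GRID",
             f"POINTS {mesh.n_nodes} double"]
    for xyz in mesh.nodes:
        lines.append(f"{xyz[0]:.9g} {xyz[1]:.9g} {xyz[2]:.9g}")
    E = mesh.n_elements
    lines.append(f"CELLS {E} {9 * E}")
    for el in mesh.elements:
        lines.append("8 " + " ".join(str(n) for n in el))
    lines.append(f"CELL_TYPES {E}")
    lines.extend(["12"] * E)

    lines.append(f"POINT_DATA {mesh.n_nodes}")
    lines.append("VECTORS displacement double")
    for v in u:
        lines.append(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")
    lines.append("SCALARS pressure double 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(f"{val:.9g}" for val in p)

    lines.append(f"CELL_DATA {E}")
    lines.append("SCALARS von_mises double 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(f"{val:.9g}" for val in vm)
    lines.append("SCALARS region int 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(str(int(c)) for c in mesh.region_labels)
    lines.append("VECTORS fluid_flux double")
    for v in flux:
        lines.append(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")
    Path(path).write_text("\n".join(lines) + "\n")
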