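"""Structured hexahedral meshing of an idealized half-disc.

The cross-section is built by the smooth square-to-ellipse mapping
``u = xi sqrt(1 - eta^2/2), v = eta sqrt(1 - xi^2/2)`` (which avoids
polar-pole degeneracy), scaled to the anterior-posterior depth and
lateral width, with an optional posterior concavity ("bean" dent).
Only the half y >= 0 is meshed; the mid-sagittal plane y = 0 is the
symmetry plane.  The axial direction is z with cartilaginous endplate
(CEP) layers spanning the top and bottom ``cep_thickness``.

Axes: x = anterior(+)/posterior(-), y = lateral, z = axial.
Node coordinates are stored in meters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import DomainError, MeshError
from .hexa import element_volumes

__all__ = ["DiscGeometry", "DiscMesh", "build_disc_mesh",
           "build_cylinder_mesh"]

REGION_CODES = {"NP": 0, "AF": 1, "CEP": 2}
REGION_NAMES = {v: k for k, v in REGION_CODES.items()}


@dataclass(frozen=True)
class DiscGeometry:
    """Parametric half-disc geometry (dimensions in mm)."""

    ap_depth: float = 15.0
    lat_width: float = 20.0
    disc_height: float = 6.0
    cep_thickness: float = 0.9
    np_area_fraction: float = 0.4
    bean_concavity: float = 0.3
    np_posterior_offset: float = -0.15  # NP centre in mapped coords

    def __post_init__(self) -> None:
        for name in ("ap_depth", "lat_width", "disc_height", "cep_thickness"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")
        if 2.0 * self.cep_thickness >= self.disc_height:
            raise DomainError("2*cep_thickness must be below disc_height")
        if not (0.0 < self.np_area_fraction < 1.0):
            raise DomainError("np_area_fraction must lie in (0, 1)")
        if not (0.0 <= self.bean_concavity < 0.9):
            raise DomainError("bean_concavity must lie in [0, 0.9)")


@dataclass
class DiscMesh:
    """Hexahedral mesh with region labels and named boundary sets."""

    nodes: np.ndarray            # (N, 3), meters
    elements: np.ndarray         # (E, 8) node indices, VTK hex order
    region_labels: np.ndarray    # (E,) int codes, see REGION_CODES
    boundary_sets: dict          # name -> node index array
    ref_centroids: np.ndarray | None = None  # (E, 2) mapped-square coords

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def element_coords(self) -> np.ndarray:
        return self.nodes[self.elements]

    def element_volumes(self) -> np.ndarray:
        return element_volumes(self.element_coords)

    def region_names(self) -> np.ndarray:
        return np.array([REGION_NAMES[c] for c in self.region_labels])


def _extrude_block(x2, y2, xi_1d, eta_1d, z_1d):
    """Extrude a structured (xi, eta) cross-section grid along z.

    Returns nodes (N, 3), hex elements (E, 8) in VTK order, per-element
    reference-square centroids (E, 2) and layer indices (E,).
    """
    n_xi = len(xi_1d) - 1
    n_eta = len(eta_1d) - 1
    n_z = len(z_1d)
    nx, ny = n_xi + 1, n_eta + 1
    nodes = np.empty((nx * ny * n_z, 3))

    def nid(i, j, k):
        return (k * ny + j) * nx + i

    # x2/y2 are (xi, eta)-indexed; transpose so the flat order is
    # j (eta) outer, i (xi) inner, matching nid()
    for k, z in enumerate(z_1d):
        base = k * ny * nx
        nodes[base:base + ny * nx, 0] = x2.T.ravel()
        nodes[base:base + ny * nx, 1] = y2.T.ravel()
        nodes[base:base + ny * nx, 2] = z

    elements, ref_centroids, kz = [], [], []
    for k in range(n_z - 1):
        for j in range(n_eta):
            for i in range(n_xi):
                elements.append([
                    nid(i, j, k), nid(i + 1, j, k),
                    nid(i + 1, j + 1, k), nid(i, j + 1, k),
                    nid(i, j, k + 1), nid(i + 1, j, k + 1),
                    nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1),
                ])
                ref_centroids.append([
                    0.5 * (xi_1d[i] + xi_1d[i + 1]),
                    0.5 * (eta_1d[j] + eta_1d[j + 1]),
                ])
                kz.append(k)
    return (nodes, np.asarray(elements, dtype=np.int64),
            np.asarray(ref_centroids), np.asarray(kz))


def _square_to_ellipse(xi: np.ndarray, eta: np.ndarray,
                       a: float, b: float) -> tuple[np.ndarray, np.ndarray]:
    x = a * xi * np.sqrt(np.maximum(1.0 - 0.5 * eta**2, 0.0))
    y = b * eta * np.sqrt(np.maximum(1.0 - 0.5 * xi**2, 0.0))
    return x, y


def _z_layers(geom: DiscGeometry, resolution: int) -> np.ndarray:
    n_cep = max(1, resolution // 4)
    n_core = max(2, resolution)
    cep = geom.cep_thickness
    core = geom.disc_height - 2.0 * cep
    z = np.concatenate([
        np.linspace(0.0, cep, n_cep + 1),
        np.linspace(cep, cep + core, n_core + 1)[1:],
        np.linspace(cep + core, geom.disc_height, n_cep + 1)[1:],
    ])
    return z


def build_disc_mesh(geom: DiscGeometry, resolution: int = 8) -> DiscMesh:
    """Structured half-disc hex mesh at roughly ``resolution`` elements
    across each axis.

    Raises :class:`~discbiphasic.errors.MeshError` if any element has a
    non-positive Jacobian.  NP elements are chosen in the mapped square
    by growing a disc (with the configured posterior offset) until the
    NP share of the cross-section area reaches ``np_area_fraction``.
    """
    if resolution < 4:
        raise DomainError("resolution must be at least 4")

    n_xi = 2 * (resolution // 2) * 2  # even count across the full AP axis
    n_eta = resolution
    xi_1d = np.linspace(-1.0, 1.0, n_xi + 1)
    eta_1d = np.linspace(0.0, 1.0, n_eta + 1)
    z_1d = _z_layers(geom, resolution) * 1e-3  # meters

    xi2, eta2 = np.meshgrid(xi_1d, eta_1d, indexing="ij")
    a = geom.ap_depth / 2.0 * 1e-3
    b = geom.lat_width / 2.0 * 1e-3
    x2, y2 = _square_to_ellipse(xi2, eta2, a, b)
    # posterior bean dent: pull the x < 0 side inward, strongest at the
    # posterior rim near the mid-plane, fading laterally
    if geom.bean_concavity > 0:
        xh = x2 / a
        yh = y2 / b
        g = np.exp(-(yh / 0.45) ** 2)
        x2 = x2 + geom.bean_concavity * a * np.maximum(0.0, -xh) * g

    nodes, elements, ref_centroids, kz = _extrude_block(
        x2, y2, xi_1d, eta_1d, z_1d)

    vols = element_volumes(nodes[elements])
    if np.any(vols <= 0) or not np.all(np.isfinite(vols)):
        raise MeshError("mesh generation produced degenerate elements")
    detJ_ok = _all_gauss_jacobians_positive(nodes[elements])
    if not detJ_ok:
        raise MeshError("non-positive Jacobian at a Gauss point")

    # region labels
    z_mid = 0.5 * (z_1d[kz] + z_1d[kz + 1])
    cep_m = geom.cep_thickness * 1e-3
    h_m = geom.disc_height * 1e-3
    is_cep = (z_mid < cep_m - 1e-12) | (z_mid > h_m - cep_m + 1e-12)

    labels = np.full(len(elements), REGION_CODES["AF"], dtype=int)
    labels[is_cep] = REGION_CODES["CEP"]

    # calibrate the NP radius in mapped coordinates against the actual
    # element cross-section areas of one core layer
    core_layer = kz == int(np.argmax(~(
        (0.5 * (z_1d[:-1] + z_1d[1:])) < cep_m)))
    layer_ids = np.nonzero(core_layer)[0]
    layer_area = vols[layer_ids]  # proportional to cross-area (uniform dz)
    d2 = ((ref_centroids[layer_ids, 0] - geom.np_posterior_offset) ** 2
          + ref_centroids[layer_ids, 1] ** 2)
    order = np.argsort(d2)
    cum = np.cumsum(layer_area[order])
    target = geom.np_area_fraction * layer_area.sum()
    n_in = int(np.searchsorted(cum, target)) + 1
    n_in = min(n_in, len(order))
    rho2 = d2[order][n_in - 1] + 1e-15

    d2_all = ((ref_centroids[:, 0] - geom.np_posterior_offset) ** 2
              + ref_centroids[:, 1] ** 2)
    is_np = (~is_cep) & (d2_all <= rho2)
    labels[is_np] = REGION_CODES["NP"]

    boundary_sets = _boundary_sets(nodes, elements)
    return DiscMesh(nodes=nodes, elements=elements, region_labels=labels,
                    boundary_sets=boundary_sets, ref_centroids=ref_centroids)


def build_cylinder_mesh(radius_mm: float, height_mm: float,
                        n_r: int = 8, n_z: int = 2) -> DiscMesh:
    """Homogeneous half-cylinder mesh (symmetry plane y = 0) for
    validation against the classical unconfined-compression solution.

    The solution of that problem is z-independent, so few axial layers
    suffice.
    """
    a = radius_mm * 1e-3
    n_xi = 2 * max(n_r // 2, 2)
    xi_1d = np.linspace(-1.0, 1.0, n_xi + 1)
    eta_1d = np.linspace(0.0, 1.0, n_r + 1)
    xi2, eta2 = np.meshgrid(xi_1d, eta_1d, indexing="ij")
    x2, y2 = _square_to_ellipse(xi2, eta2, a, a)
    z_1d = np.linspace(0.0, height_mm * 1e-3, n_z + 1)
    nodes, elements, _, _ = _extrude_block(x2, y2, xi_1d, eta_1d, z_1d)
    vols = element_volumes(nodes[elements])
    if np.any(vols <= 0):
        raise MeshError("degenerate cylinder mesh")
    labels = np.full(len(elements), REGION_CODES["AF"], dtype=int)
    return DiscMesh(nodes=nodes, elements=elements, region_labels=labels,
                    boundary_sets=_boundary_sets(nodes, elements))


def _all_gauss_jacobians_positive(coords: np.ndarray) -> bool:
    from .hexa import batched_geometry
    detJ, _ = batched_geometry(coords)
    return bool(np.all(detJ > 0))


_FACES = np.array([
    [0, 3, 2, 1], [4, 5, 6, 7],   # bottom, top
    [0, 1, 5, 4], [1, 2, 6, 5],
    [2, 3, 7, 6], [3, 0, 4, 7],
])


def _boundary_sets(nodes: np.ndarray, elements: np.ndarray) -> dict:
    """Classify exterior faces into symmetry / top / bottom / lateral and
    derive node sets; ``drained`` is every exterior node not exclusively
    on the symmetry plane."""
    from collections import Counter

    face_count: Counter = Counter()
    face_nodes = {}
    for el in elements:
        for f in _FACES:
            quad = tuple(sorted(el[f]))
            face_count[quad] += 1
            face_nodes[quad] = el[f]
    boundary_faces = [face_nodes[q] for q, c in face_count.items() if c == 1]

    z = nodes[:, 2]
    y = nodes[:, 1]
    z_min, z_max = z.min(), z.max()
    tol_z = 1e-9 + 1e-6 * (z_max - z_min)
    tol_y = 1e-9 + 1e-6 * (np.abs(y).max() + 1e-12)

    sym_nodes, top_nodes, bot_nodes = set(), set(), set()
    drained, lateral = set(), set()
    for quad in boundary_faces:
        on_sym = np.all(np.abs(y[quad]) < tol_y)
        on_top = np.all(z[quad] > z_max - tol_z)
        on_bot = np.all(z[quad] < z_min + tol_z)
        if on_sym:
            sym_nodes.update(quad.tolist())
        else:
            drained.update(quad.tolist())
            if not (on_top or on_bot):
                lateral.update(quad.tolist())
        if on_top:
            top_nodes.update(quad.tolist())
        if on_bot:
            bot_nodes.update(quad.tolist())

    return {
        "symmetry": np.array(sorted(sym_nodes), dtype=np.int64),
        "top": np.array(sorted(top_nodes), dtype=np.int64),
        "bottom": np.array(sorted(bot_nodes), dtype=np.int64),
        "drained": np.array(sorted(drained), dtype=np.int64),
        "lateral": np.array(sorted(lateral), dtype=np.int64),
    }
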