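"""Trilinear 8-node hexahedron: shape functions and batched geometry.

Node ordering follows the VTK hexahedron convention: bottom face
counter-clockwise (viewed from +z), then the top face.
"""

from __future__ import annotations

import numpy as np

# reference-cube node coordinates, VTK order
XI_NODES = np.array([
    [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
    [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
], dtype=float)

_G = 1.0 / np.sqrt(3.0)
GAUSS_POINTS = XI_NODES * _G     # 2x2x2 rule, weight 1 each
GAUSS_WEIGHTS = np.ones(8)


def shape_functions(xi: np.ndarray) -> np.ndarray:
    """N_a(xi) for one point xi (3,) -> (8,)."""
    return 0.125 * (1 + XI_NODES[:, 0] * xi[0]) \
        * (1 + XI_NODES[:, 1] * xi[1]) * (1 + XI_NODES[:, 2] * xi[2])


def shape_gradients(xi: np.ndarray) -> np.ndarray:
    """dN_a/dxi_m for one point -> (8, 3)."""
    g = np.empty((8, 3))
    for a in range(8):
        s = XI_NODES[a]
        g[a, 0] = 0.125 * s[0] * (1 + s[1] * xi[1]) * (1 + s[2] * xi[2])
        g[a, 1] = 0.125 * s[1] * (1 + s[0] * xi[0]) * (1 + s[2] * xi[2])
        g[a, 2] = 0.125 * s[2] * (1 + s[0] * xi[0]) * (1 + s[1] * xi[1])
    return g


# precomputed at the 8 Gauss points and at the element centre
GRADS_GP = np.stack([shape_gradients(gp) for gp in GAUSS_POINTS])  # (8,8,3)
SHAPES_GP = np.stack([shape_functions(gp) for gp in GAUSS_POINTS])  # (8,8)
GRADS_CENTER = shape_gradients(np.zeros(3))                         # (8,3)


def batched_geometry(coords: np.ndarray):
    """Jacobians and physical shape gradients for all elements.

    Parameters
    ----------
    coords : (E, 8, 3) element nodal coordinates.

    Returns
    -------
    detJ : (E, 8) Jacobian determinants at the Gauss points.
    grads : (E, 8, 8, 3) physical gradients dN_a/dx at each Gauss point
        (axes: element, gauss point, node, direction).
    """
    # J[e, g, m, n] = sum_a dN_a/dxi_m * x_{e a n}
    J = np.einsum("gam,ean->egmn", GRADS_GP, coords)
    detJ = np.linalg.det(J)
    invJ = np.linalg.inv(J)
    # From J_{mn} = dx_n/dxi_m: dN/dxi_m = sum_n J_{mn} dN/dx_n, so
    # (dN/dx)_n = sum_m (J^{-1})_{nm} (dN/dxi)_m
    grads = np.einsum("egnm,gam->egan", invJ, GRADS_GP)
    return detJ, grads


def center_gradients(coords: np.ndarray):
    """Physical shape gradients at the element centre -> (E, 8, 3)."""
    J = np.einsum("am,ean->emn", GRADS_CENTER, coords)
    invJ = np.linalg.inv(J)
    return np.einsum("enm,am->ean", invJ, GRADS_CENTER)


def element_volumes(coords: np.ndarray) -> np.ndarray:
    detJ, _ = batched_geometry(coords)
    return detJ.sum(axis=1)  # Gauss weights are 1
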