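"""Vertex-model energy and analytic vertex forces.

The tissue energy is

    E = sum_j [ K_V (V_j - V0)^2 + K_A (A_j - A0)^2 ] + gamma * sum_{a in B} A_a

with quadratic penalties on each cell's volume V_j and total surface area
A_j (A0 = s0 * V0^(2/3)) plus a surface tension term linear in the area of
every boundary ("vacuum" or lumen-facing) face.  Faces are triangulated by a
centroid fan; since the centroid is itself a function of the face vertices,
its chain-rule contribution is included in the gradients, so the forces are
exact derivatives of the discrete energy.
"""

from __future__ import annotations

import numpy as np

from .mesh import TissueMesh, MeshError
from .params import VertexModelParams

_EPS = 1e-14


def tissue_energy(mesh: TissueMesh, p: VertexModelParams) -> float:
    """Total mechanical energy of the tissue (sim units)."""
    A, V = mesh.cell_areas_volumes()
    if np.any(V <= 0):
        raise MeshError("degenerate cell with non-positive volume")
    A_f, _ = mesh.face_geometry()
    boundary = mesh.face_kind != 0
    e = (
        p.K_V * np.sum((V - p.V0) ** 2)
        + p.K_A * np.sum((A - p.A0) ** 2)
        + p.gamma * np.sum(A_f[boundary])
    )
    if not np.isfinite(e):
        raise MeshError("non-finite tissue energy")
    return float(e)


def tissue_forces(mesh: TissueMesh, p: VertexModelParams) -> np.ndarray:
    """Per-vertex force F_I = -dE/dr_I, exact for the fan-triangulated mesh."""
    pos = mesh.positions
    tri_face, tri_a, tri_b, fv_face, fv_vert, fsize = mesh._triangulation()
    cent = mesh.face_centroids()

    A_f, V_f = mesh.face_geometry()
    c0 = mesh.face_cells[:, 0]
    c1 = mesh.face_cells[:, 1]
    interior = c1 >= 0
    A = np.bincount(c0, weights=A_f, minlength=mesh.n_cells)
    A += np.bincount(c1[interior], weights=A_f[interior], minlength=mesh.n_cells)
    V = np.bincount(c0, weights=V_f, minlength=mesh.n_cells)
    V -= np.bincount(c1[interior], weights=V_f[interior], minlength=mesh.n_cells)
    if np.any(V <= 0):
        raise MeshError("degenerate cell with non-positive volume")

    # scalar weights multiplying each face's area / volume gradient
    dEdA_cell = 2.0 * p.K_A * (A - p.A0)
    dEdV_cell = 2.0 * p.K_V * (V - p.V0)
    wA = dEdA_cell[c0] + np.where(interior, dEdA_cell[np.clip(c1, 0, None)], 0.0)
    wA += np.where(mesh.face_kind != 0, p.gamma, 0.0)
    wV = dEdV_cell[c0] - np.where(interior, dEdV_cell[np.clip(c1, 0, None)], 0.0)

    c = cent[tri_face]
    a = pos[tri_a]
    b = pos[tri_b]
    n = np.cross(a - c, b - c)
    nrm = np.linalg.norm(n, axis=1)
    nhat = np.where(nrm[:, None] > _EPS, n / np.maximum(nrm, _EPS)[:, None], 0.0)

    # area gradients of triangle (c, a, b)
    gA_c = 0.5 * np.cross(nhat, b - a)
    gA_a = 0.5 * np.cross(nhat, c - b)
    gA_b = 0.5 * np.cross(nhat, a - c)
    # gradients of the signed tetra volume det(c, a, b)/6
    gV_c = np.cross(a, b) / 6.0
    gV_a = np.cross(b, c) / 6.0
    gV_b = np.cross(c, a) / 6.0

    wA_t = wA[tri_face][:, None]
    wV_t = wV[tri_face][:, None]
    grad = np.zeros_like(pos)
    np.add.at(grad, tri_a, wA_t * gA_a + wV_t * gV_a)
    np.add.at(grad, tri_b, wA_t * gA_b + wV_t * gV_b)

    # centroid chain rule: distribute the per-face centroid gradient equally
    gc_face = np.zeros((mesh.n_faces, 3))
    np.add.at(gc_face, tri_face, wA_t * gA_c + wV_t * gV_c)
    gc_face /= fsize[:, None]
    np.add.at(grad, fv_vert, gc_face[fv_face])

    F = -grad
    if not np.all(np.isfinite(F)):
        raise MeshError("non-finite force on a vertex")
    return F
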