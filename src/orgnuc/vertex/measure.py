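"""Per-cell shape and strain measurements.

The compressive strain of a cell is a thickness strain: fit the cell's
vertices at the final frame to a minimal-volume enclosing ellipsoid, take
the short-axis direction n_s, and measure the thickness
H(t) = max_i[r_i(t).n_s] - min_i[r_i(t).n_s]; the engineering strain is
eps_c(t) = [H(0) - H(t)] / H(0), positive under compression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .mesh import TissueMesh, MeshError

log = logging.getLogger(__name__)


def shape_index(mesh_or_area, cell: int | None = None) -> float:
    """Dimensionless shape index A / V^(2/3) of a cell (or of given A, V).

    ``shape_index(mesh, cell)`` measures a cell of a mesh;
    ``shape_index((A, V))`` evaluates the ratio directly.  A sphere gives
    6^(2/3) * pi^(1/3) ~ 4.836, a cube 6, a regular tetrahedron ~ 7.206.
    """
    if isinstance(mesh_or_area, TissueMesh):
        A_all, V_all = mesh_or_area.cell_areas_volumes()
        A, V = float(A_all[cell]), float(V_all[cell])
    else:
        A, V = map(float, mesh_or_area)
    if V <= 0:
        raise MeshError("shape index undefined for non-positive volume")
    return A / V ** (2.0 / 3.0)


@dataclass
class Ellipsoid:
    center: np.ndarray
    axes: np.ndarray  # (3, 3) rows = principal directions
    radii: np.ndarray  # (3,) semi-axis lengths, ascending

    @property
    def short_axis(self) -> np.ndarray:
        return self.axes[0]

    @property
    def aspect_ratio(self) -> float:
        return float(self.radii[-1] / self.radii[0])


def min_volume_ellipsoid(
    points: np.ndarray, tol: float = 1e-6, max_iter: int = 10000
) -> Ellipsoid:
    """Minimal-volume enclosing ellipsoid via the Khachiyan iteration.

    Iterates barycentric weights u until the update falls below ``tol``.
    Raises on degenerate (coplanar / too few) input.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 4:
        raise ValueError("need at least 4 points in 3D")
    if np.linalg.matrix_rank(P - P.mean(axis=0), tol=1e-10) < 3:
        raise MeshError("degenerate input: points are coplanar")
    n, d = P.shape
    Q = np.column_stack([P, np.ones(n)]).T  # (4, n)
    u = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        X = Q @ np.diag(u) @ Q.T
        M = np.einsum("ij,jk,ki->i", Q.T, np.linalg.inv(X), Q)
        j = int(np.argmax(M))
        step = (M[j] - d - 1.0) / ((d + 1.0) * (M[j] - 1.0))
        new_u = (1.0 - step) * u
        new_u[j] += step
        delta = np.linalg.norm(new_u - u)
        u = new_u
        if delta < tol:
            break
    center = P.T @ u
    # ellipsoid {x: (x-c)^T A (x-c) <= 1}, A = M0^-1 / d, semi-axes sqrt(d*eig(M0))
    M0 = P.T @ np.diag(u) @ P - np.outer(center, center)
    evals, evecs = np.linalg.eigh(M0 * d)
    if np.any(evals <= 0):
        raise MeshError("degenerate ellipsoid fit")
    radii = np.sqrt(evals)  # ascending
    return Ellipsoid(center=center, axes=evecs.T, radii=radii)


@dataclass
class CellStrainSeries:
    """Thickness-strain history of one cell."""

    cell_id: int
    short_axis: np.ndarray
    times: np.ndarray
    H: np.ndarray
    eps_c: np.ndarray

    @property
    def t_f(self) -> float:
        return float(self.times[-1])

    @property
    def final_strain(self) -> float:
        return float(self.eps_c[-1])


def _thickness(points: np.ndarray, n_s: np.ndarray) -> float:
    proj = points @ n_s
    return float(proj.max() - proj.min())


def compressive_strain_series(
    trajectory: list[tuple[float, TissueMesh]], cell_id: int
) -> CellStrainSeries:
    """eps_c(t) of one cell along the final-frame ellipsoid short axis."""
    if len(trajectory) < 1:
        raise ValueError("empty trajectory")
    t_f, final = trajectory[-1]
    pts_f = final.positions[final.cell_vertices(cell_id)]
    n_s = min_volume_ellipsoid(pts_f).short_axis
    times, H = [], []
    for t, mesh in trajectory:
        pts = mesh.positions[mesh.cell_vertices(cell_id)]
        times.append(t)
        H.append(_thickness(pts, n_s))
    H = np.asarray(H)
    if H[0] <= 0:
        raise MeshError("vanishing initial thickness H(0)")
    eps = (H[0] - H) / H[0]
    return CellStrainSeries(
        cell_id=cell_id,
        short_axis=n_s,
        times=np.asarray(times),
        H=H,
        eps_c=eps,
    )


def aspect_ratio_distribution(
    mesh: TissueMesh, bins: int | str = "auto"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-cell long/short ellipsoid axis ratios and a normalized histogram.

    Returns ``(ratios, hist, bin_edges)``; degenerate cells are skipped with
    a logged count.
    """
    ratios = []
    skipped = 0
    for c in range(mesh.n_cells):
        pts = mesh.positions[mesh.cell_vertices(c)]
        try:
            ratios.append(min_volume_ellipsoid(pts).aspect_ratio)
        except MeshError:
            skipped += 1
    if skipped:
        log.warning("aspect_ratio_distribution: skipped %d degenerate cells", skipped)
    ratios = np.asarray(ratios)
    hist, edges = np.histogram(ratios, bins=bins, density=True)
    return ratios, hist, edges


def max_strain_cell(trajectory: list[tuple[float, TissueMesh]]) -> int:
    """Cell with the largest final compressive strain; ties -> lowest id."""
    if len(trajectory) < 2:
        raise ValueError("need at least two frames")
    final = trajectory[-1][1]
    best_id, best = 0, -np.inf
    for c in range(final.n_cells):
        eps = compressive_strain_series(trajectory, c).final_strain
        if eps > best + 1e-12:
            best, best_id = eps, c
    return best_id
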