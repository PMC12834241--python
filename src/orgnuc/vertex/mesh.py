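"""Confluent polyhedral tissue mesh and the lumen-organoid builder.

Cells are space-filling polyhedra sharing vertices, edges and faces.  In a
generic confluent tiling every interior edge is shared by exactly three
cells and every interior face by exactly two; faces on the organoid surface
or facing the central lumen are boundary faces ("vacuum" faces carrying the
surface tension term).

The initial organoid is a centroidal-Voronoi tessellation of a spherical
shell: seed points in the shell, mirror ghost points across the outer sphere
and the lumen sphere, a few Lloyd iterations, then the Voronoi cells of the
real seeds form the tissue.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.spatial import Voronoi, cKDTree


class MeshError(RuntimeError):
    """Raised when a mesh is degenerate or a construction is infeasible."""


class TissueMesh:
    """Vertex/edge/face/cell representation of a confluent tissue.

    Parameters
    ----------
    positions : (Nv, 3) float array
        Vertex coordinates (sim length units).
    faces : sequence of int sequences
        Vertex cycles, oriented so the right-hand normal points out of
        ``face_cells[f, 0]``.
    face_cells : (Nf, 2) int array
        Cells on either side of each face; ``-1`` marks the vacuum/lumen
        side of a boundary face (always in column 1).
    face_kind : (Nf,) int array
        0 interior, 1 exterior boundary, 2 lumen boundary.
    n_cells : int
    """

    def __init__(self, positions, faces, face_cells, face_kind, n_cells):
        self.positions = np.ascontiguousarray(positions, dtype=float)
        self.faces = [np.asarray(f, dtype=np.int64) for f in faces]
        self.face_cells = np.asarray(face_cells, dtype=np.int64).reshape(-1, 2)
        self.face_kind = np.asarray(face_kind, dtype=np.int64)
        self.n_cells = int(n_cells)
        self.meta: dict = {}
        self._cache: dict = {}

    # ------------------------------------------------------------------ basic
    @property
    def n_vertices(self) -> int:
        return self.positions.shape[0]

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TissueMesh":
        m = TissueMesh(
            self.positions.copy(),
            [f.copy() for f in self.faces],
            self.face_cells.copy(),
            self.face_kind.copy(),
            self.n_cells,
        )
        m.meta = dict(self.meta)
        return m

    def invalidate(self) -> None:
        self._cache.clear()

    @property
    def cell_faces(self) -> list[list[int]]:
        if "cell_faces" not in self._cache:
            cf: list[list[int]] = [[] for _ in range(self.n_cells)]
            for fid, (c0, c1) in enumerate(self.face_cells):
                cf[c0].append(fid)
                if c1 >= 0:
                    cf[c1].append(fid)
            self._cache["cell_faces"] = cf
        return self._cache["cell_faces"]

    def edges(self) -> np.ndarray:
        """Unique undirected edges, sorted by (min id, max id)."""
        if "edges" not in self._cache:
            pairs = set()
            for cyc in self.faces:
                for k in range(len(cyc)):
                    a, b = int(cyc[k]), int(cyc[(k + 1) % len(cyc)])
                    pairs.add((min(a, b), max(a, b)))
            self._cache["edges"] = np.array(sorted(pairs), dtype=np.int64)
        return self._cache["edges"]

    def edge_faces(self) -> dict[tuple[int, int], list[int]]:
        if "edge_faces" not in self._cache:
            ef: dict[tuple[int, int], list[int]] = {}
            for fid, cyc in enumerate(self.faces):
                for k in range(len(cyc)):
                    a, b = int(cyc[k]), int(cyc[(k + 1) % len(cyc)])
                    ef.setdefault((min(a, b), max(a, b)), []).append(fid)
            self._cache["edge_faces"] = ef
        return self._cache["edge_faces"]

    # --------------------------------------------------------------- geometry
    def _triangulation(self):
        """Flattened centroid-fan triangulation arrays (cached per topology)."""
        if "tri" not in self._cache:
            tri_face, tri_a, tri_b = [], [], []
            fv_face, fv_vert = [], []
            for fid, cyc in enumerate(self.faces):
                m = len(cyc)
                for k in range(m):
                    tri_face.append(fid)
                    tri_a.append(cyc[k])
                    tri_b.append(cyc[(k + 1) % m])
                    fv_face.append(fid)
                    fv_vert.append(cyc[k])
            self._cache["tri"] = (
                np.asarray(tri_face, dtype=np.int64),
                np.asarray(tri_a, dtype=np.int64),
                np.asarray(tri_b, dtype=np.int64),
                np.asarray(fv_face, dtype=np.int64),
                np.asarray(fv_vert, dtype=np.int64),
                np.array([len(c) for c in self.faces], dtype=np.int64),
            )
        return self._cache["tri"]

    def face_centroids(self) -> np.ndarray:
        _, _, _, fv_face, fv_vert, fsize = self._triangulation()
        acc = np.zeros((self.n_faces, 3))
        np.add.at(acc, fv_face, self.positions[fv_vert])
        return acc / fsize[:, None]

    def face_geometry(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-face area and signed volume contribution (outward of c0)."""
        tri_face, tri_a, tri_b, _, _, _ = self._triangulation()
        cent = self.face_centroids()
        c = cent[tri_face]
        a = self.positions[tri_a]
        b = self.positions[tri_b]
        n = np.cross(a - c, b - c)
        area_t = 0.5 * np.linalg.norm(n, axis=1)
        vol_t = np.einsum("ij,ij->i", c, np.cross(a, b)) / 6.0
        A_f = np.bincount(tri_face, weights=area_t, minlength=self.n_faces)
        V_f = np.bincount(tri_face, weights=vol_t, minlength=self.n_faces)
        return A_f, V_f

    def cell_areas_volumes(self) -> tuple[np.ndarray, np.ndarray]:
        A_f, V_f = self.face_geometry()
        c0 = self.face_cells[:, 0]
        c1 = self.face_cells[:, 1]
        A = np.bincount(c0, weights=A_f, minlength=self.n_cells)
        interior = c1 >= 0
        A += np.bincount(c1[interior], weights=A_f[interior], minlength=self.n_cells)
        V = np.bincount(c0, weights=V_f, minlength=self.n_cells)
        V -= np.bincount(c1[interior], weights=V_f[interior], minlength=self.n_cells)
        return A, V

    def cell_vertices(self, cell: int) -> np.ndarray:
        vids: set[int] = set()
        for fid in self.cell_faces[cell]:
            vids.update(int(v) for v in self.faces[fid])
        return np.array(sorted(vids), dtype=np.int64)

    def cell_adjacency(self) -> list[tuple[int, int]]:
        inter = self.face_kind == 0
        return [tuple(sorted(fc)) for fc in self.face_cells[inter]]


# ----------------------------------------------------------------------------
# audits
# ----------------------------------------------------------------------------

def audit_mesh(mesh: TissueMesh, tol: float = 1e-9, raise_on_fail: bool = True) -> dict:
    """Topological and geometric audit of the confluence invariants.

    Checks: face cycles are simple; every cell is a closed, consistently
    oriented surface; interior faces separate exactly two cells; interior
    edges are shared by exactly three faces and three cells; cell volumes
    are positive; no duplicate vertices within ``tol``.
    """
    problems: list[str] = []

    for fid, cyc in enumerate(mesh.faces):
        if len(cyc) < 3:
            problems.append(f"face {fid} has fewer than 3 vertices")
        if len(set(int(v) for v in cyc)) != len(cyc):
            problems.append(f"face {fid} repeats a vertex")

    # closure: within each cell, every directed edge must be matched by its
    # reverse exactly once (faces of c1 traversed in reverse orientation)
    for cell in range(mesh.n_cells):
        directed: dict[tuple[int, int], int] = {}
        for fid in mesh.cell_faces[cell]:
            cyc = mesh.faces[fid]
            seq = cyc if mesh.face_cells[fid, 0] == cell else cyc[::-1]
            for k in range(len(seq)):
                e = (int(seq[k]), int(seq[(k + 1) % len(seq)]))
                directed[e] = directed.get(e, 0) + 1
        for (u, v), cnt in directed.items():
            if cnt != 1 or directed.get((v, u), 0) != 1:
                problems.append(f"cell {cell} is not a closed oriented surface")
                break

    # interior edge sharing counts
    ef = mesh.edge_faces()
    boundary_faces = set(np.nonzero(mesh.face_kind != 0)[0].tolist())
    for edge, fids in ef.items():
        if any(f in boundary_faces for f in fids):
            continue
        if len(fids) != 3:
            problems.append(f"interior edge {edge} shared by {len(fids)} faces")
            continue
        cells = set()
        for f in fids:
            cells.update(int(c) for c in mesh.face_cells[f] if c >= 0)
        if len(cells) != 3:
            problems.append(f"interior edge {edge} touches {len(cells)} cells")

    _, V = mesh.cell_areas_volumes()
    if np.any(V <= 0):
        problems.append(f"{int(np.sum(V <= 0))} cells with non-positive volume")

    if mesh.n_vertices > 1:
        pairs = cKDTree(mesh.positions).query_pairs(tol)
        if pairs:
            problems.append(f"{len(pairs)} duplicate vertex pairs within {tol}")

    report = {"ok": not problems, "problems": problems}
    if problems and raise_on_fail:
        raise MeshError("mesh audit failed: " + "; ".join(problems[:5]))
    return report


# ----------------------------------------------------------------------------
# organoid builder
# ----------------------------------------------------------------------------

def _sample_shell(rng, n, r_in, r_out):
    u = rng.standard_normal((n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    r = (rng.uniform(r_in**3, r_out**3, n)) ** (1.0 / 3.0)
    return u * r[:, None]


def _ghosts(seeds, r_out, r_in):
    """Mirror ghost points across the bounding spheres."""
    rho = np.linalg.norm(seeds, axis=1)
    u = seeds / rho[:, None]
    ghosts = [u * (2.0 * r_out - rho)[:, None]]
    n_outer = seeds.shape[0]
    if r_in > 0:
        gr = 2.0 * r_in - rho
        keep = gr > 1e-6
        inner = u[keep] * gr[keep, None]
        ghosts.append(inner)
        ghosts.append(np.zeros((1, 3)))
        n_lumen = inner.shape[0] + 1
    else:
        n_lumen = 0
    return np.vstack(ghosts), n_outer, n_lumen


def _order_ridge(vertices, axis, centroid):
    """Order a planar convex ridge polygon by angle around ``axis``."""
    d = axis / np.linalg.norm(axis)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(d @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    rel = vertices - centroid
    ang = np.arctan2(rel @ e2, rel @ e1)
    return np.argsort(ang)


def _mesh_from_voronoi(vor: Voronoi, n_real: int, n_lumen: int, merge_tol: float):
    n_points = vor.points.shape[0]
    lumen_start = n_points - n_lumen  # lumen ghosts appended last

    faces, face_cells, face_kind = [], [], []
    used: dict[int, int] = {}
    verts: list[np.ndarray] = []

    def vid(i: int) -> int:
        if i not in used:
            used[i] = len(verts)
            verts.append(vor.vertices[i])
        return used[i]

    for (p, q), rv in zip(vor.ridge_points, vor.ridge_vertices):
        p_real, q_real = p < n_real, q < n_real
        if not (p_real or q_real):
            continue
        if -1 in rv:
            raise MeshError("unbounded face adjacent to a real cell")
        if len(rv) < 3:
            continue
        if not p_real:  # put the real cell first
            p, q = q, p
            p_real, q_real = True, False
        poly = vor.vertices[rv]
        cen = poly.mean(axis=0)
        axis = vor.points[q] - vor.points[p]
        order = _order_ridge(poly, axis, cen)
        cyc = [vid(rv[k]) for k in order]
        # ensure normal points from p toward q
        a, b, c = (vor.vertices[rv[order[k]]] for k in (0, 1, 2))
        if np.cross(b - a, c - a) @ axis < 0:
            cyc = cyc[::-1]
        faces.append(np.array(cyc, dtype=np.int64))
        if q_real:
            face_cells.append((p, q))
            face_kind.append(0)
        else:
            face_cells.append((p, -1))
            face_kind.append(2 if q >= lumen_start else 1)

    positions = np.array(verts)
    # merge near-duplicate vertices
    if positions.shape[0]:
        tree = cKDTree(positions)
        pairs = tree.query_pairs(merge_tol)
        if pairs:
            remap = np.arange(positions.shape[0])
            for i, j in sorted(pairs):
                remap[max(i, j)] = remap[min(i, j)]
            keep = np.unique(remap)
            newid = {int(old): k for k, old in enumerate(keep)}
            positions = positions[keep]
            faces = [
                np.array([newid[int(remap[v])] for v in f], dtype=np.int64)
                for f in faces
            ]

    mesh = TissueMesh(positions, faces, face_cells, face_kind, n_real)
    return mesh


def build_lumen_organoid(
    n_cells: int,
    lumen_fraction: float = 0.25,
    seed: int = 1,
    lloyd_iters: int = 4,
    V0: float = 1.0,
    merge_tol: float = 1e-9,
) -> TissueMesh:
    """Build a confluent organoid of ``n_cells`` cells around a central lumen.

    ``lumen_fraction`` is the lumen volume as a fraction of the enclosing
    ball; 0 gives a solid blob.  Deterministic per seed.  The mesh is
    rescaled so the mean cell volume equals ``V0``.
    """
    if n_cells < 8:
        raise MeshError("need at least 8 cells to close a shell")
    if not 0.0 <= lumen_fraction < 1.0:
        raise ValueError("lumen_fraction must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    r_out = (3.0 * n_cells * V0 / (4.0 * np.pi * (1.0 - lumen_fraction))) ** (1.0 / 3.0)
    r_in = lumen_fraction ** (1.0 / 3.0) * r_out
    margin = 0.25 * V0 ** (1.0 / 3.0)
    seeds = _sample_shell(rng, n_cells, min(r_in + margin, r_out), r_out - margin * 0.5)

    mesh = None
    for it in range(lloyd_iters + 1):
        ghosts, _, n_lumen = _ghosts(seeds, r_out, r_in)
        vor = Voronoi(np.vstack([seeds, ghosts]))
        mesh = _mesh_from_voronoi(vor, n_cells, n_lumen, merge_tol)
        if it == lloyd_iters:
            break
        # Lloyd step: move each seed toward its cell's vertex centroid,
        # clipped back into the shell
        new_seeds = np.array(
            [mesh.positions[mesh.cell_vertices(c)].mean(axis=0) for c in range(n_cells)]
        )
        rho = np.linalg.norm(new_seeds, axis=1)
        lo = r_in + margin if r_in > 0 else 1e-6
        clipped = np.clip(rho, lo, r_out - margin * 0.5)
        seeds = new_seeds / rho[:, None] * clipped[:, None]

    # normalize mean cell volume to V0
    _, V = mesh.cell_areas_volumes()
    if np.any(V <= 0):
        raise MeshError("degenerate cell in constructed organoid")
    scale = (V0 / V.mean()) ** (1.0 / 3.0)
    mesh.positions *= scale
    mesh.invalidate()
    mesh.meta.update(
        n_cells=n_cells,
        lumen_fraction=lumen_fraction,
        seed=seed,
        r_outer=r_out * scale,
        r_lumen=r_in * scale,
    )
    audit_mesh(mesh)
    return mesh
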