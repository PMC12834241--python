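"""Reconnection events: the 3D analog of T1 neighbor exchanges.

An interior edge shorter than the threshold length l_th is replaced by a
small triangular face (edge -> triangle), letting the two cells at the ends
of the edge come into contact; a triangular face whose edges are all below
threshold collapses back to an edge (triangle -> edge).  Both moves preserve
the confluent sharing counts (three cells per interior edge, two per
interior face).  Moves that would involve boundary elements, create
non-manifold faces, or disconnect the cell adjacency graph are rejected
rather than applied.

New elements are created with size ``l_new = l_new_factor * l_th`` so an
applied move does not immediately re-trigger its inverse.
"""

from __future__ import annotations

import numpy as np

from .mesh import TissueMesh


class _Mut:
    """Mutable scratch representation of a mesh during reconnections."""

    def __init__(self, mesh: TissueMesh):
        self.pos: list[np.ndarray] = [p.copy() for p in mesh.positions]
        self.faces: list[list[int] | None] = [list(map(int, f)) for f in mesh.faces]
        self.face_cells: list[list[int]] = [list(map(int, fc)) for fc in mesh.face_cells]
        self.face_kind: list[int] = [int(k) for k in mesh.face_kind]
        self.alive_v: list[bool] = [True] * mesh.n_vertices
        self.n_cells = mesh.n_cells
        self.meta = dict(mesh.meta)

    # ------------------------------------------------------------- structure
    def maps(self):
        edge_faces: dict[tuple[int, int], list[int]] = {}
        vertex_faces: dict[int, set[int]] = {}
        for fid, cyc in enumerate(self.faces):
            if cyc is None:
                continue
            m = len(cyc)
            for k in range(m):
                a, b = cyc[k], cyc[(k + 1) % m]
                edge_faces.setdefault((min(a, b), max(a, b)), []).append(fid)
                vertex_faces.setdefault(a, set()).add(fid)
        return edge_faces, vertex_faces

    def edge_cells(self, edge_faces, e) -> set[int]:
        cells: set[int] = set()
        for f in edge_faces.get(e, ()):
            cells.update(c for c in self.face_cells[f] if c >= 0)
        return cells

    def vertex_cells(self, vertex_faces, v) -> set[int]:
        cells: set[int] = set()
        for f in vertex_faces.get(v, ()):
            cells.update(c for c in self.face_cells[f] if c >= 0)
        return cells

    def new_vertex(self, p: np.ndarray) -> int:
        self.pos.append(np.asarray(p, dtype=float))
        self.alive_v.append(True)
        return len(self.pos) - 1

    def adjacency_connected_without(self, skip_face: int) -> bool:
        adj: dict[int, set[int]] = {c: set() for c in range(self.n_cells)}
        for fid, cyc in enumerate(self.faces):
            if cyc is None or fid == skip_face or self.face_kind[fid] != 0:
                continue
            c0, c1 = self.face_cells[fid]
            adj[c0].add(c1)
            adj[c1].add(c0)
        seen = {0}
        stack = [0]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == self.n_cells

    def to_mesh(self) -> TissueMesh:
        vmap: dict[int, int] = {}
        positions: list[np.ndarray] = []
        faces, face_cells, face_kind = [], [], []
        for fid, cyc in enumerate(self.faces):
            if cyc is None:
                continue
            new_cyc = []
            for v in cyc:
                if v not in vmap:
                    vmap[v] = len(positions)
                    positions.append(self.pos[v])
                new_cyc.append(vmap[v])
            faces.append(new_cyc)
            face_cells.append(self.face_cells[fid])
            face_kind.append(self.face_kind[fid])
        mesh = TissueMesh(np.array(positions), faces, face_cells, face_kind, self.n_cells)
        mesh.meta = self.meta
        return mesh


def _replace_pair(cyc: list[int], a: int, b: int, w: int) -> list[int] | None:
    """Replace the adjacent pair (a, b) in a cycle with the single vertex w."""
    m = len(cyc)
    for k in range(m):
        u, v = cyc[k], cyc[(k + 1) % m]
        if {u, v} == {a, b}:
            out = [w if x == u else x for x in cyc if x != v]
            return out
    return None


def _try_edge_to_triangle(M: _Mut, a: int, b: int, l_new: float) -> bool:
    edge_faces, vertex_faces = M.maps()
    e = (min(a, b), max(a, b))
    fids = edge_faces.get(e)
    if fids is None or len(fids) != 3:
        return False
    if any(M.face_kind[f] != 0 for f in fids):
        return False
    pairs = [frozenset(M.face_cells[f]) for f in fids]
    sides = set().union(*pairs)
    if len(sides) != 3 or len(set(pairs)) != 3 or any(len(p) != 2 for p in pairs):
        return False
    side_face = dict(zip(pairs, fids))

    cells_a = M.vertex_cells(vertex_faces, a)
    cells_b = M.vertex_cells(vertex_faces, b)
    if len(cells_a) != 4 or len(cells_b) != 4:
        return False
    if not sides <= cells_a or not sides <= cells_b:
        return False
    (Ca,) = cells_a - sides
    (Cb,) = cells_b - sides
    if Ca == Cb:
        return False

    touched = vertex_faces[a] | vertex_faces[b]
    if any(M.face_kind[f] != 0 for f in touched):
        return False
    if len(vertex_faces[a]) != 6 or len(vertex_faces[b]) != 6:
        return False
    # the end cells must not already share a face
    if any(frozenset(M.face_cells[f]) == frozenset((Ca, Cb)) for f in touched):
        return False
    if any(len(M.faces[f]) < 4 for f in fids):  # side faces lose one vertex
        return False

    ga: dict[int, int] = {}
    gb: dict[int, int] = {}
    for Ci in sides:
        fa = [f for f in vertex_faces[a] if frozenset(M.face_cells[f]) == frozenset((Ca, Ci))]
        fb = [f for f in vertex_faces[b] if frozenset(M.face_cells[f]) == frozenset((Cb, Ci))]
        if len(fa) != 1 or len(fb) != 1:
            return False
        ga[Ci], gb[Ci] = fa[0], fb[0]
    all_faces = fids + list(ga.values()) + list(gb.values())
    if len(set(all_faces)) != 9:
        return False

    # ---------------------------------------------------------- geometry
    ra, rb = M.pos[a], M.pos[b]
    mid = 0.5 * (ra + rb)
    u = rb - ra
    un = np.linalg.norm(u)
    if un < 1e-14:
        u = np.array([0.0, 0.0, 1.0])
    else:
        u = u / un
    wid: dict[frozenset, int] = {}
    for pair, f in side_face.items():
        cyc = M.faces[f]
        cen = np.mean([M.pos[v] for v in cyc], axis=0)
        d = cen - mid
        d = d - (d @ u) * u
        dn = np.linalg.norm(d)
        if dn < 1e-12:
            d = np.cross(u, np.array([1.0, 0.3, 0.2]))
            dn = np.linalg.norm(d)
        wid[pair] = M.new_vertex(mid + (l_new / np.sqrt(3.0)) * d / dn)

    # ---------------------------------------------------------- new cycles
    new_cycles: dict[int, list[int]] = {}
    for pair, f in side_face.items():
        nc = _replace_pair(M.faces[f], a, b, wid[pair])
        if nc is None:
            return False
        new_cycles[f] = nc

    def split_end(face_id: int, old_v: int, Ci: int) -> bool:
        cyc = M.faces[face_id]
        if cyc.count(old_v) != 1:
            return False
        k = cyc.index(old_v)
        p, nxt = cyc[k - 1], cyc[(k + 1) % len(cyc)]
        ep = (min(p, old_v), max(p, old_v))
        en = (min(old_v, nxt), max(old_v, nxt))
        X = M.edge_cells(edge_faces, ep) - {Ca, Cb, Ci}
        Y = M.edge_cells(edge_faces, en) - {Ca, Cb, Ci}
        if len(X) != 1 or len(Y) != 1 or X == Y:
            return False
        wx = wid.get(frozenset((Ci, next(iter(X)))))
        wy = wid.get(frozenset((Ci, next(iter(Y)))))
        if wx is None or wy is None:
            return False
        new_cycles[face_id] = cyc[:k] + [wx, wy] + cyc[k + 1 :]
        return True

    for Ci in sides:
        if not split_end(ga[Ci], a, Ci):
            return False
        if not split_end(gb[Ci], b, Ci):
            return False

    for f, nc in new_cycles.items():
        if len(nc) < 3 or len(set(nc)) != len(nc):
            return False

    # Triangle face between the end cells, stored with c0 = Ca.  Its winding
    # is fixed combinatorially: traversing any updated (Ca, Ci) face in
    # Ca-outward orientation visits two new vertices as (wa -> wb); closure
    # of Ca's surface then requires T to contain the reverse edge (wb -> wa).
    wvals = set(wid.values())
    Ci = next(iter(sides))
    f = ga[Ci]
    nc = new_cycles[f]
    seq = nc if M.face_cells[f][0] == Ca else nc[::-1]
    tri = None
    for k in range(len(seq)):
        wa_, wb_ = seq[k], seq[(k + 1) % len(seq)]
        if wa_ in wvals and wb_ in wvals:
            (wc_,) = wvals - {wa_, wb_}
            tri = [wb_, wa_, wc_]
            break
    if tri is None:
        return False

    # ------------------------------------------------------------- commit
    for f, nc in new_cycles.items():
        M.faces[f] = nc
    M.faces.append(tri)
    M.face_cells.append([Ca, Cb])
    M.face_kind.append(0)
    M.alive_v[a] = False
    M.alive_v[b] = False
    return True


def _try_triangle_to_edge(M: _Mut, ft: int, l_new: float) -> bool:
    cyc = M.faces[ft]
    if cyc is None or len(cyc) != 3 or M.face_kind[ft] != 0:
        return False
    edge_faces, vertex_faces = M.maps()
    Ca, Cb = M.face_cells[ft]
    extras: dict[int, frozenset] = {}
    for w in cyc:
        cw = M.vertex_cells(vertex_faces, w)
        if len(cw) != 4 or not {Ca, Cb} <= cw:
            return False
        if any(M.face_kind[f] != 0 for f in vertex_faces[w]):
            return False
        if len(vertex_faces[w]) != 6:
            return False
        extras[w] = frozenset(cw - {Ca, Cb})
    sides = set().union(*extras.values())
    if len(sides) != 3 or len(set(extras.values())) != 3:
        return False

    touched = set().union(*(vertex_faces[w] for w in cyc))
    side_face: dict[frozenset, int] = {}
    ga: dict[int, int] = {}
    gb: dict[int, int] = {}
    for w, pair in extras.items():
        fs = [f for f in vertex_faces[w] if frozenset(M.face_cells[f]) == pair]
        if len(fs) != 1:
            return False
        side_face[pair] = fs[0]
    for Ci in sides:
        fa = [f for f in touched if frozenset(M.face_cells[f]) == frozenset((Ca, Ci))]
        fb = [f for f in touched if frozenset(M.face_cells[f]) == frozenset((Cb, Ci))]
        if len(fa) != 1 or len(fb) != 1:
            return False
        if len(M.faces[fa[0]]) < 4 or len(M.faces[fb[0]]) < 4:
            return False
        ga[Ci], gb[Ci] = fa[0], fb[0]
    all_faces = [ft] + list(side_face.values()) + list(ga.values()) + list(gb.values())
    if len(set(all_faces)) != 10:
        return False
    if not M.adjacency_connected_without(ft):
        return False

    # new edge along the triangle normal; Ca sits on the -normal side
    p0, p1, p2 = (M.pos[v] for v in cyc)
    cen = (p0 + p1 + p2) / 3.0
    n = np.cross(p1 - p0, p2 - p0)
    nn = np.linalg.norm(n)
    if nn < 1e-14:
        return False
    n = n / nn
    va = M.new_vertex(cen - 0.5 * l_new * n)
    vb = M.new_vertex(cen + 0.5 * l_new * n)

    new_cycles: dict[int, list[int]] = {}
    for w, pair in extras.items():
        f = side_face[pair]
        fc = M.faces[f]
        if fc.count(w) != 1:
            return False
        k = fc.index(w)
        p = fc[k - 1]
        ep = (min(p, w), max(p, w))
        Z = M.edge_cells(edge_faces, ep) - set(pair)
        if len(Z) != 1 or next(iter(Z)) not in (Ca, Cb):
            return False
        first, second = (va, vb) if next(iter(Z)) == Ca else (vb, va)
        new_cycles[f] = fc[:k] + [first, second] + fc[k + 1 :]
    wset = set(cyc)
    for Ci in sides:
        for f, newv in ((ga[Ci], va), (gb[Ci], vb)):
            fc = M.faces[f]
            ws = [v for v in fc if v in wset]
            if len(ws) != 2:
                return False
            nc = _replace_pair(fc, ws[0], ws[1], newv)
            if nc is None:
                return False
            new_cycles[f] = nc
    for f, nc in new_cycles.items():
        if len(nc) < 3 or len(set(nc)) != len(nc):
            return False

    for f, nc in new_cycles.items():
        M.faces[f] = nc
    M.faces[ft] = None
    for w in cyc:
        M.alive_v[w] = False
    return True


# ----------------------------------------------------------------------------
# public API
# ----------------------------------------------------------------------------

def attempt_reconnections(
    mesh: TissueMesh, l_th: float, l_new_factor: float = 1.5
) -> TissueMesh:
    """Scan for sub-threshold edges and triangles and apply valid moves.

    Edges are scanned in (min id, max id) order; then triangular faces whose
    edges are all below threshold are scanned in face-index order.  The
    returned mesh records the number of applied moves in
    ``meta["n_reconnections"]``.
    """
    if l_th <= 0:
        raise ValueError("l_th must be positive")
    l_new = l_new_factor * l_th
    M = _Mut(mesh)
    n_events = 0

    pos = mesh.positions
    edges = mesh.edges()
    lengths = np.linalg.norm(pos[edges[:, 0]] - pos[edges[:, 1]], axis=1)
    for (a, b), L in zip(edges[lengths < l_th].tolist(), lengths[lengths < l_th]):
        if not (M.alive_v[a] and M.alive_v[b]):
            continue
        if _try_edge_to_triangle(M, a, b, l_new):
            n_events += 1

    for ft in range(len(M.faces)):
        cyc = M.faces[ft]
        if cyc is None or len(cyc) != 3:
            continue
        ps = [M.pos[v] for v in cyc]
        el = [np.linalg.norm(ps[k] - ps[(k + 1) % 3]) for k in range(3)]
        if max(el) >= l_th:
            continue
        if _try_triangle_to_edge(M, ft, l_new):
            n_events += 1

    out = M.to_mesh()
    out.meta["n_reconnections"] = n_events
    return out


def edge_to_triangle(mesh: TissueMesh, a: int, b: int, l_new: float) -> tuple[TissueMesh, bool]:
    """Apply a single edge -> triangle move if valid; returns (mesh, applied)."""
    M = _Mut(mesh)
    ok = _try_edge_to_triangle(M, int(a), int(b), l_new)
    out = M.to_mesh() if ok else mesh
    return out, ok


def triangle_to_edge(mesh: TissueMesh, face_id: int, l_new: float) -> tuple[TissueMesh, bool]:
    """Apply a single triangle -> edge move if valid; returns (mesh, applied)."""
    M = _Mut(mesh)
    ok = _try_triangle_to_edge(M, int(face_id), l_new)
    out = M.to_mesh() if ok else mesh
    return out, ok
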