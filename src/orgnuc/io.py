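"""Readers/writers and run manifests.

Text formats: extended XYZ for trajectory frames (species tags CHR/LAM),
CSV for bond lists and per-cell measurement tables, JSON for configs,
manifests and fits, MatrixMarket for sparse contact maps.  Text output
quotes 9 significant digits; the in-memory arrays are the ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as sio
from scipy import sparse


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------

def write_xyz_frame(fh, positions: np.ndarray, species, comment: str = "") -> None:
    fh.write(f"{positions.shape[0]}\n{comment}\n")
    for tag, (x, y, z) in zip(species, positions):
        fh.write(f"{tag} {x:.9g} {y:.9g} {z:.9g}\n")


def write_nucleus_xyz(path, traj) -> None:
    """All frames of a nucleus trajectory as concatenated extended XYZ."""
    N, M = traj.chain.shape[1], traj.lamina.shape[1]
    species = ["CHR"] * N + ["LAM"] * M
    with open(path, "w") as fh:
        for k in range(traj.n_frames):
            pos = np.vstack([traj.chain[k], traj.lamina[k]])
            write_xyz_frame(
                fh, pos, species,
                comment=f"t={traj.times[k]:.9g} strain={traj.strains[k]:.9g}",
            )


def read_xyz_frames(path):
    """Parse concatenated extended XYZ; yields (comment, species, positions)."""
    frames = []
    lines = Path(path).read_text().splitlines()
    k = 0
    while k < len(lines):
        n = int(lines[k])
        comment = lines[k + 1]
        species, pos = [], np.empty((n, 3))
        for i in range(n):
            parts = lines[k + 2 + i].split()
            species.append(parts[0])
            pos[i] = [float(v) for v in parts[1:4]]
        frames.append((comment, species, pos))
        k += 2 + n
    return frames


def write_tissue_xyz(path, frames) -> None:
    """Vertex positions of a tissue trajectory as extended XYZ."""
    with open(path, "w") as fh:
        for t, mesh in frames:
            write_xyz_frame(
                fh, mesh.positions, ["VTX"] * mesh.n_vertices, comment=f"t={t:.9g}"
            )


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

def write_bond_csv(path, state) -> None:
    df = pd.DataFrame(state.bond_table(), columns=["i", "j", "type", "rest_length"])
    df.to_csv(path, index=False)


def read_bond_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_cell_measurements_csv(path, mesh, strains=None, aspect_ratios=None) -> None:
    from .vertex.measure import shape_index

    A, V = mesh.cell_areas_volumes()
    rows = {
        "cell": np.arange(mesh.n_cells),
        "volume": V,
        "area": A,
        "shape_index": A / V ** (2.0 / 3.0),
    }
    if aspect_ratios is not None:
        rows["aspect_ratio"] = aspect_ratios
    if strains is not None:
        rows["eps_c"] = strains
    pd.DataFrame(rows).to_csv(path, index=False)


def write_strain_series_csv(path, series) -> None:
    pd.DataFrame(
        {"t": series.times, "H": series.H, "eps_c": series.eps_c}
    ).to_csv(path, index=False)


def read_strain_series_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# contact maps
# ---------------------------------------------------------------------------

def write_contact_map(path, cmap) -> None:
    """MatrixMarket coordinate format (upper triangle)."""
    sio.mmwrite(str(path), sparse.triu(cmap.matrix, k=1).astype(np.int8))


def read_contact_map(path):
    upper = sio.mmread(str(path)).tocsr().astype(bool)
    full = upper + upper.T
    from .compare import ContactMap

    return ContactMap(matrix=full.tocsr(), cutoff=float("nan"))


def write_contact_difference_csv(path, diff: dict) -> None:
    rows = []
    for status in ("shared", "ref_only", "pert_only"):
        for i, j in sorted(diff[status]):
            rows.append((i, j, status))
    pd.DataFrame(rows, columns=["i", "j", "status"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# manifests / JSON
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(path, data: dict) -> None:
    Path(path).write_text(json.dumps(_jsonable(data), indent=2, sort_keys=True))


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def write_fit_json(path, fit) -> None:
    write_json(
        path,
        {
            "alpha": fit.alpha,
            "alpha_err": fit.alpha_err,
            "b": fit.b,
            "b_err": fit.b_err,
            "c": fit.c,
            "c_err": fit.c_err,
            "cov": fit.cov,
            "x": fit.x,
            "y": fit.y,
        },
    )


def run_manifest(module: str, params: dict, seed: int, extra: dict | None = None) -> dict:
    """Manifest sufficient to replay a run on one platform."""
    from . import __version__

    man = {
        "module": module,
        "params": _jsonable(params),
        "seed": int(seed),
        "code_version": __version__,
    }
    if extra:
        man.update(_jsonable(extra))
    return man
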