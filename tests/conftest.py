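"""Shared fixtures: desk-scale meshes and nuclei, generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from orgnuc.vertex import build_lumen_organoid, VertexModelParams, TissueMesh
from orgnuc.nucleus import NucleusParams, assemble_state, run_compression
from orgnuc.protocols import constant_rate_protocol


@pytest.fixture(scope="session")
def blob27():
    """27-cell solid organoid (no lumen)."""
    return build_lumen_organoid(27, lumen_fraction=0.0, seed=3)


@pytest.fixture(scope="session")
def organoid64():
    """64-cell organoid with a central lumen."""
    return build_lumen_organoid(64, lumen_fraction=0.15, seed=3)


@pytest.fixture
def vparams():
    return VertexModelParams(s0=5.6)


def make_cube_mesh(edge: float = 1.0) -> TissueMesh:
    """Single cubic cell with outward-oriented faces (V = a^3, A = 6 a^2)."""
    a = edge
    pos = np.array(
        [
            [0, 0, 0], [a, 0, 0], [a, a, 0], [0, a, 0],
            [0, 0, a], [a, 0, a], [a, a, a], [0, a, a],
        ],
        dtype=float,
    )
    faces = [
        [0, 3, 2, 1],  # bottom (z=0), normal -z
        [4, 5, 6, 7],  # top, normal +z
        [0, 1, 5, 4],  # y=0, normal -y
        [2, 3, 7, 6],  # y=a, normal +y
        [0, 4, 7, 3],  # x=0, normal -x
        [1, 2, 6, 5],  # x=a, normal +x
    ]
    face_cells = [(0, -1)] * 6
    face_kind = [1] * 6
    return TissueMesh(pos, faces, face_cells, face_kind, 1)


@pytest.fixture
def cube_mesh():
    return make_cube_mesh()


@pytest.fixture(scope="session")
def micro_nucleus_params():
    return NucleusParams(N=200, M_lam=500, N_C=100, N_L=16, shell_spacing_factor=1.4)


@pytest.fixture(scope="session")
def micro_state(micro_nucleus_params):
    return assemble_state(micro_nucleus_params, seed=5)


@pytest.fixture(scope="session")
def micro_compression(micro_nucleus_params, micro_state):
    """Short plate-compression run reused across dynamics tests."""
    proto = constant_rate_protocol(0.40, 6.0)
    return run_compression(
        micro_state, proto, micro_nucleus_params, seed=5, n_frames=7
    )
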