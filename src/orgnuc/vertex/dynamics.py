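"""Brownian dynamics of the vertex model and the ring-compression drive.

Vertices follow overdamped Euler-Maruyama updates

    r <- r + mu * F * dt + sqrt(2 * mu * kT_eff * dt) * eta

with eta standard normal per component, so each free vertex diffuses with
effective diffusion coefficient mu * kT_eff.
"""

from __future__ import annotations

import numpy as np

from .mesh import TissueMesh, MeshError
from .params import VertexModelParams
from .energy import tissue_forces
from .reconnect import attempt_reconnections
from ..protocols import RingCompressionProtocol


def step_brownian(
    mesh: TissueMesh,
    p: VertexModelParams,
    rng: np.random.Generator,
    in_place: bool = False,
) -> TissueMesh:
    """One Euler-Maruyama step; topology unchanged."""
    out = mesh if in_place else mesh.copy()
    F = tissue_forces(out, p)
    mu = p.mobility
    disp = mu * F * p.dt
    if p.kT_eff > 0:
        disp = disp + np.sqrt(2.0 * mu * p.kT_eff * p.dt) * rng.standard_normal(
            out.positions.shape
        )
    if not np.all(np.isfinite(disp)):
        raise MeshError("Brownian step produced non-finite displacement")
    out.positions = out.positions + disp
    out.invalidate()
    return out


def _band_selection(mesh: TissueMesh, protocol: RingCompressionProtocol) -> np.ndarray:
    """Boolean mask of driven 'outer ring' vertices (geometric selection)."""
    R = mesh.meta.get("r_outer")
    if R is None:
        R = float(np.max(np.linalg.norm(mesh.positions, axis=1)))
    ax = protocol.axis
    z = mesh.positions[:, ax]
    radial_dims = [d for d in range(3) if d != ax]
    rho = np.linalg.norm(mesh.positions[:, radial_dims], axis=1)
    sel = (np.abs(z) <= protocol.axial_half_width_frac * R) & (
        rho >= (1.0 - protocol.radial_band_frac) * R
    )
    return sel


def apply_ring_compression(
    mesh: TissueMesh,
    protocol: RingCompressionProtocol,
    t: float,
    reference_strain: float = 0.0,
) -> TissueMesh:
    """Rescale the radial coordinate of the driven band to the ramp at ``t``.

    The driven vertices' cylindrical radii (about the protocol axis) are
    multiplied by ``(1 - strain(t)) / (1 - reference_strain)``; pass the
    strain already imposed on the mesh as ``reference_strain`` when stepping
    incrementally.  Undriven vertices are untouched.
    """
    sel = _band_selection(mesh, protocol)
    if protocol.total_strain > 0 and not np.any(sel):
        raise MeshError("ring compression band selects no vertices")
    out = mesh.copy()
    factor = (1.0 - protocol.strain(t)) / (1.0 - reference_strain)
    ax = protocol.axis
    radial_dims = [d for d in range(3) if d != ax]
    out.positions[np.ix_(sel, radial_dims)] *= factor
    out.invalidate()
    return out


def run_tissue_compression(
    mesh: TissueMesh,
    p: VertexModelParams,
    protocol: RingCompressionProtocol,
    seed: int,
    n_frames: int = 11,
    t_end: float | None = None,
    reconnect: bool = True,
) -> list[tuple[float, TissueMesh]]:
    """Drive the organoid through the ring protocol; returns (time, frame) list.

    Each step applies Brownian dynamics, then reconnection attempts, then the
    incremental ring drive.  The driven band is re-selected geometrically
    every step so it survives reconnection-induced vertex relabeling.
    """
    rng = np.random.default_rng(seed)
    t_end = protocol.start + protocol.duration if t_end is None else t_end
    n_steps = max(1, int(round(t_end / p.dt)))
    frame_steps = np.unique(np.linspace(0, n_steps, n_frames).astype(int))

    current = mesh.copy()
    frames: list[tuple[float, TissueMesh]] = []
    events = 0
    if 0 in frame_steps:
        frames.append((0.0, current.copy()))
    t = 0.0
    for step in range(1, n_steps + 1):
        current = step_brownian(current, p, rng, in_place=True)
        if reconnect:
            current = attempt_reconnections(current, p.l_th)
            events += current.meta.get("n_reconnections", 0)
        prev_strain = protocol.strain(t)
        t = step * p.dt
        sel = _band_selection(current, protocol)
        if np.any(sel):
            ax = protocol.axis
            radial_dims = [d for d in range(3) if d != ax]
            factor = (1.0 - protocol.strain(t)) / (1.0 - prev_strain)
            current.positions[np.ix_(sel, radial_dims)] *= factor
            current.invalidate()
        if step in frame_steps:
            frames.append((t, current.copy()))
    frames[-1][1].meta["total_reconnections"] = events
    return frames
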