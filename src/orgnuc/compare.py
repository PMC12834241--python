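"""Comparative chromatin observables.

Paired simulations (identical initial configuration and thermal noise, a
perturbed crosslink set) are compared through displacement fields and their
thresholded differences, mean displacement/strain differences versus strain
and versus crosslinker difference, the nonlinear scaling law
y - b = c * x^alpha relating the crosslinker difference x to the mean
displacement difference y, per-spring strain maps, and contact maps (the
simulation analog of a Hi-C matrix).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

log = logging.getLogger(__name__)

#: threshold panel (sim length units) used for displacement-difference maps
DIFFERENCE_THRESHOLDS = (0.0, 1.0, 1.5, 2.0, 2.5, 3.0)

#: default gate on displacement differences, in monomer radii
DISPLACEMENT_GATE_RADII = 3.5


class PairingError(ValueError):
    """Comparison requested between runs that are not paired."""


# ---------------------------------------------------------------------------
# displacement fields
# ---------------------------------------------------------------------------

@dataclass
class DisplacementField:
    """Per-monomer displacements u_i = r_i(t) - r_i(0).

    ``magnitudes_rc`` are in monomer-radius units (the convention used for
    the displacement statistics and the scaling law).
    """

    u: np.ndarray
    r_c: float
    time: float

    @property
    def magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.u, axis=1)

    @property
    def magnitudes_rc(self) -> np.ndarray:
        return self.magnitudes / self.r_c


def displacement_field(traj, frame: int, r_c: float | None = None) -> DisplacementField:
    """Chain displacement field between frame 0 and ``frame``."""
    if not -traj.n_frames <= frame < traj.n_frames:
        raise IndexError(f"frame {frame} not in trajectory")
    u = traj.chain[frame] - traj.chain[0]
    if r_c is None:
        r_c = traj.manifest.get("r_c", 0.05)
    return DisplacementField(u=u, r_c=float(r_c), time=float(traj.times[frame]))


def displacement_pdf(field: DisplacementField, bins="fd"):
    """Normalized histogram of |u| in monomer radii (Freedman-Diaconis)."""
    mags = field.magnitudes_rc
    hist, edges = np.histogram(mags, bins=bins, density=True)
    return hist, edges


def _check_paired(ref, pert):
    if ref.u.shape != pert.u.shape:
        raise PairingError("displacement fields have different monomer counts")


def displacement_difference(
    ref: DisplacementField, pert: DisplacementField, threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """d_i = |u_i^ref - u_i^pert| and the mask d_i > threshold.

    ``threshold`` is in simulation length units, matching the map panels
    (0.0, 1.0, 1.5, 2.0, 2.5, 3.0).  Requires paired runs (same monomer
    indexing); refuse otherwise.
    """
    _check_paired(ref, pert)
    d = np.linalg.norm(ref.u - pert.u, axis=1)
    return d, d > threshold


def mean_displacement_difference(
    ref_fields: list[DisplacementField],
    pert_fields: list[DisplacementField],
    threshold_rc: float = DISPLACEMENT_GATE_RADII,
    convention: str = "paired",
) -> dict:
    """Mean displacement difference across paired realizations, with SEM.

    For each realization the per-monomer differences d_i = |u_i^ref -
    u_i^pert| (in monomer radii) are gated at ``threshold_rc`` and averaged;
    the ensemble mean and SEM over realizations are returned.  With
    ``convention="unpaired_means"`` the alternative reading
    | <|u^ref|> - <|u^pert|> | is used instead.
    Zero support after gating is flagged, not an error.
    """
    if len(ref_fields) != len(pert_fields) or not ref_fields:
        raise PairingError("need equal, non-empty ref and pert ensembles")
    per_real = []
    supports = []
    for r, q in zip(ref_fields, pert_fields):
        _check_paired(r, q)
        if convention == "paired":
            d = np.linalg.norm(r.u - q.u, axis=1) / r.r_c
            sel = d > threshold_rc if threshold_rc > 0 else np.ones_like(d, bool)
            supports.append(int(sel.sum()))
            per_real.append(float(d[sel].mean()) if sel.any() else 0.0)
        elif convention == "unpaired_means":
            per_real.append(
                abs(float(r.magnitudes_rc.mean()) - float(q.magnitudes_rc.mean()))
            )
            supports.append(r.u.shape[0])
        else:
            raise ValueError(f"unknown convention {convention!r}")
    vals = np.asarray(per_real)
    n = vals.size
    return {
        "y": float(vals.mean()),
        "sem": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        "per_realization": vals,
        "n": n,
        "zero_support": all(s == 0 for s in supports),
    }


def distinguishability_onset(
    y_by_level: dict, strains: np.ndarray, n_sem: float = 2.0
):
    """Smallest strain at which perturbation levels separate from the floor.

    ``y_by_level`` maps a perturbation size (e.g. crosslinkers removed) to a
    (realizations x strains) array of the comparison statistic.  The level 0
    entry (or the smallest level) defines the noise floor.  Separation at a
    strain means every other level's mean -/+ ``n_sem`` SEM band lies
    strictly above the floor's band.  Returns ``(onset, curves)`` where
    ``onset`` is the strain or None if the levels never separate; curves
    carry the full mean/SEM tables.
    """
    strains = np.asarray(strains, dtype=float)
    levels = sorted(y_by_level)
    if len(levels) < 2:
        raise ValueError("need at least two perturbation levels")
    curves = {}
    for lev in levels:
        arr = np.atleast_2d(np.asarray(y_by_level[lev], dtype=float))
        if arr.shape[1] != strains.size:
            raise ValueError("statistic grid does not match the strain grid")
        n = arr.shape[0]
        sem = arr.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(strains.size)
        curves[lev] = {"mean": arr.mean(axis=0), "sem": sem}
    floor = curves[levels[0]]
    others = [curves[lev] for lev in levels[1:]]
    onset = None
    for k, s in enumerate(strains):
        hi_floor = floor["mean"][k] + n_sem * floor["sem"][k]
        if all(o["mean"][k] - n_sem * o["sem"][k] > hi_floor for o in others):
            onset = float(s)
            break
    return onset, curves


# ---------------------------------------------------------------------------
# scaling law
# ---------------------------------------------------------------------------

@dataclass
class ScalingFit:
    """Fit of y = b + c * x^alpha with 1-sigma uncertainties."""

    alpha: float
    b: float
    c: float
    alpha_err: float
    b_err: float
    c_err: float
    cov: np.ndarray = field(repr=False, default=None)
    x: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)

    @property
    def superlinear(self) -> bool:
        """alpha > 1 at ~95% confidence (two-sided 1.96 sigma)."""
        return self.alpha - 1.96 * self.alpha_err > 1.0

    @property
    def not_faster_than_linear(self) -> bool:
        return self.alpha - 1.96 * self.alpha_err <= 1.0

    def predict(self, x):
        return self.b + self.c * np.asarray(x, float) ** self.alpha


def fit_scaling_law(x, y, weights=None, maxfev: int = 20000) -> ScalingFit:
    """Weighted nonlinear least squares of y = b + c * x^alpha.

    Initialization: alpha = 2, b = min(y), c from the two-point slope;
    bounds alpha in (0, 10].  ``weights`` are per-point standard deviations
    (as scipy's ``sigma``).  Raises on non-convergence with diagnostics.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need at least 4 (x, y) points")
    if np.any(x <= 0):
        raise ValueError("x must be positive for the power law")

    def model(x_, b, c, alpha):
        return b + c * x_**alpha

    b0 = float(np.min(y))
    i, j = int(np.argmin(x)), int(np.argmax(x))
    with np.errstate(divide="ignore", invalid="ignore"):
        c0 = (y[j] - y[i]) / (x[j] ** 2 - x[i] ** 2)
    if not np.isfinite(c0) or c0 <= 0:
        c0 = max(1e-6, (np.max(y) - b0) / max(np.max(x) ** 2, 1.0))
    try:
        popt, pcov = curve_fit(
            model,
            x,
            y,
            p0=[b0, c0, 2.0],
            sigma=weights,
            absolute_sigma=weights is not None,
            bounds=([-np.inf, 0.0, 1e-6], [np.inf, np.inf, 10.0]),
            maxfev=maxfev,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"power-law fit failed to converge: {exc}; "
            f"x range [{x.min()}, {x.max()}], y range [{y.min()}, {y.max()}]"
        ) from exc
    errs = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    fit = ScalingFit(
        alpha=float(popt[2]),
        b=float(popt[0]),
        c=float(popt[1]),
        alpha_err=float(errs[2]),
        b_err=float(errs[0]),
        c_err=float(errs[1]),
        cov=pcov,
        x=x,
        y=y,
    )
    if not np.all(np.isfinite(popt)):
        raise RuntimeError("power-law fit returned non-finite parameters")
    if fit.not_faster_than_linear:
        log.info("scaling fit: not faster than linear (alpha=%.3f)", fit.alpha)
    return fit


# ---------------------------------------------------------------------------
# spring strain maps
# ---------------------------------------------------------------------------

@dataclass
class SpringStrainMap:
    """Per-spring engineering strains eps = (l - l0)/l0 at one frame."""

    strains: np.ndarray
    bonds: np.ndarray
    bond_type: str
    time: float
    threshold: float | None = None

    def filtered(self, magnitude_threshold: float) -> np.ndarray:
        """Indices of springs with |eps| above the display threshold."""
        return np.nonzero(np.abs(self.strains) > magnitude_threshold)[0]

    def tension_counts(self, magnitude_threshold: float = 0.30) -> dict:
        sel = self.filtered(magnitude_threshold)
        eps = self.strains[sel]
        return {"tension": int(np.sum(eps > 0)), "compression": int(np.sum(eps < 0))}


def spring_strain_map(
    traj, frame: int, magnitude_threshold: float = 0.30
) -> SpringStrainMap:
    """Chain-spring strain map at ``frame`` (rest lengths from the build)."""
    state = traj.state0
    rest = state.chain_rest
    if np.any(rest <= 0):
        raise ValueError("zero rest length in chain bonds")
    pos = traj.chain[frame]
    bonds = state.chain_bonds
    L = np.linalg.norm(pos[bonds[:, 1]] - pos[bonds[:, 0]], axis=1)
    eps = (L - rest) / rest
    return SpringStrainMap(
        strains=eps,
        bonds=bonds,
        bond_type="chain",
        time=float(traj.times[frame]),
        threshold=magnitude_threshold,
    )


def mean_strain_difference(ref_maps, pert_maps) -> dict:
    """Mean |eps_ref - eps_pert| over springs and paired realizations."""
    if len(ref_maps) != len(pert_maps) or not ref_maps:
        raise PairingError("need equal, non-empty ref and pert ensembles")
    per_real = []
    for r, q in zip(ref_maps, pert_maps):
        if r.strains.shape != q.strains.shape:
            raise PairingError("strain maps have different spring counts")
        per_real.append(float(np.abs(r.strains - q.strains).mean()))
    vals = np.asarray(per_real)
    n = vals.size
    return {
        "y": float(vals.mean()),
        "sem": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        "per_realization": vals,
        "n": n,
    }


# ---------------------------------------------------------------------------
# contact maps
# ---------------------------------------------------------------------------

@dataclass
class ContactMap:
    """Symmetric boolean monomer-monomer adjacency at a distance cutoff."""

    matrix: sparse.csr_matrix
    cutoff: float
    include_chain_neighbors: bool = True

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_contacts(self) -> int:
        return self.matrix.nnz // 2

    def pairs(self) -> set[tuple[int, int]]:
        coo = sparse.triu(self.matrix, k=1).tocoo()
        return set(zip(coo.row.tolist(), coo.col.tolist()))


def contact_map(
    positions: np.ndarray,
    cutoff: float,
    include_chain_neighbors: bool = True,
) -> ContactMap:
    """Contacts between monomers closer than ``cutoff``.

    The reference cutoff is two chromatin particle diameters (4 r_c).  The
    diagonal is excluded; chain-adjacent pairs (i, i+1) are kept by default
    and can be dropped with ``include_chain_neighbors=False``.
    """
    pos = np.asarray(positions, dtype=float)
    if not np.all(np.isfinite(pos)):
        raise ValueError("non-finite positions")
    n = pos.shape[0]
    pairs = cKDTree(pos).query_pairs(cutoff, output_type="ndarray")
    if not include_chain_neighbors and pairs.size:
        pairs = pairs[np.abs(pairs[:, 0] - pairs[:, 1]) != 1]
    if pairs.size:
        i = np.concatenate([pairs[:, 0], pairs[:, 1]])
        j = np.concatenate([pairs[:, 1], pairs[:, 0]])
        mat = sparse.csr_matrix(
            (np.ones(i.size, dtype=bool), (i, j)), shape=(n, n)
        )
    else:
        mat = sparse.csr_matrix((n, n), dtype=bool)
    return ContactMap(matrix=mat, cutoff=float(cutoff),
                      include_chain_neighbors=include_chain_neighbors)


def contact_map_difference(ref: ContactMap, pert: ContactMap) -> dict:
    """Gained/lost contact pairs and overlay statistics."""
    if ref.n != pert.n:
        raise ValueError("contact maps have different dimensions")
    pr, pp = ref.pairs(), pert.pairs()
    shared = pr & pp
    return {
        "shared": shared,
        "ref_only": pr - pp,
        "pert_only": pp - pr,
        "n_shared": len(shared),
        "n_ref_only": len(pr - pp),
        "n_pert_only": len(pp - pr),
    }


def mean_contacts_per_monomer(cmap: ContactMap) -> float:
    """(2 x contacts) / N: average contacts per chromatin monomer."""
    return 2.0 * cmap.n_contacts / cmap.n
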