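"""Loading protocols: ring compression for the tissue, plate compression for
the nucleus, and the coupling that turns a cell-strain history into a plate
schedule under the nuclear-shape-tracks-cell-shape assumption."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import UnitRegistry, DEFAULT_UNITS


@dataclass(frozen=True)
class RingCompressionProtocol:
    """Radially drive 'outer' vertices in a mid-plane band inward.

    The band selects vertices with axial coordinate within
    ``axial_half_width`` of the mid-plane and cylindrical radius in the outer
    ``radial_band`` fraction of the organoid radius.  Selected radii follow a
    linear ramp reaching ``total_strain`` at ``start + duration``.
    """

    total_strain: float = 0.20
    duration: float = 1000.0
    start: float = 0.0
    axis: int = 2
    axial_half_width_frac: float = 0.10  # fraction of organoid radius
    radial_band_frac: float = 0.30  # outer fraction of radius driven

    def __post_init__(self) -> None:
        if not 0.0 <= self.total_strain < 1.0:
            raise ValueError("total strain must lie in [0, 1)")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    def strain(self, t: float) -> float:
        """Imposed radial strain at time ``t`` (linear ramp, then hold)."""
        s = np.clip((t - self.start) / self.duration, 0.0, 1.0)
        return float(self.total_strain * s)


@dataclass(frozen=True)
class PlateProtocol:
    """Two rigid plates compressing the nucleus along ``axis``.

    ``strain(t)`` is the total engineering strain on the plate gap
    (``gap(t) = gap0 * (1 - strain(t))``), applied symmetrically: half of the
    gap reduction on each side.  Either a constant rate or a tabulated strain
    history can back the schedule.
    """

    total_strain: float
    duration: float
    axis: int = 2
    wall_stiffness: float | None = None  # None -> use the bond stiffness K
    times: np.ndarray | None = field(default=None, repr=False)
    strains: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.total_strain < 1.0:
            raise ValueError("total strain must lie in [0, 1)")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if (self.times is None) != (self.strains is None):
            raise ValueError("times and strains must be given together")
        if self.times is not None:
            t = np.asarray(self.times, dtype=float)
            s = np.asarray(self.strains, dtype=float)
            if t.shape != s.shape or t.ndim != 1 or t.size < 2:
                raise ValueError("strain table must be two equal 1-d arrays")
            if np.any(np.diff(t) <= 0):
                raise ValueError("strain table times must increase")
            if np.any(s >= 1.0):
                raise ValueError("strain table reaches >= 100% compression")
            if np.any(np.diff(s) < -1e-12):
                raise ValueError("gap(t) must be non-increasing during compression")
            object.__setattr__(self, "times", t)
            object.__setattr__(self, "strains", s)

    @property
    def rate(self) -> float:
        """Mean strain rate (per unit of the protocol's own time base)."""
        return self.total_strain / self.duration

    def strain(self, t: float) -> float:
        if self.times is not None:
            return float(np.interp(t, self.times, self.strains))
        s = np.clip(t / self.duration, 0.0, 1.0)
        return float(self.total_strain * s)

    def gap(self, t: float, gap0: float) -> float:
        g = gap0 * (1.0 - self.strain(t))
        if g <= 0:
            raise ValueError("plates crossed: gap <= 0")
        return g


def constant_rate_protocol(
    total_strain: float, duration: float, axis: int = 2
) -> PlateProtocol:
    """Linear gap schedule with rate = total_strain / duration.

    ``constant_rate_protocol(0.40, 5e4)`` (times in seconds) reproduces the
    reference loading: rate 8e-6 s^-1, compressing the nucleus to 60% of its
    height with 20% taken on each side.
    """
    if not 0.0 < total_strain < 1.0:
        # a zero-strain protocol is still useful as an identity control
        if total_strain != 0.0:
            raise ValueError("total strain must lie in [0, 1)")
    if duration <= 0:
        raise ValueError("duration must be positive")
    return PlateProtocol(total_strain=total_strain, duration=duration, axis=axis)


def _monotone_smooth(y: np.ndarray) -> np.ndarray:
    """Isotonic (non-decreasing) regression of a noisy strain series."""
    from sklearn.isotonic import IsotonicRegression

    x = np.arange(y.size, dtype=float)
    return IsotonicRegression(increasing=True).fit_transform(x, y)


def cell_strain_to_protocol(
    times: np.ndarray,
    eps_c: np.ndarray,
    nucleus_height: float,
    units: UnitRegistry = DEFAULT_UNITS,
    rescale_time: bool = True,
    smooth: bool = True,
) -> PlateProtocol:
    """Map a cell compressive-strain history onto a nuclear plate protocol.

    Under the assumption that nuclear shape tracks cell shape, the plate gap
    follows ``gap(t) = nucleus_height * (1 - eps_c(t))`` with the same strain
    as the cell.  Tissue and nucleus simulations share the same time unit
    (50 s), so by default the time axis carries over unchanged
    (``rescale_time=True`` maps through the registry, which is the identity
    when both time scales are equal); with ``rescale_time=False`` only the
    total strain is matched and the caller retains the tabulated shape on a
    normalized clock.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(eps_c, dtype=float)
    if t.shape != e.shape or t.ndim != 1 or t.size < 2:
        raise ValueError("times and eps_c must be equal-length 1-d arrays")
    if np.any(e >= 1.0):
        raise ValueError("cell strain reaches >= 100%: no feasible gap")
    if nucleus_height <= 0:
        raise ValueError("nucleus height must be positive")
    if smooth:
        e = _monotone_smooth(e)
    e = np.clip(e, 0.0, None)
    if rescale_time:
        # tissue clock -> seconds -> nucleus clock; identity when the two
        # domains share time_s, which they do by default
        t = t * units.factor("time", "tissue") / units.factor("time", "nucleus")
    else:
        t = (t - t[0]) / (t[-1] - t[0])
    total = float(e[-1])
    duration = float(t[-1] - t[0])
    return PlateProtocol(
        total_strain=total,
        duration=duration if duration > 0 else 1.0,
        times=t - t[0],
        strains=e,
    )
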