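"""Unit registry mapping simulation units to biophysical units.

The tissue and nucleus simulations use different length scales (one tissue
length unit is a cell diameter ~10 um; one nucleus length unit is 1 um) but
share the same time scale (50 s per simulation time unit) and energy scale
(one effective thermal energy k_B*T_eff ~ 1e-21 J).
"""

from __future__ import annotations

from dataclasses import dataclass

#: quantity kinds understood by :func:`convert_units`
KINDS = (
    "length",
    "time",
    "energy",
    "velocity",
    "strain_rate",
    "spring_constant",
)


@dataclass(frozen=True)
class UnitRegistry:
    """Linear scale factors from simulation units to SI-ish lab units.

    Lengths are expressed in micrometres, times in seconds, energies in
    joules.  ``spring_constant`` converts to nN/um.
    """

    tissue_length_um: float = 10.0
    nucleus_length_um: float = 1.0
    time_s: float = 50.0
    energy_J: float = 1e-21

    def __post_init__(self) -> None:
        for name in ("tissue_length_um", "nucleus_length_um", "time_s", "energy_J"):
            if getattr(self, name) <= 0:
                raise ValueError(f"unit scale {name} must be positive")

    def length_scale(self, domain: str) -> float:
        if domain == "tissue":
            return self.tissue_length_um
        if domain == "nucleus":
            return self.nucleus_length_um
        raise ValueError(f"unknown domain {domain!r}")

    def factor(self, kind: str, domain: str = "nucleus") -> float:
        """Multiplicative factor taking a sim-unit value to lab units."""
        L = self.length_scale(domain)
        if kind == "length":
            return L
        if kind == "time":
            return self.time_s
        if kind == "energy":
            return self.energy_J
        if kind == "velocity":
            return L / self.time_s
        if kind == "strain_rate":  # dimensionless per time
            return 1.0 / self.time_s
        if kind == "spring_constant":
            # energy / length^2, reported in nN/um:
            # 1 J/um^2 = 1e6 N.um/um^2 / um ... -> 1 J/um^2 = 1e15 nN/um
            return self.energy_J / L**2 * 1e15
        raise ValueError(f"unknown quantity kind {kind!r}")


DEFAULT_UNITS = UnitRegistry()


def convert_units(
    value: float,
    kind: str,
    direction: str = "to_lab",
    units: UnitRegistry = DEFAULT_UNITS,
    domain: str = "nucleus",
) -> float:
    """Convert ``value`` between simulation and lab units.

    Parameters
    ----------
    value : float
        The number to convert.
    kind : str
        One of :data:`KINDS`.
    direction : str
        ``"to_lab"`` (sim -> lab) or ``"to_sim"`` (lab -> sim).
    domain : str
        ``"tissue"`` or ``"nucleus"``; selects the length scale.
    """
    f = units.factor(kind, domain=domain)
    if direction == "to_lab":
        return value * f
    if direction == "to_sim":
        return value / f
    raise ValueError(f"unknown direction {direction!r}")
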