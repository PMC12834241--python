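"""Parameters of the chromatin-lamina nucleus model (simulation units).

One length unit is 1 um, one time unit is 50 s, and the energy unit is the
effective thermal energy k_B*T_eff ~ 1e-21 J; the bond stiffness K = 140
then maps to 1.4e-4 nN/um.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path


@dataclass(frozen=True)
class MotorConfig:
    """Monopole motors: active chain monomers pushing/pulling neighbors.

    Off by default (the compression studies run without motor activity).
    ``force_range`` defaults to two monomer diameters; ``extensile`` selects
    pushing rather than pulling; ``tau_m`` is the mean turnover time after
    which a motor relocates to a random chain position.
    """

    enabled: bool = False
    N_m: int = 0
    strength: float = 0.0
    force_range: float = 0.2
    extensile: bool = False
    tau_m: float = 1.0

    def __post_init__(self) -> None:
        if self.enabled:
            if self.force_range <= 0:
                raise ValueError("motor force range must be positive")
            if self.N_m < 0 or self.tau_m <= 0:
                raise ValueError("invalid motor configuration")


@dataclass(frozen=True)
class NucleusParams:
    """Reference nucleus parameters: N = 5e3 chromatin monomers of radius
    r_c = 0.05, bond/crosslink/linkage stiffness K = 140, soft-core
    stiffness K_ex = 140, N_C = 2440-2500 crosslinkers, M_lam = 1e4 lamina
    monomers at mean coordination ~4.5, N_L = 400 linkages, diffusion
    constant D_Teff = 1, damping xi = 1 (mobility 1/xi)."""

    N: int = 5000
    r_c: float = 0.05
    K: float = 140.0
    K_ex: float = 140.0
    N_C: int = 2500
    M_lam: int = 10000
    z_target: float = 4.5
    N_L: int = 400
    D_Teff: float = 1.0
    xi: float = 1.0
    dt: float = 0.001
    wall_stiffness: float | None = None  # None -> K
    shell_spacing_factor: float = 1.05  # lamina spacing in units of sigma
    rest_length_mode: str = "as_built"  # or "uniform" (2*r_c everywhere)
    crosslink_mode: str = "proximal"  # molecular-range bridging; or "uniform"
    chain_lamina_excluded: bool = True
    chain_lamina_sigma_factor: float = 3.0  # lamina seen as a finite-thickness sheet
    chain_lamina_kex_factor: float = 2.0  # firmer shell contact, still Euler-stable
    motors: MotorConfig = field(default_factory=MotorConfig)

    def __post_init__(self) -> None:
        if min(self.N, self.M_lam, self.N_C, self.N_L) < 0:
            raise ValueError("counts must be non-negative")
        if self.K < 0 or self.K_ex < 0:
            raise ValueError("stiffnesses must be non-negative")
        if self.dt <= 0 or self.xi <= 0 or self.r_c <= 0:
            raise ValueError("dt, xi, r_c must be positive")
        if self.N_C > self.N * (self.N - 1) // 2:
            raise ValueError("more crosslinks than available monomer pairs")
        if self.rest_length_mode not in ("as_built", "uniform"):
            raise ValueError("rest_length_mode must be 'as_built' or 'uniform'")
        if self.crosslink_mode not in ("proximal", "uniform"):
            raise ValueError("crosslink_mode must be 'proximal' or 'uniform'")

    @property
    def mobility(self) -> float:
        return 1.0 / self.xi

    @property
    def sigma(self) -> float:
        """Contact distance between two monomers (sum of radii)."""
        return 2.0 * self.r_c

    @property
    def k_wall(self) -> float:
        return self.K if self.wall_stiffness is None else self.wall_stiffness

    @property
    def shell_radius(self) -> float:
        """Radius giving the lamina a near-close-packed triangular spacing.

        With nearest-neighbor distance d = shell_spacing_factor * sigma and
        one monomer per triangular-lattice area (sqrt(3)/2) d^2,
        R = d * sqrt(sqrt(3) * M / (8 pi)).  For M = 1e4, sigma = 0.1 this
        gives R ~ 2.8 (a ~5.5 um nucleus).
        """
        d = self.shell_spacing_factor * self.sigma
        return d * math.sqrt(math.sqrt(3.0) * self.M_lam / (8.0 * math.pi))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "NucleusParams":
        data = json.loads(Path(path).read_text())
        if "motors" in data and isinstance(data["motors"], dict):
            data["motors"] = MotorConfig(**data["motors"])
        return cls(**data)
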