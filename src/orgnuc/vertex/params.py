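"""Parameters of the 3D vertex model."""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

# shape index of a sphere, 6^(2/3) * pi^(1/3): no closed surface can do better
SPHERE_SHAPE_INDEX = 6.0 ** (2.0 / 3.0) * 3.141592653589793 ** (1.0 / 3.0)


@dataclass(frozen=True)
class VertexModelParams:
    """Reference parameter set of the organoid vertex model (sim units).

    Defaults follow the reference simulations: active energy kT_eff = 1e-4,
    timestep 0.005, area stiffness K_A = 1, volume stiffness K_V = 10,
    target volume V0 = 1, target shape index s0 in 5.0-5.8, boundary surface
    tension gamma = 1, reconnection threshold l_th = 0.02, 152 cells,
    damping xi = 1 (mobility mu = 1/xi).
    """

    kT_eff: float = 1e-4
    dt: float = 0.005
    K_A: float = 1.0
    K_V: float = 10.0
    V0: float = 1.0
    s0: float = 5.6
    gamma: float = 1.0
    l_th: float = 0.02
    N_cells: int = 152
    xi: float = 1.0

    def __post_init__(self) -> None:
        if min(self.K_A, self.K_V, self.gamma, self.kT_eff) < 0:
            raise ValueError("stiffnesses and kT_eff must be non-negative")
        if self.dt <= 0 or self.l_th <= 0 or self.V0 <= 0 or self.xi <= 0:
            raise ValueError("dt, l_th, V0 and xi must be positive")
        if self.s0 < SPHERE_SHAPE_INDEX:
            raise ValueError(
                f"target shape index {self.s0} below the sphere bound "
                f"{SPHERE_SHAPE_INDEX:.3f} is unattainable"
            )

    @property
    def mobility(self) -> float:
        return 1.0 / self.xi

    @property
    def A0(self) -> float:
        """Target area implied by the dimensionless shape index."""
        return self.s0 * self.V0 ** (2.0 / 3.0)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "VertexModelParams":
        data = json.loads(Path(path).read_text())
        # config files may use the reference table key "N" for the cell count
        if "N" in data:
            data["N_cells"] = data.pop("N")
        return cls(**data)
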