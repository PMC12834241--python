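"""End-to-end workflow: tissue compression -> cell strain -> nuclear
loading -> paired crosslink-perturbation ensembles -> comparison statistics
-> scaling fit.

The paired-ensemble contract: for each realization one reference nucleus is
built and compressed; each perturbed run reuses the identical initial
configuration (state, rest lengths) minus k crosslinks and consumes the
identical thermal noise stream, so every difference is attributable to the
crosslink perturbation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .fixtures import FixtureSpec, generate_fixture
from .nucleus import (
    NucleusParams,
    assemble_state,
    remove_crosslinks,
    run_compression,
)
from .nucleus.state import stream_rng
from .protocols import PlateProtocol, cell_strain_to_protocol
from .vertex import (
    run_tissue_compression,
    max_strain_cell,
    compressive_strain_series,
    aspect_ratio_distribution,
)
from .compare import (
    displacement_field,
    mean_displacement_difference,
    fit_scaling_law,
    spring_strain_map,
    mean_strain_difference,
    contact_map,
    mean_contacts_per_monomer,
)
from . import io as onio

log = logging.getLogger(__name__)


def paired_ensemble(
    params: NucleusParams,
    protocol: PlateProtocol,
    deltas: list[int],
    n_realizations: int,
    base_seed: int,
    n_frames: int = 5,
    equilibration: float = 3.0,
    keep_trajectories: bool = False,
):
    """Paired reference/perturbed compression runs over a removal grid.

    Each realization first thermalizes the fully crosslinked nucleus for
    ``equilibration`` time units without plates; the equilibrated
    configuration is the shared initial state of the reference and every
    perturbed run (which differ only by removed crosslink springs), so the
    common crumpling transient of the floppy shell does not enter the
    comparison.  Realization r uses root seed ``base_seed + r``; the
    removal permutation comes from the realization's "removal" stream, so
    removal sets are nested across the grid.  Returns displacement fields,
    strain maps and final-frame contact statistics per removal level
    (level 0 = reference).
    """
    levels = [0] + [d for d in deltas if d != 0]
    out = {
        "fields": {d: [] for d in levels},
        "strain_maps": {d: [] for d in levels},
        "contacts": {d: [] for d in levels},
        "trajectories": {d: [] for d in levels} if keep_trajectories else None,
        "levels": levels,
        "seeds": [],
    }
    cutoff = 4.0 * params.r_c  # two chromatin particle diameters
    from .protocols import constant_rate_protocol

    for r in range(n_realizations):
        seed = base_seed + r
        out["seeds"].append(seed)
        ref = assemble_state(params, seed=seed)
        if equilibration > 0:
            warm = run_compression(
                ref, constant_rate_protocol(0.0, equilibration), params,
                seed=seed + 500_000_000, n_frames=2,
            )
            ref.set_positions(np.vstack([warm.chain[-1], warm.lamina[-1]]))
        rm_seed = int(stream_rng(seed, "removal").integers(2**31 - 1))
        for d in levels:
            if d == 0:
                state = ref
            else:
                state = ref.with_crosslinks(
                    remove_crosslinks(ref.crosslink_bonds, d, seed=rm_seed)
                )
            traj = run_compression(state, protocol, params, seed=seed, n_frames=n_frames)
            out["fields"][d].append(displacement_field(traj, -1, r_c=params.r_c))
            out["strain_maps"][d].append(spring_strain_map(traj, -1))
            out["contacts"][d].append(
                mean_contacts_per_monomer(contact_map(traj.chain[-1], cutoff))
            )
            if keep_trajectories:
                out["trajectories"][d].append(traj)
        log.info("paired ensemble: realization %d/%d done", r + 1, n_realizations)
    return out


def ensemble_scaling_table(ensemble, threshold_rc: float = 0.0) -> pd.DataFrame:
    """y(Delta) table (mean displacement difference vs crosslinkers removed)."""
    rows = []
    ref = ensemble["fields"][0]
    for d in ensemble["levels"]:
        if d == 0:
            continue
        res = mean_displacement_difference(
            ref, ensemble["fields"][d], threshold_rc=threshold_rc
        )
        strain = mean_strain_difference(
            ensemble["strain_maps"][0], ensemble["strain_maps"][d]
        )
        rows.append(
            {
                "delta": d,
                "y": res["y"],
                "sem": res["sem"],
                "strain_diff": strain["y"],
                "strain_diff_sem": strain["sem"],
                "contacts_per_monomer": float(np.mean(ensemble["contacts"][d])),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PipelineConfig:
    fixture: FixtureSpec = field(default_factory=FixtureSpec)
    deltas: tuple = (5, 10, 15, 20, 25, 30)
    n_realizations: int = 12
    threshold_rc: float = 3.5  # the displacement-difference gate, in monomer radii
    out_dir: str | None = None
    full_scale: bool = False  # full reference sizes; hours of compute

    def nucleus_params(self) -> NucleusParams:
        if self.full_scale:
            return NucleusParams()
        return self.fixture.nucleus_params()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the whole workflow and return (and optionally write) a report."""
    if config.full_scale:
        log.warning(
            "full-scale reproduction requested: reference study sizes "
            "(152 cells; 5e3+1e4 monomers, 24 paired realizations) need "
            "hours-to-days of compute"
        )
    fix = generate_fixture(config.fixture)
    spec = config.fixture

    # --- stage 1: tissue compression
    frames = run_tissue_compression(
        fix["mesh"], fix["vertex_params"], fix["ring_protocol"],
        seed=spec.seed, n_frames=9,
    )
    cell = max_strain_cell(frames)
    series = compressive_strain_series(frames, cell)
    ratios_before, _, _ = aspect_ratio_distribution(frames[0][1])
    ratios_after, _, _ = aspect_ratio_distribution(frames[-1][1])

    # --- stage 2: coupling (cell strain -> plate protocol); the default
    # reproduction mode is the constant-rate protocol at the same total
    # strain, the tabulated eps_c(t) pathway is recorded alongside
    nucleus_params = config.nucleus_params()
    gap_height = 2.0 * nucleus_params.shell_radius
    coupled = cell_strain_to_protocol(series.times, series.eps_c, gap_height)
    protocol = fix["plate_protocol"]

    # --- stage 3+4: paired ensembles and comparison statistics
    ensemble = paired_ensemble(
        nucleus_params, protocol, list(config.deltas),
        config.n_realizations, base_seed=spec.seed * 1000 + 1,
    )
    table = ensemble_scaling_table(ensemble, threshold_rc=config.threshold_rc)
    sem = table["sem"].to_numpy()
    fit = fit_scaling_law(
        table["delta"], table["y"], weights=sem if np.all(sem > 0) else None
    )

    report = {
        "tissue": {
            "max_strain_cell": int(cell),
            "final_strain": series.final_strain,
            "mean_aspect_ratio_before": float(np.mean(ratios_before)),
            "mean_aspect_ratio_after": float(np.mean(ratios_after)),
        },
        "coupling": {
            "coupled_total_strain": coupled.total_strain,
            "protocol_total_strain": protocol.total_strain,
            "protocol_duration": protocol.duration,
        },
        "scaling_table": table.to_dict(orient="list"),
        "fit": {
            "alpha": fit.alpha,
            "alpha_err": fit.alpha_err,
            "b": fit.b,
            "b_err": fit.b_err,
            "c": fit.c,
            "superlinear": bool(fit.superlinear),
        },
        "contacts_reference": float(np.mean(ensemble["contacts"][0])),
        "manifest": onio.run_manifest(
            "pipeline", asdict(config.fixture), spec.seed,
            extra={"deltas": list(config.deltas), "n_realizations": config.n_realizations},
        ),
    }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        onio.write_json(out / "report.json", report)
        table.to_csv(out / "y_vs_delta.csv", index=False)
        onio.write_fit_json(out / "scaling_fit.json", fit)
        onio.write_strain_series_csv(out / "cell_strain.csv", series)
    return report
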