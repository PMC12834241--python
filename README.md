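# orgnuc

Coupled multiscale simulations linking tissue mechanics to chromatin
organization: a 3D vertex model of a lumen-containing brain-organoid-like
tissue under localized ring compression, a chromatin–lamina model of a
deformable cell nucleus under plate compression, and the comparative
analysis that asks how *slightly different* chromatin architectures —
encoded as different numbers of chromatin crosslinkers — reorganize under
the same mechanical strain.

The package is for computational biophysicists studying mechanogenomics:
it provides the simulators, the coupling (nuclear shape tracks cell
shape), and the paired-comparison observables (displacement-difference
maps, spring-strain maps, contact maps, and a nonlinear scaling law).

## Models

**Tissue.**  Cells are confluent polyhedra with energy

    E = Σ_j [ K_V (V_j − V0)² + K_A (A_j − A0)² ] + γ Σ_{α∈B} A_α,

A0 = s0·V0^(2/3) with shape index s0, γ acting on exterior and
lumen-facing faces.  Vertices follow overdamped Brownian dynamics with
exact analytic forces; short edges and small triangles exchange through
reconnection events (the 3D analog of T1 transitions).  Per-cell
compressive strain is the thickness strain ε_c(t) = [H(0) − H(t)]/H(0)
along the final-frame minimal-ellipsoid short axis.

**Nucleus.**  A Rouse chain of N monomers (radius r_c, springs K) with N_C
crosslink springs bridging spatially proximate monomer pairs, confined by
a spring-bonded lamina shell of M monomers (mean coordination ≈ 4.5) tied
to the chain by N_L permanent linkages; harmonic soft-core excluded
volume; overdamped dynamics ξṙ = F + Gaussian noise of variance 2 D dt.
Two one-sided harmonic plates compress the shell (never the chromatin
directly) at a prescribed strain rate.

**Comparison.**  Reference (fully crosslinked) and perturbed (k
crosslinkers removed) nuclei share the identical initial configuration and
thermal noise; the mean displacement difference y as a function of the
crosslinker difference x is fit to the scaling law y = b + c·x^α.

## Worked example

```python
import numpy as np
from orgnuc.nucleus import NucleusParams
from orgnuc.protocols import constant_rate_protocol
from orgnuc.pipeline import paired_ensemble, ensemble_scaling_table

params = NucleusParams(N=500, M_lam=1000, N_C=250, N_L=40,
                       shell_spacing_factor=1.4, dt=0.00075)
protocol = constant_rate_protocol(0.40, 8.0)   # 40% strain, sim time units
ens = paired_ensemble(params, protocol, deltas=[10, 20, 30],
                      n_realizations=3, base_seed=1001)
table = ensemble_scaling_table(ens, threshold_rc=3.5)
print(table[["delta", "y", "sem"]].to_string(index=False))
print(f"contacts/monomer (reference): {np.mean(ens['contacts'][0]):.2f}")
```

prints (a few minutes on one core):

```
 delta        y      sem
    10 4.326544 0.514052
    20 4.411086 0.509232
    30 4.555548 0.149990
contacts/monomer (reference): 55.22
```

Each row is the mean displacement difference y between the fully
crosslinked nucleus and the same nucleus with ``delta`` crosslinkers
removed (in monomer radii, gated at 3.5 monomer radii, with the standard
error over the paired realizations): y grows with the crosslinker
difference, and the reference contact count sets the Hi-C-like baseline
that shrinks as crosslinkers are removed.  With more removal levels and
realizations the same table feeds ``orgnuc.compare.fit_scaling_law`` for
the power law y = b + c·x^α.  The protocol arithmetic mirrors the
reference loading: `constant_rate_protocol(0.40, 5e4)` (times in seconds)
reports a strain rate of exactly 8e-6 s⁻¹.

A command-line interface wraps the same library:

    orgnuc tissue-run --cells 27 --strain 0.2 --duration 10 --out runs/tissue
    orgnuc nucleus-pair --remove-crosslinks 10 --seed 1 --out runs/pair
    orgnuc pipeline --preset ensemble --seed 1 --out runs/report

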