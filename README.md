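# flock3d

A minimal continuous model of three-dimensional flocking, for researchers
in collective animal behaviour and active matter who want a small,
fully-tested reference simulator. N self-propelled agents in a periodic
cube follow

    m dv_i/dt = (m/τ)(v0 − |v_i|) v̂_i + Σ_{j≠i} (c/r_ij²) r̂_ij + ξ_i(t),

i.e. each agent (i) relaxes its *speed* toward a preferred value v0 with
time constant τ along its own heading, (ii) repels neighbours closer than
a cutoff R with an inverse-square central force, and (iii) optionally
feels an isotropic random force of fixed magnitude ξ. There is no
explicit velocity-alignment rule: the model demonstrates that speed
control, radial repulsion and the effective weak cohesion of periodic
boundaries are sufficient for stable spatial ordering. Interaction delay
(all forces evaluated t_d earlier) and noise are first-class, so the
stability of the ordered state to both disturbances can be studied.

Ordering is measured by the efficiency E(t) = |Σ v_i|/(N v0) — 1 for a
perfectly aligned flock at speed v0, of order N^(−1/2) for random
headings — and ensembles are summarised by the Binder cumulant
B(E) = 1 − ⟨E⁴⟩/(3⟨E²⟩²).

The package provides:

* `flock3d.model` / `flock3d.space` — forces, parameters, periodic
  geometry and the cell-grid neighbour search;
* `flock3d.integrator` — forward Euler and explicit midpoint stepping
  with noise injection and ring-buffered delayed forces, plus a compiled
  (numba) kernel for long runs;
* `flock3d.initial` — disordered and ordered (equilibrated) starts with
  minimum-distance placement;
* `flock3d.observables` — efficiency, Binder cumulant, transition times,
  ensemble histograms;
* `flock3d.pair_encounter` — the symmetric two-agent scattering
  experiment: the momentum change ΔI(d, φ) and the alignment threshold
  angle;
* `flock3d.experiments` + a `flock3d` CLI — reproducible drivers for the
  ordering ensemble, noise hysteresis and delay sweeps.

## Worked example

Two agents approach symmetrically with their velocity planes d = 2 m
apart, at an initial angle φ between their velocities. Does the
encounter align them?

```python
from flock3d import threshold_angle
from flock3d.pair_encounter import EncounterConfig, run_encounter

res = run_encounter(EncounterConfig(d=2.0, phi=60.0, dt=1e-4))
print(f"delta_I = {res.delta_I:.6f} kg m/s")
print(f"closest approach = {res.closest_approach:.2f} m")
print(f"threshold angle = {threshold_angle(2.0, dt=1e-4):.1f} deg")
```

prints

```
delta_I = 0.002347 kg m/s
closest approach = 4.49 m
threshold angle = 42.9 deg
```

The pair's total momentum grows by 2.3×10⁻³ kg·m/s — they leave more
aligned than they arrived — and the sign of ΔI flips at φ ≈ 43°: pairs
arriving at larger angles align, pairs at smaller angles do not. Across
plane separations d = 1–10 m this threshold stays between 40° and 50°,
the microscopic seed of the collective ordering.

A many-agent run from disorder:

```python
import numpy as np
from flock3d.experiments import desk_scale_params
from flock3d.initial import init_disordered
from flock3d.integrator import run

params = desk_scale_params(N=50)          # production density, L = 31.5 m
state = init_disordered(params, np.random.default_rng(3))
out = run(state, params, T=2.5e4, record_every=10.0, seed=3)
print(f"E(0) = {out.efficiency[0]:.3f} -> E(T) = {out.efficiency[-1]:.3f}")
```

prints `E(0) = 0.142 -> E(T) = 0.974`: the swarm leaves the disordered
plateau (E ~ N^(−1/2)) and locks into the ordered state. Transition
waiting times are broadly distributed — at this system size individual
seeds order anywhere between ~10⁴ and ~10⁵ s, as expected for a
nucleation-like discontinuous transition.

From the shell:

```bash
flock3d pair  --d 2 --out pair_scan.csv
flock3d order --scale desk --seed 1 --seed 2 --horizon 10000 --out runs/
flock3d noise --xi 0 --xi 50 --horizon 1000 --out noise/
flock3d delay --delay-ms 0 --delay-ms 50 --horizon 500 --out delay/
```

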