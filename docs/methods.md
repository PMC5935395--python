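# Methods

## Model

`flock3d` simulates N self-propelled agents in a cubic box of side L with
periodic boundaries in all three directions. Agent i carries a position
r_i and velocity v_i, and obeys

    m dv_i/dt = (m/τ) (v0 − |v_i|) v_i/|v_i|  +  Σ_{j≠i} (c/r_ij²) r̂_ij  +  ξ_i(t),

where r_ij = r_i − r_j is the minimum-image displacement, the sum runs
over neighbours with r_ij below the cutoff R, and ξ_i is an optional
random force. The first term relaxes each agent's *speed* toward the
preferred value v0 with time constant τ, acting purely along the agent's
own heading — there is no explicit velocity-alignment term, no
anisotropy, and no vision cone; the model's point is that speed control
plus radial repulsion plus the effective weak cohesion of the periodic
box suffice for spatial ordering. The inverse-square repulsion is the
collision-avoidance mechanism; it is strong at short range and (in the
many-agent runs) truncated at R.

Default constants (SI units): v0 = 5 m/s, τ = 1 s, m = 1 kg, c = 1 N·m²,
R = 10 m, L = 50 m with N = 200 (number density 1.6×10⁻³ m⁻³), Δt = 10⁻³ s
with the midpoint integrator. The box must satisfy floor(L/R) ≥ 3 so the
27-cell neighbour search of the cell grid is exhaustive.

## Integration

Many-agent runs use the classical explicit midpoint method: forces F1 at
(t, x) build a half-step state at t + Δt/2; forces F2 evaluated there
advance the velocity over the full step, while the position advances with
the half-step velocity. Positions are wrapped into [0, L) every step;
velocities are unbounded. The two-agent encounter experiment uses forward
Euler at Δt = 10⁻⁵ s, whose accuracy is verified explicitly (below). For
the single-agent speed ODE the midpoint endpoint error scales as Δt²
(halving Δt reduces it ≈4×), Euler as Δt.

A compiled (numba) kernel executes the inner loop; a transparent
pure-Python step implementation defines the semantics and the two are
tested against each other. The kernel's pair search is an all-pairs
minimum-image scan with the cutoff applied per pair; at the system sizes
used here (3³–5³ grid cells) the 27-cell grid search would visit the same
pairs, and the grid implementation in `flock3d.space` is verified against
an O(N²) oracle instead of being duplicated inside the kernel.

## Noise

The noise force has a fixed magnitude ξ and a direction drawn uniformly
on the sphere, independently per agent and per application
("uncorrelated in time and among agents"). Two amplitude conventions are
implemented for the velocity increment applied over an interval h:

* **step** (default): |Δv| = ξ·h/m — a constant force of magnitude ξ held
  over the interval, giving velocity diffusion ξ²Δt/m² per unit time.
  This is the convention the model's reported noise thresholds (order
  kept/destroyed near ξ ≈ 50 at Δt = 10⁻³ s) are calibrated to: the
  resulting stationary speed fluctuation ~ξ√(τΔt/2)/m ≈ 1.1 m/s is
  comparable to v0 = 5 m/s, which is the regime where hysteresis is
  observable.
* **sqrt**: |Δv| = ξ·√h/m — diffusive scaling, Δt-independent, provided
  for sensitivity checks. At ξ = 50 it implies stationary fluctuations of
  ~35 m/s ≫ v0, deep in the disordered regime.

In the midpoint scheme a fresh impulse with h = Δt/2 perturbs the
half-step velocity and an independent impulse with h = Δt is added after
the full-step update. Noise is drawn at application time and never
routed through the delay buffers.

## Delayed interactions

A single delay t_d (an exact integer multiple of Δt) applies to all
deterministic forces: the right-hand side at time t uses the forces
evaluated at t − t_d, including self-propulsion. Ring buffers store every
full-step and half-step force evaluation; a lookup before the buffer
holds t_d of history returns the oldest record (clamped lookup), which
avoids a discontinuous force onset at the start of a run. With t_d = 0
the buffered path reproduces the plain path bit for bit, which is
asserted exactly in the tests.

## Initial conditions

Positions are drawn uniformly by sequential rejection sampling with all
minimum-image pair distances ≥ 0.6·L·N^(−1/3) (≈5.1 m for the production
box — a loose packing the sampler fills easily). Speeds start exactly at
v0. The disordered start draws independent uniform headings, so
E(0) ~ N^(−1/2) (≈0.07 at N = 200). The ordered start aligns every
velocity along one random heading and then relaxes the spatial structure
with a noiseless equilibration run before relabelling time to t = 0; the
production protocol equilibrates for 10⁵ s, desk-scale runs use 10³ s,
after which E has settled near 1 (the transient dip as agents attain
spatial order is visible early in the run).

## Observables

* Efficiency E(t) = |Σ v_i|/(N v0); not clamped above 1 (it can exceed 1
  when many agents are faster than v0).
* Binder cumulant B(E) = 1 − ⟨E⁴⟩/(3⟨E²⟩²) with plain moment estimators
  across an ensemble (bias corrections are negligible at the run counts
  used); optional B/N normalisation.
* Transition time: earliest recorded time after which E stays above a
  threshold for a dwell window (default one recording interval), on the
  recorded cadence without interpolation.
* Ensemble histogram: counts of runs per (ratio-spaced time bin ×
  E bin of width 0.01), as in the production figures (time ratio 10^(1/30)).

"Tail E" is the mean of E over the final 10% of a run's horizon; a run is
classified ordered above 0.8, disordered below 0.3, undecided between.

## Two-agent encounter

Two identical agents whose velocities stay mirror images of each other:
agent 1 at (−D0/2, 0, +d/2) with velocity v0(sin φ/2, cos φ/2, 0), agent
2 its image under (x, z) → (−x, −z). The literal point reflection through
the centre of mass would force the total momentum to vanish identically,
so the geometry is realised as the x = 0 mirror plane with opposite
velocity-plane offsets ±d/2 — the only reading under which the pair's
total momentum can grow. "Horizontal distance" is the xy-projected
separation (projection along the plane normal): D0 = 1000 m at the start,
integration stops at 1100 m. Parameters v0 = 1 m/s, τ = 1 s, c = 1 N·m²,
ξ = 0, no cutoff, no box; Euler with dt = 10⁻⁵ s (scans use 10⁻⁴ s,
justified by the measured dt-sensitivity of ΔI, which is well below the
mapped ΔI scale). ΔI = |p1 + p2| at the stop minus its initial value;
by symmetry the total momentum points along y throughout. The threshold
angle where ΔI changes sign is located by a coarse scan plus bisection.

The threshold grows with the plane separation — closer passages align
pairs arriving at smaller angles: measured values (dt-stable) are ≈35°
at d = 1 m, 42.9° at d = 2 m, ≈49–50° across d = 3–6 m, and ≈55° at
d = 10 m. The characteristic 40–50° alignment band therefore covers the
mid-range separations d ≈ 2–6 m.

## Problem sizes and what the desk-scale tests show

The production ensembles (500 runs of N = 200 to t = 10⁶ s; hysteresis
grids over 10⁵ s) are cluster-scale; this package asserts the model's
behaviour at reduced scale and ships the production presets unasserted.
Desk-scale choices: N = 50 at the production density (L ≈ 31.5 m),
horizons of 10³–10⁴ s, ensembles of 5 seeds; encounter scans at
Δt = 10⁻⁴ s with spot checks at 10⁻⁵ s.

One caveat the reduced scale exposes: the disorder→order transition is a
rare-event (nucleation-like) process with a broad waiting-time
distribution. At N = 50 and the production density a substantial
fraction of seeds have not yet ordered by t = 10⁴ s (the paper-scale
system transitions between 10⁴ and 10⁶ s), so assertions that *every*
run orders within 10⁴ s are at the mercy of the waiting-time tail; the
acceptance suite states the contract at that horizon and the measured
pass rate is reported honestly by `scripts/acceptance.py`.

The noise-stability boundary moves with system size: at N = 50 an
equilibrated ordered flock survives ξ = 5 indefinitely on the horizons
tested but is torn apart within a few hundred seconds at ξ ≳ 20, whereas
the production system holds order at ξ = 50. The desk-scale hysteresis
check therefore sits at ξ = 5 (ordered start keeps E > 0.8, disordered
start stays below 0.3, over 5 seeds and a 500 s horizon, after a 300 s
ordered-start equilibration), with a strong-noise control at ξ = 100.
Delay persistence is asserted from ordered starts at t_d = 10 and 50 ms
(tail E > 0.9 over 300 s, 5 seeds). The complementary delay contract —
that the disorder→order *rate* decreases with t_d — needs completed
disordered-start transitions and is therefore cluster-scale; at desk
scale it is not asserted (the delay machinery itself is verified exactly
through the zero-delay identity and the delayed-path unit tests).

The synthetic start states emulate the study conditions exactly (they
are the study conditions — the model has no external data); what passing
tests do not show is behaviour at production N and horizons, which the
presets reach only on longer budgets.

## Numerical choices

* Pair distance cutoff is strict (< R); distances use the minimum-image
  convention throughout, including initial placement.
* Cell side is L/floor(L/R) ≥ R so the grid tiles the box exactly.
* |v| = 0 makes the propulsion direction undefined; the force is zero
  there (any fixed direction would break isotropy; the event is
  measure-zero and unreachable from v(0) = v0 starts).
* Coincident agents (r = 0) are a hard error: the initializer forbids
  them and the integrator aborts on the resulting non-finite forces.
* The noise stream is chunk-seeded from the run seed at every recording
  interval, so a seeded run is exactly reproducible at a fixed recording
  cadence.

## Known limitations

* The kernel's all-pairs search is O(N²) per step; production N = 200 is
  comfortable, but much larger systems would want the cell grid inside
  the compiled loop.
* The delay buffer's warm-up clamp (oldest-record lookup) is a modelling
  choice where the protocol is silent; its effect is confined to the
  first t_d of a run.
* Whether the original integrator advanced positions with the half-step
  or the updated velocity is not documented; the classical midpoint
  (half-step velocity) is used.
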