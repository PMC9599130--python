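# Methods

`spillsim` is a particle-based Monte Carlo model of glutamate release,
diffusion and astroglial uptake in a stochastically generated neuropil.
This note records the model, its assumptions, the numerical choices, and the
limits of what the synthetic tissue can show about real brain tissue.

## Tissue model

Brain neuropil is represented as a cubic arena (default edge 4 μm) filled
with randomly scattered, **overlapping spheres** whose radii are uniform
between 50 and 300 nm, mimicking the size range of neuronal and astroglial
processes seen in 3D-EM reconstructions. The extracellular space (ECS) is
the complement of the sphere union; nothing else is modelled inside cells.
A disk-shaped **synaptic cleft** (120 nm diameter × 20 nm height, axis along
z) sits at the arena centre; its two flat faces are reflecting membranes
(pre- and postsynaptic), its lateral rim is open, and no sphere surface may
come within 10 nm of the cleft cylinder (candidates violating this exclusion
are redrawn).

Spheres are added one at a time, centres uniform over the arena, until the
fraction of uniform calibration test points left uncovered reaches the
target ECS fraction α (default 0.2, physiological range 0.1–0.3). Adding
one sphere moves α by only ~1e-4, so the stopping overshoot is negligible
against the default tolerance of 0.01. The realized α is then *validated*
on an independent set of test points (default 1e5); generation fails loudly
if the tolerance is missed.

**Astroglia labelling.** Each sphere receives a uniform mark u at creation
and is labelled astroglial when u falls below a threshold chosen so that the
astroglial share of *total* volume matches the target (default 10%,
hippocampal-like). The threshold is the k-th order statistic of the
per-point minimum covering mark (k = target × number of calibration points),
which is the exact solution of the "calibrate the labelling probability"
problem — monotone-equivalent to bisection but deterministic. A test point
covered by both kinds counts as astroglial: the overlap rule favours the
binding surface and is configurable in spirit (documented here; the
classifier lives in one kernel).

Two edge effects are worth knowing. Because sphere *centres* are confined
to the arena, coverage thins near the walls, so the arena-wide α slightly
exceeds the α of the interior region around the synapse (~0.16 locally when
the global value is 0.20). The validation is arena-wide, and we
keep it that way. Second, every trial generates a fresh tissue realization;
all reported profiles are averages over such realizations.

## Molecule dynamics

1000 glutamate molecules are released instantaneously, uniform over the
cleft cylinder volume. Each performs a **fixed-length isotropic random
walk** with step δ = 5 nm and time step

    dt = δ² / (6 D),   D = 0.5 μm²/ms  →  dt ≈ 8.3 ns,

the exact 3-D relation between a fixed-step walk and its diffusion limit.
A Gaussian-displacement mode (per-axis σ = √(2D dt)) is available as a
non-default variant; both reproduce MSD = 6Dt in an empty arena.

Collisions with neuronal *and* astroglial sphere surfaces, the arena walls
and the cleft faces are **specular (mirror) reflections**: the first
segment–surface intersection is found, the remaining displacement is
reflected about the local tangent plane, and the process repeats, up to 8
reflections per step; the rare step that cannot be completed is rejected
(the molecule stays put) and counted. Astroglial surfaces reflect like
neuronal ones — molecules remain extracellular; only the binding rule
differs.

**Binding.** While a free molecule is within 5 nm of an astroglial surface
it is exposed to the first-order binding law with time constant Ψ: the
lifetime CDF P(t) = 1 − exp(−t/Ψ) (t = time in the current proximity
episode; the episode clock resets once the molecule departs by more than
5 nm). Because the exponential law is memoryless, this is implemented as
the per-step hazard 1 − exp(−dt/Ψ), which is the only discretization that
converges as dt → 0; the episode clock is still tracked so that
non-exponential laws could be substituted. Binding is irreversible within
the simulated window (≤5 ms; transporter unbinding takes tens of
milliseconds) and freezes the molecule at its binding site. δ must not
exceed the 5 nm shell so the shell cannot be jumped over in one step;
that constraint is validated.

Ψ defaults to 1 ms, of the order suggested by calibrating this class of
model against optical glutamate-sensor imaging of hippocampal CA1 synapses;
the sweep default brackets it with Ψ ∈ {0.3, 0.6, 1, 2, 4} ms and
α ∈ {0.10 … 0.30}.

**A consequence of the convergent hazard reading.** With a 5 nm shell, ~10%
astroglia and the default geometry, a free molecule spends only ~1% of its
time inside the shell, so the effective capture rate is ~0.01/Ψ per ms and
only a few percent of molecules are bound by 3 ms. Much heavier uptake —
most of the released glutamate captured within a few hundred nanometres of
the cleft inside 3 ms — would require an effective in-shell hazard orders
of magnitude above 1/Ψ. One rule that produces such amplification is a
per-step (or per-collision) Bernoulli trial with probability P(t) itself;
we deliberately avoid it because its capture rate scales as 1/dt and
therefore does not converge as the step size shrinks. The regime matters
for any quantity driven by the *amount* of uptake: free/bound ratios,
near-synapse bound concentrations, and the direction of the λ_bound-vs-Ψ
trend, which is survival-limited under strong uptake but
integration-weighted — and therefore reversed — under weak uptake.

## Analysis

Snapshots are binned into concentric spherical shells centred on the cleft
centre, starting at the cleft boundary radius (60 nm), default bin width
25 nm. Counts convert to concentration via C = n/(N_A·V_ECS) with the shell
ECS volume estimated by **stratified** test-point sampling (equal points per
shell — plain uniform sampling would starve the tiny near-cleft shells that
matter most). Bound molecules are binned by their frozen binding site and
share the ECS shell volume denominator, so the free/bound ratio equals the
raw count ratio. Shells with no estimated ECS volume are reported missing
(NaN), never zero; mass balance over bins + inside-boundary + out-of-range
tallies is exact per snapshot.

The **length constant λ** is the distance at which a profile first decays to
1/e of its reference value; the reference is the first bin beyond the cleft
boundary and λ is measured from that bin's centre, with linear interpolation
between the bracketing bin centres. Measuring from the bin centre (rather
than the 60 nm edge) removes a half-bin-width bias and recovers the true
constant of an exactly exponential profile to <2% for bins ≤ λ/10. Profiles
that never reach 1/e in range yield an explicitly undefined (NaN) λ.

"Near the synapse" for ratio reporting means the first 50 nm beyond the
cleft boundary. Space-averaged concentrations divide the free count within
a radius by the test-point-estimated ECS volume of that ball.

## Experiments and seeds

`run_trials` generates n fresh geometries (default 10 per figure-style
study; 5 in the acceptance script to keep a single-CPU run in minutes) and
averages profiles with per-bin standard errors. All randomness flows from
explicit integer seeds through `numpy` SeedSequence; a (seed_root, trial)
pair maps deterministically to geometry, walk and profile streams, so any
cell of a sweep can be reproduced in isolation. Sweeps default to **paired
seeds** (common random numbers across grid cells) because the Ψ/α trends
are small against trial-to-trial variability; setting `paired_seeds=False`
restores an injective (seed_root, cell, trial) mapping.

## Numerical choices and problem sizes

- δ = 5 nm (≤ binding shell); a convergence check against δ ∈ {2.5, 10} nm
  is recommended when changing shells or D.
- Reflection budget 8 per step; rejected-step rate is ~1e-6 under defaults
  and is logged.
- Spatial hash grid: cell edge 0.1 μm, candidate margin 0.05 μm; single-cell
  lookups are exhaustive for any query within the margin, and a per-particle
  "safe step" budget (provable clearance / δ) skips collision tests without
  changing trajectories. Index and brute force agree exactly by test.
- Geometry calibration uses 2×1e5 points, validation 1e5 (binomial SE
  ~1.3e-3 on α).
- Test-suite simulations are scaled down (hundreds of molecules,
  sub-millisecond to 3 ms durations, 2–5 trials) to keep the default run in
  minutes on one CPU; the statistics tested are invariant to that scale.

## Known limitations

- Spheres only: no elongated processes, sheets, or reconstructed meshes;
  one synapse per arena; no receptors, no transporter state cycling, no
  unbinding, no electrodiffusion or flow.
- The synthetic tissue matches real neuropil in volume fractions and length
  scales but not in connectivity or surface chemistry; passing tests show
  the *simulator* is correct under its stated laws, not that the laws
  exhaust the biology.
- The near-wall coverage thinning described above makes the arena boundary
  slightly "leakier" than the interior; profiles are only analysed within
  half the arena edge of the release site.
- Concentrations assume 1000 molecules per vesicle-release; real estimates
  run 2000–3000, so absolute μM values scale accordingly.
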