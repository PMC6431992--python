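# Methods

## The model

`poreslab` simulates a coarse-grained, charged, semiflexible polymer
driven through a nanopore into the laterally unbounded gap between two
parallel flat membranes. The chain has `N + 1` monomers (N = number of
bonds). All quantities are dimensionless: length in units of the maximum
bond extension, energy in k_BT, time in Monte Carlo steps (MCS).

The total energy is

U = U_FENE + U_Morse + U_bend + U_wall + U_elec

with the terms:

- **FENE bonds.** U_FENE(l) = −(k r₀²/2) ln[1 − ((l−l₀)/r₀)²] per bond,
  with k = 20, preferred length l₀ = 0.7 and hard limits
  l_min = 0.4 < l < l_max = 1.0, r₀ = 0.3. A trial move that takes a bond
  to or beyond the limits is rejected outright (infinite-energy
  sentinel). The prefactor uses the standard FENE form k r₀²/2, so the
  effective harmonic constant near l₀ is k.
- **Morse excluded volume** between all non-bonded pairs (|i−j| > 1):
  U_M(r) = ε[e^(−2α(r−r_min)) − 2e^(−α(r−r_min))] with α = 24,
  r_min = 0.8, ε = 1. Because α is large the potential is steep and
  short-ranged; it is truncated (not shifted) at r_c = 1.5 where its
  magnitude is ≈ 1.0e−7. Totals with and without the cutoff agree to
  better than 1e−4 for the conformations the tests probe.
- **Bending.** U_b = κ(1 + cos θ) per interior joint, where θ is the
  interior angle between consecutive bonds: collinear bonds have θ = π
  and zero energy, a full backfold costs 2κ. Equivalently
  U_b = κ(1 − b̂_i·b̂_{i+1}). This convention makes stiff chains straight,
  which is the only reading under which large κ produces stretched
  conformations.
- **Walls.** The membranes are purely repulsive and are modeled as smooth
  analytic solids: the left membrane is the slab −L ≤ z ≤ 0 minus the
  open pore cylinder of radius D/2 (L = 2, D = 1.2), the right membrane
  the half-space z ≤ −(L+R). The wall potential is the positive branch of
  the Morse form, shifted to be exactly zero beyond r_min and continuous
  there:
  U_W(r) = ε[e^(−2α(r−r_min)) − 2e^(−α(r−r_min))] + ε for r ≤ r_min,
  else 0. Physically the walls are a layer of immobile monomers of
  diameter σ = r_min whose **centers lie σ/2 inside the material
  surface**; the chain therefore evaluates U_W at
  r = (distance to the surface) + σ/2 (parameter `wall_offset`, default
  0.4). This matters: evaluating U_W at the bare surface distance would
  put ≈ 1.5e4 k_BT on the pore axis (the pore radius 0.6 is less than
  r_min) and no chain could ever pass. With the offset the on-axis
  energy is zero and the pore admits a single file of effectively
  σ-sized monomers, consistent with D < 2 r_min. Surface distances are
  true Euclidean distances to the nearest point of the solid — near the
  pore rim the nearest point is the rim circle — so the energy field is
  continuous everywhere, including across the pore mouth planes.
- **Electric driving.** Each monomer carries unit charge q = 1.
  A uniform field E acts along −z inside the pore only:
  U_e(z) = 0 for z ≥ 0, qEz for −L ≤ z < 0, and −qEL for z < −L. The
  force −qE acts only while a monomer's z lies in the pore column, and
  the total potential drop per translocated monomer is qEL. The field is
  keyed to the z-coordinate alone; only in-pore monomers can occupy that
  column anyway since the membrane material excludes everything else.
  Monomer–monomer electrostatics and hydrodynamics are omitted.

## Dynamics and protocol

Single-monomer Metropolis dynamics: a monomer is chosen uniformly at
random, displaced by increments drawn uniformly from (−0.25, 0.25) in
each coordinate, and the move is accepted with probability
min(1, e^(−ΔU/k_BT)). N + 1 trial moves form one MCS, the time unit.
ΔU is computed incrementally from the ≤ 2 bonds, ≤ 3 angles, non-bonded
pairs within the cutoff, and the wall and electric terms of the moved
monomer; the accumulated increments match a full recomputation to 1e−6
relative over 1e5 accepted moves (verified in the acceptance suite).

One sample proceeds as:

1. **Relaxation.** The head monomer is held on the pore axis half a bond
   inside the mouth (`z_park` = −0.35) and the pore is treated as
   closed: the whole z = 0 plane reflects monomers 1..N (moves to z < 0
   rejected). The chain starts as a straight rod along +z with all bonds
   at l₀ — a configuration that is always valid, so no stochastic
   construction/retry step is needed — and relaxes until the mean total
   energy of two consecutive windows of `relax_window` = 500 MCS agrees
   to `relax_tol` = 1% relative, with a floor of `relax_mcs` = 1000 and
   a cap of `relax_max_mcs` = 50000 MCS. The held head's own wall term
   is excluded from the monitored energy (it sits inside the closed
   mouth; the term is a frozen constant).
2. **Release.** At t = 0 the head is released and the pore opened.
   Parking the head *inside* the mouth makes the chain pore-engaged from
   the start; parking it on the cis side instead (the knob accepts any
   position in (−L, l₀)) leaves the chain free to diffuse away into the
   laterally unbounded half-space, where nothing ever returns it to the
   pore — measured at desk scale, 19 of 20 such samples were still
   searching after 2e6 MCS. With inside parking the withdrawal/restart
   rule below gives well-defined statistics.
3. **Withdrawal and restart.** After every MCS the pore occupancy of
   each monomer (z in (−L, 0) and x²+y² < (D/2)²) is logged. If the pore
   is empty and every monomer is on the cis side (z > 0), the attempt
   has failed: the stored equilibrated conformation is restored, the
   clock reset, and `attempts` incremented. The restart reuses the same
   equilibrated conformation; randomness simply continues.
4. **Completion.** When every monomer has passed the pore exit plane
   (z < −L) the sample is done and τ = elapsed MCS of the successful
   attempt. W(s) is the number of MCS monomer s spent inside the pore
   during that attempt (re-entries included; granularity one MCS); the
   largest per-monomer last-exit time equals τ.
5. **Guard.** A sample whose *total* MCS across restarts exceeds
   `max_mcs` is marked failed, excluded from τ and W(s) statistics, and
   counted separately.

Seeding: sample i uses seed `base_seed + i`; internally the relaxation
and translocation phases use streams (2s) and (2s+1) mod 2³¹−1 of
numpy's Mersenne-Twister-compatible generator inside the compiled
kernels. Identical seed and parameters give bit-identical records.
Samples are independent, so ensemble results do not depend on execution
order.

## Observables and analysis

- Ensemble aggregation: mean τ with standard error (SD/√n), elementwise
  mean and SE of W(s), failure counts, acceptance-rate summary.
- τ histograms use Freedman–Diaconis binning by default and report the
  sample skewness g₁; near-Gaussian ensembles give |g₁| ≈ 0, a slow
  right tail gives g₁ > 0.
- W(s) peak finding: 3-point moving-average smoothing, then the first
  interior local maximum in a configurable window (default s ∈ [2, 30]);
  when the profile has no strict maximum but is not monotone, the cusp —
  the point of largest curvature magnitude — is reported; strictly
  monotone windows return a no-peak sentinel.
- Power-law exponents (τ ~ N^α, τ ~ κ^β, the τ(R) and τ(E) slopes) come
  from unweighted ordinary least squares of log₁₀τ on log₁₀x, matching
  how the source data were fitted; a variance-weighted option exists but
  is not the default. Fit sub-ranges are explicit (R ∈ [2, 10] for the
  confinement slope; E ∈ [1.5, 10] for the field slope).

## Numerical choices

- The compiled kernels (numba, `fastmath`) use a large finite rejection
  sentinel (1e30) instead of IEEE infinity; the public API converts it
  back to `math.inf`. Fastmath changes floating-point association, so
  results are reproducible for a given build but not guaranteed
  bit-identical across compiler versions.
- Boundary conventions: z = 0 belongs to cis; the pore is the open
  cylinder −L < z < 0; points exactly on a material surface have
  wall gap 0 (the solid is topologically open), where U_W(0 + σ/2) is
  large but finite.
- Region classification and surface distance are total functions; points
  inside membrane material get a sentinel that maps to infinite energy.

## Desk-scale problem sizes

The published study used 5000-sample ensembles of N = 150 chains on a
cluster. This package's test and acceptance runs use deliberately
smaller problems chosen so the whole suite completes on one CPU in
roughly a quarter of an hour: chains of N = 15–50 bonds, 20–100 samples
per parameter point, and a `max_mcs` guard of 2e6–5e6 MCS. At this scale the qualitative behavior
is reproduced — τ decreasing and then flattening with R, τ decreasing
with E, τ growing with κ, α ≈ 1.7 within the physical band (1, 2) — but
exponent *values* are not expected to match the full-scale study, whose
grids start where ours end. The `SweepSpec` defaults make full-scale
grids (N up to 150, 5000 samples) a matter of configuration, not code.

## What the trial-move acceptance rate turned out to be

The source reports an average acceptance rate in the (60%, 70%) range at
step half-width 0.25. With the potentials exactly as stated, this
implementation measures ≈ 23% at κ = 10 and lower at larger κ (≈ 9% at
κ = 40, ≈ 5% at κ = 70). The dominant rejection channel is bending: a
displaced interior monomer perturbs up to three joint angles, each
costing O(κ·δ²/l₀²), which at κ ≥ 10 and δ ≈ 0.25 is several k_BT per
move. The reported window does not appear reachable with the stated
step size and stiffness range; the acceptance-rate check is kept in the
acceptance suite at its published value and fails honestly, documented
here rather than retuned. The step size is left at 0.25 because the
printed value is part of the model definition.

## Known limitations

- Walls are smooth analytic surfaces; any fine structure a discrete
  lattice of wall monomers would imprint on W(s) is absent.
- No monomer–monomer electrostatics, no hydrodynamic coupling, no
  membrane elasticity, no solvent.
- The per-MCS occupancy log cannot resolve sub-MCS pore transits; with
  a maximum displacement of 0.25 per accepted move and a pore of length
  2 this would require ≥ 8 accepted moves of one monomer within a
  single MCS, which for practical purposes never happens.
- Withdrawn attempts restart from the same equilibrated conformation
  rather than re-equilibrating; for the strongly driven regimes studied
  the equilibrated cis coil decorrelates within a few hundred MCS of
  dynamics anyway.
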