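# Methods

This note documents the models, numerical choices and limitations of
krigforce: what each stage assumes, which parameters matter, and what the
synthetic test bed does and does not demonstrate about real data.

## Features: atomic local frames

Every atom is the origin of its own right-handed local frame: the x-axis
points to the heaviest bonded neighbour (A₂), and the xy-plane sweeps
toward the second-heaviest atom bonded to the origin (A₃); an atom with a
single bond (H in water) falls back to the heaviest remaining atom for A₃.
Mass ties are broken by the lower original atom index — the
symmetry-degenerate case (the two hydrogens of water) has no chemically
preferred order, and a deterministic rule keeps model files reproducible.

The feature vector is d(A₁A₂) and d(A₁A₃) in Å and the angle A₂-A₁-A₃ in
**radians** (angles share the kernel with distances, and radians keep the
θ_h scales within an order of magnitude of each other; degrees would
stretch that axis ×57). For N > 3 the remaining atoms contribute spherical
polars (r, θ, φ) in the frame, with φ measured by atan2 in the right-handed
frame; this path is implemented for generality but not exercised by the
water study, and its Jacobian columns use central finite differences while
the three frame features are differentiated in closed form. Connectivity
comes from covalent radii with a fractional tolerance of 0.3, fixed once
from the seed geometry; frames are never redefined mid-trajectory.

## The synthetic partitioned surface

Real per-atom labels require wavefunctions plus topological integration;
the test bed replaces that stage with an analytic surface partitioned
exactly:

* `E_intra^A` — Morse terms on the atom's own bonded frame distances
  (depths 350 kJ/mol for O, 150 for H; width 2.2 Å⁻¹; r₀ = 1.01582 Å) plus
  a harmonic valence-angle term (300 kJ/mol rad⁻², θ₀ = 1.69561 rad) when
  both frame partners are bonded. Keeping E_intra^A a smooth function of
  atom A's *own* features mirrors the assumption each kriging model makes.
* `V_cl^AA'` — point-charge Coulomb over all pairs (q_O = −0.66 e,
  q_H = +0.33 e).
* `V_x^AA'` — an attractive exponential −180·exp(−2.2 r) kJ/mol on bonded
  pairs.

The accounting identity E_mol = Σ_A [E_intra + ½(V_cl + V_x)] is exact by
construction. The Morse r₀ and angle θ₀ were solved once (root of the
analytic internal gradient) so that the full minimum sits at
r(O–H) = 0.960 Å, ∠H-O-H = 104.5°, comfortably inside the ±20% sampling
box; `reference_minimum` re-locates it at run time by a dense grid search
plus gradient root-polish (energy-only polishing stalls at the roundoff
floor of E ≈ −555 kJ/mol, so the minimizer is pinned by solving ∇E = 0
instead). The constants are fixture data chosen for qualitative fidelity —
Coulomb alone opens the valence angle (like-charged hydrogens), exchange
alone compresses the bonds — not quantitative physics claims.

Label noise is i.i.d. Gaussian per atomic component (default σ =
0.05 kJ/mol, the order of the ±0.1 kJ/mol accuracy floor that atomic
integration noise imposes on recovering a reference energy). The
integration-error surrogate L(Ω) is log-normal (median 1e-5 a.u., log-s.d.
0.8) with a 2% contamination of "bad integrations" (median 3e-3 a.u.), so
the loose (0.001 a.u.) and tight (0.00005 a.u. = 0.13 kJ/mol) scrubbing
thresholds each delete a different, predictable subset.

## Sampling

A finite-difference Hessian (central stencils, step 1e-3 Å, symmetrized) at
the minimum is mass-weighted and diagonalized; the six |λ| < 1 kJ/mol/Å²/amu
modes are discarded as rigid-body motion. Samples displace the seed by
Σ c_m·(mass-unweighted mode m) with c_m uniform on ±s/√λ_m — stiff modes
move less, and the maximum potential energy per mode is ≈ s²/2. Rigid-body
contamination reintroduced by mass-unweighting is projected out. Samples
violating the ±20% bond/valence-angle box (closed intervals, measured
against the seed) are rejected and redrawn.

The amplitude default s = 12 √(kJ/mol) was calibrated once so the accepted
ensemble's molecular-energy range lands on the ~2·10² kJ/mol scale
(measured: ≈ 190 kJ/mol over 2000 samples) with a rejection rate under 50%
(measured: ≈ 44%). The exact stochastic law behind published normal-mode
samplers is not specified; this uniform-in-mode law is a documented
stand-in with the same two properties that matter downstream: symmetric
coverage of the box and no unphysical geometries.

## Kriging

Kernel R_ij = exp(−Σ_h θ_h |x_h^i − x_h^j|^{p_h}) + λ·1{i=j}, one θ_h and
p_h per feature, p_h ∈ [1, 2] optimized per dimension. μ̂ is the
generalized-least-squares mean (1ᵀR⁻¹y)/(1ᵀR⁻¹1) — the standard companion
of the "estimated global mean" formulation — and a = R⁻¹(y − 1μ̂), both via
Cholesky, never explicit inversion. The nugget defaults to λ = 1e-10 with
×10 escalation to at most 1e-6 on factorization failure.

Hyperparameters maximize the concentrated log-likelihood
−(n/2)·ln σ̂² − ½·ln det R with a global-best particle swarm over
(log₁₀ θ ∈ [−6, 3], p ∈ [1, 2]); defaults 40 particles × 200 iterations,
inertia 0.72, cognitive = social = 1.49, velocities clamped to the bound
width, positions clipped. Features are not standardized: θ_h absorbs scale,
and units are recorded in the model file.

One numerical guard matters. For very smooth responses the likelihood is
maximized in the long-length-scale limit where R is numerically singular;
the weights then grow to ~1e8 and predictions lose about eight digits to
cancellation — enough to corrupt finite-difference force validation and
add noise to optimization trajectories, even though the fit looks superb.
Hyperparameters whose Cholesky factor's estimated reciprocal condition
number falls below 1e-7 therefore score −∞ during training. The accuracy
cost is small (the 500-point component model still reaches a test MAE of
≈ 0.05 kJ/mol, ≈ 0.03% of the test energy range) and every trained model
stays numerically smooth.

Model files are JSON with floats serialized in hex, so save → load → save
is bit-identical.

## Forces and optimizers

∂ŷ/∂x_k follows from the kernel derivative with the cusp sign factor
δ_jk = +1 if x_k^j − x_k ≤ 0 else −1, kept verbatim including the tie case
(at p_k < 2 the two-sided derivative does not exist at a training feature;
the convention returns the one-sided value). The chain rule through the
feature Jacobian gives Cartesian forces; because features are rigid-motion
invariant, net force and net torque vanish to machine precision. Far from
all training data every correlation vanishes, predictions collapse to μ̂,
and forces go to zero — the flat mean-reverted region. A final geometry
whose maximum kernel correlation with any training point is below 1e-8 is
flagged mean-reverted and the run reported not converged, since near-zero
forces there carry no information.

The zero-Kelvin optimizer advances Δα = ½·(F/m)·dt² per step from rest
(velocities implicitly zeroed every step) and always runs its full step
budget. The unit constant for (kJ/mol/Å, amu, fs) → Å is
1e-7/(N_A·u) ≈ 1.0000e-4, assembled from SI constants and unit-tested
against a hand-computed single step. Stability requires
k·(½dt²·1e-4/m) < 2 per curvature k; for water's stiffest synthetic mode
(~7·10³ kJ/mol/Å²) and dt = 1 fs the contraction factor is ≈ 0.66.

The conjugate-gradient optimizer walks along the current direction in fixed
dt-scaled increments (the same ½·(d/m)·dt² law applied to the direction
vector) until the energy rises, then restarts along a Polak–Ribière
conjugate of the new force (β clamped at 0; plain restart on non-descent).
It stops when the largest per-atom displacement over a full cycle drops
below the distance tolerance. The forced uphill probe that ends every cycle
is recorded and flagged; the reported solution is the penultimate point, so
a CG energy trace always ends with a peak. Four presets name the studied
parameter sets: set1/set2 = zero-Kelvin, 5000 steps at 1.0/0.5 fs;
set3/set4 = CG at 1 fs with 1e-5/1e-6 Å tolerance.

## Validation machinery

S-curves are the empirical CDF of absolute molecular-energy errors
(per-point increment 100/n %). Model statistics report test/train energy
ranges, maximum error, MAE, and a prediction percentage error defined as
100·MAE/(test range) — the definition consistent with published statistics
tables relating the three rows. The landscape scan zero-Kelvin-optimizes
every supplied start (default 2000 steps at 0.5 fs) with a vectorized
stepper that is update-for-update identical to the per-start optimizer
(asserted in the tests) and aggregates final ΔE against the reference
minimum.

## Problem sizes used by the tests and the acceptance script

The study conditions are kept at full size where they are the point: 2000
sampled geometries, 500 training + 500 test geometries, zero-Kelvin runs of
5000 steps, a 200-start scan of 2000 steps. Particle-swarm budgets in the
test/acceptance configurations are 20 particles × 60 iterations — on the
3-feature water problem the likelihood surface is simple enough that larger
swarms change the trained models negligibly, and this keeps a full
retraining of nine models to about two minutes. Finite-difference force
oracles use a field with p = 2, moderate fixed length scales
(θ = [30, 30, 10]) and λ = 1e-6: a C³ surface with bounded third
derivatives, which the oracle's truncation error requires; freely trained
exponents p < 2 make the *oracle* diverge near training features without
the analytic forces being wrong.

## Limitations

* The synthetic surface is three-dimensional, unimodal and noise-controlled.
  Passing tests demonstrate the machinery — exact partition accounting,
  correct analytic forces, optimizer behaviour, scrubbing and validation
  plumbing — not that kriging models of real wavefunction-partitioned
  energies reach any particular accuracy; real labels carry correlated
  integration noise and multi-minimum landscapes this generator does not
  emulate.
* Spherical-polar features (N > 3) are typed and implemented but untested
  beyond smoke level, and their Jacobian is numerical.
* No prediction variance, gradient-enhanced kriging or sparse
  approximations: n ≤ 500 throughout, and the pipeline never uses a
  variance.
* The ±20% constraint and single-reference sampling confine models to
  near-equilibrium geometries; far-from-equilibrium starts mean-revert by
  design rather than extrapolating.
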