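# Methods

`titramd` implements continuous constant-pH molecular dynamics (CpHMD) for
a polarizable atomic-multipole potential. This note records the model, the
numerical choices, and what the shipped test systems do and do not
demonstrate.

## The extended Hamiltonian

Protonation states are continuous dynamical variables. Each titratable
site k carries a titration variable λ_k (1 = protonated) and, for residues
with two proton placements (His δ/ε, carboxylate O1/O2), a tautomer
variable ζ_k. Both are driven through θ-coordinates with
λ = sin²θ, which bounds them to [0, 1] without reflecting walls and makes
dU/dθ = dU/dλ · 2 sinθ cosθ vanish smoothly at the end states.

The total potential is

    U(X, θ) = U_bonded(X) + U_nonbonded(X, λ, ζ) + U_bias(λ, ζ).

Bonded terms always use the protonated-state parameters — a deprotonated
site keeps its alchemically decoupled proton bonded in place — so they
contribute nothing to dU/dθ. The bias has three parts per site:

* **barrier** 4 β_t λ(1−λ) (+ the ζ analogue where a tautomer exists):
  zero at the end states, maximal (= β_t) at λ = 0.5. Default β_t = 2.0
  kcal/mol (exposed in configuration); it suppresses unphysical
  intermediate states and sets the end-state transition kinetics.
* **model bias** U_mod: the negated polynomial fit of the model compound's
  titration PMF, so that for the reference compound the free-energy
  surface between end states is flat and only differences from the
  reference environment drive titration. His carries three surfaces (one
  titration PMF per tautomer end, mixed linearly in ζ, plus a tautomer
  surface scaled by 1−λ); Asp/Glu carry a tautomer surface scaled by λ,
  constrained symmetric because their two oxygens are chemically
  equivalent.
* **pH bias** ln(10)·k_B·T·(pKa_ref − pH)·(1−λ): the deprotonation free
  energy of the model compound at the ensemble pH.

## State interpolation

Permanent multipoles (charge, dipole, traceless quadrupole) and
polarizabilities interpolate linearly between end states:

* Lys/Cys:  M(λ) = (1−λ) M^U + λ M^P
* Asp/Glu:  M(λ, ζ) = (1−λ) M^U + λ [ζ M^P1 + (1−ζ) M^P2]
  (protonated tautomerism; ζ = 1 puts the proton on O1)
* His:      M(λ, ζ) = λ M^P + (1−λ) [ζ M^U1 + (1−ζ) M^U2]
  (neutral tautomerism; ζ = 1 is the ε-protonated HIE form, matching the
  +1 direction tag of the HE2 proton; HIP is the protonated state)

Derivatives of these forms are exact linears. Interpolation happens in
the local multipole frame; the frame convention and frame atoms must be
identical for all end states of an atom (validated at construction), so a
single rotation per atom maps both M and its λ/ζ derivatives to the global
frame, and one torque accumulation per atom is valid.

Van der Waals interactions of titrating hydrogens scale by f(λ, ζ):
λ for Lys/Cys, λ·f^m(ζ) for Asp/Glu, (1−λ)f^m(ζ)+λ for His, with
f^m = ζ for a +1-tagged proton and 1−ζ for −1. All other atoms are
unscaled. No soft core is used on titrating hydrogens: the proton sits
inside its heavy atom's repulsive wall, so the scaled term stays regular.
A soft-core buffered 14-7 (and a soft-core real-space charge kernel with
its λ-derivative) is provided for completeness.

## Electrostatics

The quadrupole convention is fixed project-wide: Q is the traceless
symmetric Cartesian 3×3 (e·Å²) and the energy operator is
q + d·∇ + (Q/3):∇∇. The Coulomb constant is 332.063713 kcal·Å/(mol·e²).

Everything is phrased through per-atom *potential stacks* — the potential
and its Cartesian derivatives up to third order at each site, produced by
a given source set. Energies, fields, forces, torques and state
derivatives are contractions of moments (or their λ/ζ derivatives) with
these stacks. Under periodic boundary conditions the stack is

* **real space**: pairwise erfc kernel under the minimum image, with
  masking scale factors (1-2: 0.0, 1-3: 0.0, 1-4: 0.4, 1-5: 0.8 for
  permanent terms) and, for polarization interactions, Thole damping
  applied as short-range bare-kernel corrections. Interaction tensors up
  to rank 5 are generated symbolically once from the recursion
  B_{k+1} = −(1/r) dB_k/dr, so the bare, erfc and damped kernels share
  one set of tensor expressions.
* **reciprocal space**: either a direct structure-factor k-sum (exact to
  the Gaussian-tail tolerance; the default for the small cells used here
  and the oracle for the mesh) or smooth particle-mesh Ewald with
  B-spline spreading of charge + dipole + quadrupole sources (order 5,
  spacing ≤ 1 Å by default; the acceptance comparison uses order 10 at
  0.25 Å, which agrees with the k-sum to ~1e-11 relative).
* **self**: closed-form corrections from the small-r expansion of
  erf(βr)/r, through quadrupole order.
* **neutrality**: a uniform-background term −π q_tot²/(2β²V) for charged
  cells, whose state derivative uses dq_tot/dλ (= ±1 e per site).

Torques are converted to frame-atom forces through the analytic
derivative of the rotation matrix with respect to frame-atom positions
(each frame type — z-then-x, z-then-bisector, bisector, z-only,
trisector — has an exact dR/dx); the conversion conserves total force
and total torque.

Ewald parameters of the toy cells use larger β with reduced cutoffs
(β·cutoff ≥ ~4, making the real-space truncation below 1e-8 of a typical
pair energy); the production-style default is β = 0.545 Å⁻¹ with a 7 Å
cutoff.

## Polarization

Induced dipoles solve (α⁻¹ − T) μ = E_d, where E_d is the permanent field
under group-based masking (atoms in the same polarization group do not
polarize each other) and T is the Thole-damped dipole–dipole interaction
(exponential damping, a = 0.39). The energy is U_pol = −½ μ·E_p with E_p
the bonded-masked permanent field. Because the two mask sets differ, the
gradient needs the adjoint set ν solving the same system for E_p; both are
converged in one preconditioned conjugate-gradient loop (diagonal α
preconditioner, direct-field start), which is the operational meaning of
"a single SCF per step". Default tolerance 1e-6 e·Å (max dipole change);
derivative-validation tests tighten it to 1e-10 because the analytic
state-derivative is exact only in the converged limit, with first-order
error in the residual.

The state derivative from one converged SCF is

    dU_pol/dλ = −½ (Ė_p·μ + ν·Ė_d) − ½ Σ_i α̇_i F_d,i·F_p,i

with Ė the fields sourced by the moment derivatives Ṁ (full Ewald:
real + reciprocal + self) and F = E + Tμ the total fields, which stay
finite where α = 0. The Thole damping width is frozen at a
state-independent value (fixed charge-density approximation): atoms
interpolating between two nonzero polarizabilities (thiolate sulfur
4.0 ↔ 2.8 Å³, carboxylate oxygens) use the mean of their end-state
values, titrating hydrogens their protonated-state value. This is what
removes every T-matrix term from dU/dλ and makes a single SCF sufficient.

## Dynamics and sampling

Cartesian and θ degrees of freedom propagate jointly under BAOAB Langevin
splitting, thermostatted at one bath temperature (θ fictitious mass
default 5 amu·Å²). With friction 0 the integrator reduces to velocity
Verlet and conserves the extended energy (drift < 1e-4 kcal/mol/step at
0.5 fs on the titratable crystal toy). Sites start at λ = ζ = 0.5.

pH replica exchange swaps pH values between neighboring replicas
(alternating even/odd pairs, default every 500 steps) with the Metropolis
probability built from the pH-bias term only. Records follow a pH value,
not a walker. A swap between equal pH values is a no-op, so a same-pH
ladder reproduces single-run trajectories exactly.

Model parameterization: 11 evenly spaced fixed-λ windows, conformational
sampling per window, Bennett-acceptance-ratio estimates between neighbors
(self-consistent equation solved by bisection to 1e-10), cumulative PMF
fit to a polynomial (default degree 4) anchored at G(0) = 0, negated into
U_mod. pKa estimation counts λ ≤ 0.10 as deprotonated and λ ≥ 0.90 as
protonated, discards the rest (and a 10% burn-in), and fits
S_deprot = 1/(1 + 10^{n(pKa − pH)}) by unweighted nonlinear least squares.

## Test systems

All test systems are generated deterministically in code: a multipolar
diatomic, small water boxes (AMOEBA-style water fixture parameters), the
five titratable residues as minimal solvated model compounds (a
titratable fragment plus two waters — a desk-scale stand-in for capped
model peptides in a 40 Å water box), an 8-ion rock-salt cube (Madelung
oracle), and a P1 cell containing an imidazole hydrogen-bonded to a
carboxylate (inspired by histidyl-aspartate crystal contacts, not a
reproduction of any deposited structure). Their multipole/polarizability
values are chemically plausible fixture parameters, not a published
force-field distribution; end-state charge differences are exactly ±1 e.

What passing tests show: that every analytic derivative (Cartesian, λ, ζ)
of every energy term is exact against finite differences; that the
electrostatics agree with textbook limits (Coulomb, Madelung) and the
mesh agrees with the exact k-sum; that a single SCF yields the exact
polarization state derivative; and that the full
titrate → count → Hill-fit pipeline recovers a known pKa. What they do
not show: force-field accuracy for real peptides, nanosecond-scale
convergence behavior, or crystal titration-state predictions — those
require real parameter sets and far longer simulations.

## The analytic titration benchmark

The statistical-mechanics recovery test uses an atom-free two-state site:
with U_mod = 0 and no nonbonded terms, the θ marginal is exactly
Boltzmann in barrier + pH bias, and the end-state counting ratio obeys
Henderson–Hasselbalch up to a small, exactly computable distortion from
the counting windows (numerical integration of the 1-D Boltzmann density
gives a fitted pKa of exactly the reference and a Hill coefficient of
0.952 at β_t = 2.0 — the counting window at λ ≤ 0.1 averages over a
slightly tilted basin). The benchmark runs three replicate 7-replica
pH-REX simulations (the same replicate protocol used for model-compound
validation), pools end-state counts, and fits the Hill curve. Sampling
parameters for this toy — θ mass 2 amu·Å², 1.5 fs steps, friction
30 ps⁻¹ — put the friction near the Kramers turnover for the barrier
frequency (~60 ps⁻¹ at β_t = 2), maximizing end-state transitions
(~250 crossings per 200k-step run at the midpoint pH).

## Known limitations

* Only P1 (triclinic) cells; no space-group symmetry operators.
* The bonded model for toy systems is harmonic bonds plus 1-3 distance
  terms anchored at the construction geometry — adequate to keep
  geometries sane in short runs, not a transferable force field.
* Dispersion has no long-range tail correction.
* The mesh PME evaluates energies and site potential stacks; dynamics on
  the shipped cells default to the exact k-sum backend, which is faster
  below a few hundred atoms.
* Anisotropic polarizabilities, charge-penetration corrections, and
  extrapolated SCF propagation are out of scope.
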