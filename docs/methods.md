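# Methods

This note records the models, numerical choices and known limitations of the
package, in the order the pipeline runs.

## Toy force field and systems

The energy function is the smallest model that carries the full term
taxonomy of a molecular-mechanics force field: harmonic bonds and angles
(U = ½k(x−x₀)²), cosine torsion series Σ V_n(1+cos(nφ−γ)), 12-6
Lennard-Jones in the Rmin convention, and unscreened Coulomb
(332.06 q_iq_j/r kcal·Å/mol).  Units are kcal/mol, Å and degrees at every
I/O boundary, radians internally; R = 1.9872×10⁻³ kcal/(mol·K), T defaults
to 300 K.  Nonbonded pairs within three bonds are excluded entirely (no 1-4
scaling): torsional profiles are then shaped by the explicit cosine terms
alone, which is what makes well counts provable.  There are no cutoffs and
no periodic boundary conditions; systems have tens of atoms.

Frozen atoms model the rigid shell around a flexible binding region: they
enter every energy term but carry no degrees of freedom, so minimization and
distortion leave their coordinates bit-identical.

`build_chain(n)` yields a chain with `n` freely rotatable bonds (default
3-fold torsions, V = 2.5 kcal/mol, i.e. a 5 kcal/mol ≈ 8.4 RT barrier —
high enough that each well is locally harmonic to a good approximation, low
enough that the search hops wells easily).  With positive force constants
and no nonbonded clash the landscape has exactly 3ⁿ minima, which is the
package's main exhaustiveness oracle.  `build_host_guest()` builds a rigid
pocket — a hydrophobic hexagonal floor plus a triad of +0.30 e anchor
charges, with two flexible rim atoms — and a 6-atom guest chain with a
−0.90 e head and a bulky apolar tail, the minimal realization of two-point
(polar anchor + hydrophobic pocket) recognition.  The free guest populates
both folded (≈3.3 Å end-to-end) and extended (≈6.3 Å) families.

Solvation backends: `none`; `born` — generalized-Born pairwise screening
with the Still f_GB = √(r² + a_ia_j e^(−r²/4a_ia_j)) and fixed per-atom Born
radii, between interior dielectric 1 and exterior 80 (it reduces exactly to
the Born ion formula for one atom); `surface-area` — γ·SASA with
Shrake–Rupley sphere sampling (960 deterministic golden-spiral points/atom,
probe 1.4 Å, γ = 0.00542 kcal/mol/Å²).  A grid Poisson–Boltzmann solver is
deliberately out of scope at desk scale; the Born backend is the default
polar model and any replacement only has to be a deterministic function of
coordinates.  The surface-area term is not differentiable and is restricted
to trajectory post-processing; gradient-based minimization accepts `none`
and `born`.

## Synthetic dihedral trajectories

The generator draws each dihedral series from a von Mises mixture with
prescribed state centers (degrees in [−180, 180)), concentration parameters
and weights; an optional persistence probability re-uses the previous
frame's mixture component, giving Markov-correlated frames.  Angles are
reported wrapped to [−180°, 180°), so a state centered at ±180° deliberately
straddles the boundary.  Generation is bit-reproducible under a fixed seed.
What the generator does *not* emulate: intra-well anharmonicity beyond the
von Mises shape, correlations *between* dihedrals, and kinetics — so tests
that pass on these fixtures validate the counting/shifting machinery, not
force-field realism.

## BAT coordinates and Hessians

Mobile atoms are placed by a z-matrix built breadth-first over the bond
graph; disconnected mobile fragments (a guest inside a frozen host) are
anchored by pseudo-references to the nearest placed atoms, which converts
the fragment's six rigid-body coordinates into ordinary internal
coordinates — exactly how relative ligand placement enters the complex's
configuration integral.  For a fully mobile molecule the root triad carries
the external position/orientation, leaving 3N−6 internal coordinates.
Every conformer of one system uses the same reference z-matrix so torsion
vectors are comparable.

The BAT Hessian is assembled as H_q = JᵀH_xJ + g_x·∂²x/∂q², with the
Cartesian Hessian from central differences of the analytic gradient
(step 10⁻⁵ Å) and the Jacobian and curvature of the exact reconstruction
map from central differences in q (step 10⁻⁴; the curvature term uses
5-point/4-point stencils at step 10⁻³ to keep round-off near 10⁻⁹ even far
from minima).  Because the rebuild is evaluated in a canonical frame, the
Hessian depends on internal coordinates only and is exactly invariant under
rigid motion of the input.  Torsional modes are eigenvectors of the
sub-matrix with all bond and angle rows/columns removed; bond/angle
stiffness enters Z_i through the harmonic determinant of its own block.
The b/a–torsion coupling block is thereby neglected inside Z_i (it is
second-order for stiff bonds/angles); the dense-quadrature equivalence
tests bound the resulting error at under 0.1 kcal/mol on the toy systems.

The BAT volume element r² sinθ is treated as constant across wells by
default (it cancels in ΔΔ comparisons of wells with near-identical bond
lengths and angles); `ThermoConfig(jacobian="local")` carries it inside
each Z_i instead.

## Conformational search

Two-stage minimization: scipy conjugate gradient (capped at 60 iterations,
loose gtol) followed by a damped-Newton stage with Cholesky-verified steps
and backtracking, converging the gradient inf-norm below 10⁻⁶ kcal/mol/Å.
A third stage inspects the free-subspace Hessian and escapes stationary
points with downhill curvature (torsional barrier tops are stationary too),
so every converged record is a true minimum; records that fail are flagged
and excluded.  The returned energy never exceeds the starting energy.

Each search iteration distorts every pool member along every torsional
eigenmode by ±30°, ±60°, …, ±180° (a complete sweep of the period; the
fixed ladder makes the search deterministic without any random numbers),
minimizes all candidates, removes repeats, discards conformers more than
10 RT above the current best well, and recomputes the accumulated G.  The
iteration stops when G improves by less than 0.05 kcal/mol (the observed
convergence is 2–4 iterations on the toy systems).  Re-seeding from *every*
pool member each iteration (not only new members) was chosen as the more
exhaustive variant and is still cheap at desk scale.

Repeats are records matching within 10° circular max-torsion distance AND
10⁻⁴ kcal/mol; the lowest-energy representative survives and the operation
is idempotent.  Degenerate flat profiles (free rotors) produce stationary
points everywhere along the torsion; two equal-energy records whose
straight torsional path never rises more than 10⁻³ kcal/mol above them are
recognized as one well and merged.

The grid-enumeration oracle seeds one minimization from every point of a
12-per-torsion grid (12³ = 1728 starts for the 27-well chain) and
deduplicates identically — an exponential-cost route kept independent of
the mode-following search it validates.

## Local integrals and free energies

Z_i = e^(−βE_min) · Π_bond/angle √(2πRT/λ) · Π_torsion f(λ): stiff torsional
modes (λ ≥ 2 kcal/mol/rad², reading the printed first-derivative-style
threshold units as curvatures, since the threshold gates Hessian
eigenvalues) contribute the Gaussian factor; soft modes are integrated by a
201-point trapezoid along their eigenvector over ±6 harmonic σ clipped to
the torsional period (a free rotor thus integrates to its full 2π).  All
accumulation is done in log space, so well depth never overflows.  ⟨U+W⟩
within a well is E_min + ½RT per harmonic mode plus the quadrature
expectation along soft modes; the per-term (valence/LJ/Coulomb/W)
decomposition reported for ledgers Boltzmann-averages the well-bottom
values.

G° multiplies ΣZ_i by 8π²/C°′ with C°′ = N_A·10⁻²⁷ Å⁻³ (1 M): each species
carries the external-rotation volume and the standard-state factor once, so
ΔG° of complex formation picks up the conventional 1 M reference exactly
once — a non-interacting guest allowed a free volume of 1/C°′ and full
rotation binds with ΔG° = 0.  The alternative reading of the printed
standard-state factor (divide instead of multiply) is available as
`ThermoConfig(standard_state_convention="divide")`; it shifts every
species' G° by a constant and cancels in ΔΔG.

The entropy split follows the well-count bound: −TΔS_conf = RT ln(M/k) with
M the wells within the retention window and k the bound-pose credit;
−TΔS_vib is the remainder.  With 482 wells and one bound pose the bound is
RT ln 482 = 3.7 kcal/mol at 300 K.

## Trajectory analyses

Wrap repair: a population straddling ±180° is detected on a 5°-bin circular
histogram (both boundary bins occupied while some bin elsewhere is empty);
the minority side is shifted by ±360° (ties shift the negative side up).
The repaired series' linear standard deviation equals the circular
(circular-mean-re-wrapped) standard deviation by construction, which the
tests verify against an independent scipy-based oracle.  Rotamer states are
maximal runs of bins at or above 0.5 % occupancy separated by ≥ 2 empty
bins on the canonical 144-bin histogram over [−360°, +360°]; bin width is
fixed at 5° for this profile.  Gaps of ≥ 60° between state centers and
populations ≥ 2× the occupancy threshold guarantee recovery of the
generating state count.  RMSF superposes frames on the analyzed selection
(Kabsch) before measuring fluctuation about the mean structure.
Block-average errors split the series into contiguous blocks and report
std(block means)/√n_blocks; trending series inflate the estimate, which is
a documented caveat rather than an error.

## Interaction decomposition

The single-trajectory contract evaluates complex, receptor and ligand on
the same frames.  ΔU_VDW and ΔU_Coul are computed directly as the
intermolecular pair sums; since the masks must partition whole molecules,
no bonded term crosses the interface and ΔU_val is identically zero — the
implementation additionally recomputes the three valence sums per frame and
asserts their difference vanishes.  ΔW terms are the non-additive
complex-minus-parts differences of the solvation backend.  Errors are block
averages (default 5 blocks); a leading `discard_fraction` drops
equilibration frames.

## Problem sizes

Default study sizes, chosen so every oracle stays exhaustive: chains of 1–3
torsions (3/9/27 wells; grid oracle 12 points per torsion), dense-quadrature
references at 2001 (1-D) and 241² (2-D) points, synthetic trajectories of
10⁴ frames for population recovery and 5·10³ for wrap repair, and the
host–guest demo searched with a reduced amplitude ladder (±60°, ±120°,
±180°), a 5 RT retention window and two iterations — a deliberately
desk-scale survey of the complex's pose ensemble rather than an exhaustive
one.

## Known limitations

* The harmonic bond/angle treatment inside Z_i ignores bond/angle–torsion
  coupling; accurate here because the toys keep bonds and angles stiff.
* Soft-mode anharmonicity is corrected along one eigenvector at a time;
  coupled anharmonic (multi-mode) wells are beyond the 1-D quadrature.
* The Born backend is a screening model, not a Poisson–Boltzmann solve; on
  real solutes the two differ systematically.
* Rotamer populations lose the sub-threshold histogram tails (≈1 % per
  state at the default threshold); together with multinomial sampling noise
  this puts typical recovery errors at 10⁴ frames around 0.01–0.02, so the
  per-state populations are counts of the *resolved* states, not unbiased
  mixture-weight estimates.
* The search's completeness guarantee is empirical (oracle-checked on
  enumerable systems); no global-optimality proof is implied for larger
  systems.
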