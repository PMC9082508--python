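# Methods

## The exact landscape

The package treats the exact electronic problem as constrained optimization
of E(c) = cᵀHc over the unit sphere of an orthonormal many-particle basis.
All landscape quantities are computed in an explicit tangent frame: the
N×(N−1) matrix **c**⊥ whose columns complete **c** to an orthonormal basis.
The frame is built deterministically from the Householder reflector that
maps **c** onto a signed first coordinate axis; the remaining reflector
columns are the frame.  The frame is a gauge choice — energies, gradient
norms, Hessian spectra and indices are gauge-invariant, raw frame
coordinates are not, and the API documents them as such.

Key identities used throughout (all exact, tested to 1e−10):

* local gradient g = c⊥ᵀ(2Hc); ‖g‖² = 4(⟨H²⟩ − ⟨H⟩²);
* constrained Hessian Q = 2c⊥ᵀ(H − E(c)I)c⊥; at the k-th eigenstate its
  spectrum is {2(E_i − E_k)} and its index is k;
* spectrum reconstruction {E_k} ∪ {E_k + λ_i/2} from one stationary point;
* geodesics between eigenstates carry E(θ) = E_i cos²θ + E_j sin²θ and
  ‖∇E‖² = ΔE² sin²2θ, so every eigenstate pair is separated by a variance
  barrier of height ΔE²/4 at θ = π/4.

Stationary points are enumerated by dense symmetric diagonalization (LAPACK
via numpy); each eigenstate yields a ±c_k sign pair.  Degenerate
eigenvalues produce zero Hessian eigenvalues; such points belong to flat
continua of stationary points and are flagged rather than canonicalized —
any orthonormal basis of the degenerate subspace is as good as any other.

Gradient extremals are constructed analytically as eigenstate-pair
geodesics.  On the exact landscape these *are* the extremals (the local
gradient stays an eigenvector of the local Hessian along them, which the
`extremal_residual` diagnostic verifies to 1e−9), so no predictor–corrector
path following is implemented.  The residual uses the orthogonal-component
formulation ‖Q̃g − (ĝᵀQ̃g)ĝ‖ instead of an explicit eigenvector test to
avoid eigenvalue-ordering ambiguity; points with ‖g‖ below the
stationarity tolerance return zero by convention.

Numerical tolerances: stationarity 1e−9 on the gradient norm, degeneracy
1e−8 on eigenvalue gaps (both configurable keyword arguments).  These are
appropriate for hartree-scale problems in double precision and are not
meant for Hamiltonians with norms far from O(1).

The stereographic projection for three-state problems is centered on
(c₁, c₂, c₃) = (0, 1, 0): X = c₁/(1 + c₂), Y = c₃/(1 + c₂).  The antipode
(0, −1, 0) maps to infinity and is signalled with (inf, inf), not an
exception.  The sign convention of the axes is a package choice; only the
topology (which states coincide, which point is at infinity) is meaningful.

## The H₂ model

The testbed is two hydrogen atoms on the z axis at separation R (bohr),
each carrying the standard STO-3G 1s contraction (exponents 3.42525091,
0.62391373, 0.16885540 bohr⁻², coefficients 0.15432897, 0.53532814,
0.44463454, i.e. the ζ = 1.24-scaled hydrogen fit).  The contraction is
renormalized at construction so the self-overlap is 1 to 1e−12 rather than
to the 7 digits of the published coefficients.

Integrals use the closed forms for s-type Gaussians (Gaussian product
theorem plus the Boys function F₀(x) = ½√(π/x)erf(√x), continuous at 0).
Only s functions are implemented — the model needs nothing else, and
general angular momentum is a non-goal.  The test suite pins the integrals
three independent ways: adaptive quadrature of the defining integrals
(separable 1D products for overlap/kinetic, 2D spherical quadrature for the
Coulomb terms), standard textbook reference values at R = 1.4 bohr, and a
generic bitstring Slater–Condon determinant-CI builder whose 6×6 spectrum
must contain the three CSF eigenvalues (the leftover triple being the
degenerate triplet).

The singlet Hamiltonian is assembled over the CSFs {σ_g², (σ_gσ_u singlet),
σ_u²} with symmetry MOs σ_g/σ_u = (χ₁ ± χ₂)/√(2(1 ± S₁₂)) and nuclear
repulsion 1/R added to the diagonal, so eigenvalues are total energies and
printed-geometry comparisons are direct (a constant shift changes no
gradient or Hessian).  Elements (1,2) and (2,3) vanish by g/u symmetry; the
(1,3) coupling is the exchange integral (gu|gu).

A physics note that matters when reading dissociation curves: in a minimal
basis the open-shell singlet of *symmetry* orbitals is the ionic ¹Σ_u⁺
state.  At large R the ground state tends to twice the one-atom energy
while the two *excited* singlets (gerade and ungerade ionic combinations)
become degenerate, staying roughly one on-site repulsion above the ground
state.  The suite tests exactly this behavior.

## Ansatz submanifolds

Both embeddings are trigonometric, so ‖c(t)‖ = 1 holds identically and the
plain parameter derivatives of any composed objective are the constrained
derivatives — no Lagrange multipliers or retraction steps are needed.

* RHF: doubly occupied orbital ψ₁ = cos ϕ σ_g + sin ϕ σ_u, giving
  c(ϕ) = (cos²ϕ, √2 cos ϕ sin ϕ, sin²ϕ), period π (an orbital sign flip
  leaves the determinant invariant).
* ESMF: with ψ₂ = −sin ϕ σ_g + cos ϕ σ_u, the state is
  c(θ, ϕ) = cos θ·[ψ₁ψ̄₁] + sin θ·|ψ₁ψ₂, S=0⟩.  Expanding the open-shell
  singlet of (ψ₁, ψ₂) in the fixed CSF basis gives
  (−√2 cs, c² − s², √2 cs) with c = cos ϕ, s = sin ϕ.  Domain
  (θ, ϕ) ∈ [0, 2π) × [0, π); θ → θ + π is an overall sign flip.

Three objectives are supported on either embedding: the energy, the
Hamiltonian variance (the quantity σ-SCF-style methods optimize), and the
squared norm of the constrained energy gradient (the SGM objective, which
is zero exactly at energy-stationary parameters and strictly positive at
variance-only artifacts).  Energy and variance gradients/Hessians are exact
analytic derivatives of the composed quadratic/quartic forms; the SGM
gradient is analytic (it equals 2·Hessian·gradient of the energy) while the
SGM Hessian uses central finite differences of that analytic gradient with
step 1e−5, which classifies indices to far better than the 1e−9 eigenvalue
threshold on these smooth trigonometric landscapes.

`find_stationary_points` scans a dense periodic grid (default 720 points
per parameter, minimum 64), seeds Newton iteration at every grid-local
minimum of ‖gradient‖² (8-neighborhood for two parameters), and accepts
roots with gradient norm below 1e−11.  Newton steps are trust-capped at 0.5
rad to keep each seed inside its cell's basin; non-convergent seeds are
dropped with a logged warning, never silently merged.  Survivors are
de-duplicated in state space — two parameter points are the same solution
if their embedded 3-vectors agree up to overall sign within 1e−6 — which
sidesteps parameter aliasing entirely.  Degenerate partners (e.g. the
symmetry-broken RHF pair) are reported as separate points sharing an
objective value within 1e−7, matching how such solutions are counted in
practice.  The exhaustive scan-then-polish design is deliberate for 1–2
periodic parameters: it is cheap and guarantees solution counts are not
missed, where multistart quasi-Newton could drop a basin.

`solution_curves` repeats the search over a bond-length grid and links
branches by nearest embedded-state distance (up to sign, acceptance radius
0.5); branch births and deaths — Coulson–Fischer-type events — are logged,
not raised.  Default grid density 240 per parameter for curves, trading a
little polish head-room for speed across many geometries; every reported
point is still polished to 1e−11.

Reported parameter values can be mapped to principal ranges
(−π/2, π/2] with `principal_parameters`, under which the ESMF global
minimum at equilibrium reads (θ, ϕ) = (0.5026, −0.3304) with the sign
anticorrelation between the two angles being the meaningful invariant.

## Synthetic fixtures

Random test Hamiltonians are H = U diag(Λ) Uᵀ with U a seeded random
orthogonal matrix (QR of a Gaussian matrix with the sign gauge fixed for
determinism).  They emulate exactly what the landscape theorems require —
an arbitrary real symmetric operator with a prescribed spectrum — and
nothing else: no sparsity, no symmetry blocking, no realistic integral
structure.  Passing property tests on them demonstrates the geometric
theorems (sign pairs, index = excitation level, the 4×variance identity,
barrier ordering), not the quality of any quantum-chemistry approximation;
the H₂ model is what ties the geometry to real electronic structure.
Default seed 20220218; bulk property tests draw sub-seeds from it.

## Known limitations

* Real-valued wave functions only; no complex phases or geometric phases.
* The two-orbital, two-electron ansatz algebra is hard-coded; general
  many-orbital rotations are out of scope.
* Dense diagonalization limits practical Hilbert-space sizes to a few
  thousand.
* The square-gradient landscape's own Hessian on the full hypersphere has
  no closed form here; barrier saddle indices beyond the adjacency-rank
  bookkeeping are checked only by finite-difference spot tests.
* No plotting: scan commands export (X, Y, E) and (θ, E, |∇E|², variance)
  tables for external tools.
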