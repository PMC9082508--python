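# statescape

Geometry of electronic-structure energy landscapes on the unit hypersphere —
exact states as classified stationary points, gradient extremals and variance
barriers between them, and the constrained stationary points of approximate
(RHF, ESMF) wave-function submanifolds, with a self-contained minimal-basis
H₂ model as the verifiable testbed.

## The problem and the model

A normalized configuration-interaction wave function in an *N*-dimensional
Hilbert space is a coefficient vector **c** on the unit sphere *S*^(N−1), and
its energy is the quadratic form

    E(c) = cᵀ H c,        ‖c‖ = 1,

with **H** the real symmetric Hamiltonian matrix.  The whole apparatus of
energy-landscape theory then applies exactly:

* the ambient gradient is 2**Hc**; projecting it with an orthonormal tangent
  frame **c**⊥ gives the local gradient **c**⊥ᵀ(2**Hc**), which vanishes iff
  **c** is an eigenvector;
* the constrained Hessian 2**c**⊥ᵀ(**H** − E**I**)**c**⊥ at the *k*-th
  eigenstate has eigenvalues 2(E_i − E_k), so its index equals the excitation
  level: the ground state gives the only minima (a ± sign pair), the *k*-th
  excited state an index-*k* saddle pair, and one point's energy plus Hessian
  spectrum encode the *entire* spectrum;
* gradient extremals are the great-circle geodesics
  cos θ·**c**_i + sin θ·**c**_j between eigenstate pairs, with
  E(θ) = E_i cos²θ + E_j sin²θ and |∇E|² = ΔE²sin²2θ;
* |∇E(c)|² = 4(⟨H²⟩ − ⟨H⟩²), so the variance landscape used by σ-SCF-style
  excited-state solvers inherits barriers of height ΔE² at the geodesic
  midpoints θ = π/4.

Approximate wave functions live on parametric submanifolds of the same
sphere.  For minimal-basis singlet H₂ (two electrons in σ_g, σ_u; CSF basis
{σ_g², open-shell singlet, σ_u²}) the package provides the closed-shell RHF
circle c(ϕ) = (cos²ϕ, √2 cos ϕ sin ϕ, sin²ϕ) and the two-angle excited-state
mean-field (ESMF) surface c(θ, ϕ) mixing the reference determinant with the
open-shell singlet of the rotated orbitals.  Multiple SCF solutions,
Coulson–Fischer points, unphysical variance optima and the
square-gradient-minimization (SGM) filter all appear as constrained
stationary-point structure of these embeddings.  The 3×3 CSF Hamiltonian is
built from scratch: STO-3G integrals by closed-form s-type Gaussian formulas
(Boys function), symmetry MOs, Slater–Condon rules, nuclear repulsion 1/R on
the diagonal.

Who is this for: anyone studying state-specific / excited-state electronic
structure methods who wants a small, exactly verifiable sandbox where
"solutions of a method" = "constrained stationary points on a landscape"
can be computed, classified and plotted end to end.

## Worked example

```bash
python examples/04_rhf_esmf_solutions.py
```

prints (abridged):

```
RHF energy solutions at R = 1.437707 bohr: 2
  phi =  0.000000  E = -1.11531209 Eh  index 0
  phi =  1.570796  E =  0.41386031 Eh  index 1
RHF energy solutions at R = 3.0 bohr: 4
  phi =  0.000000  E = -0.88527500 Eh  index 0
  phi =  1.570796  E = -0.43170088 Eh  index 0
  phi =  1.041240  E = -0.37138249 Eh  index 1
  phi =  2.100353  E = -0.37138249 Eh  index 1

ESMF global minimum at equilibrium:
  (theta, phi) = ( 0.5026, -0.3304)
  E = -1.1367634411 Eh   exact ground state = -1.1367634411 Eh
  RHF ground state on the ESMF surface: E = -1.11531209 Eh, Hessian index 1
```

Reading this: at the equilibrium bond length only the symmetry-pure σ_g²
minimum and σ_u² maximum exist on the RHF circle; at R = 3 bohr a degenerate
symmetry-broken pair has been born past the Coulson–Fischer point.  On the
ESMF surface the RHF ground state is no longer a minimum — simultaneous
orbital + CI relaxation lowers the energy to the *exact* ground state at
(θ, ϕ) = (±0.5026, ∓0.3304).

The other examples cover the Hamiltonian build (`01`), exact landscape
classification and spectrum-from-one-point reconstruction (`02`), geodesics
and variance barriers (`03`), and σ-SCF-analogue variance branches across
bond lengths (`05`).  The same functionality is scriptable through the thin
`statescape` CLI (`statescape h2 hamiltonian`, `statescape landscape
stationary`, `statescape ansatz scan`, ... — see `--help`).

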