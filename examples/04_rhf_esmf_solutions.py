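"""Constrained stationary points on the RHF and ESMF submanifolds.

The closed-shell RHF states form a one-angle circle on the H2 singlet
sphere: two solutions at equilibrium, four once the symmetry-broken pair is
born beyond the Coulson-Fischer point.  Adding the open-shell singlet with
a CI angle theta gives the two-parameter ESMF surface, on which the RHF
ground state turns into an index-1 saddle and a lower, exact global minimum
appears at (theta, phi) = (+-0.5026, -+0.3304).
"""

import numpy as np

from statescape import (
    build_csf_hamiltonian,
    esmf_embedding,
    find_stationary_points,
    principal_parameters,
    rhf_embedding,
)

for R in (1.437707, 3.0):
    ham = build_csf_hamiltonian(R)
    pts = find_stationary_points(rhf_embedding(), ham, "energy")
    print(f"RHF energy solutions at R = {R} bohr: {len(pts)}")
    for s in pts:
        print(f"  phi = {s.parameters[0]: .6f}  E = {s.energy: .8f} Eh"
              f"  index {s.hessian_index}")

ham = build_csf_hamiltonian(1.437707)
emb = esmf_embedding()
pts = find_stationary_points(emb, ham, "energy")
best = min(pts, key=lambda s: s.energy)
theta, phi = principal_parameters(emb, best.parameters)
e0 = np.linalg.eigvalsh(ham.matrix)[0]
print("\nESMF global minimum at equilibrium:")
print(f"  (theta, phi) = ({theta: .4f}, {phi: .4f})")
print(f"  E = {best.energy:.10f} Eh   exact ground state = {e0:.10f} Eh")
rhf_ground = [s for s in pts if np.allclose(s.parameters, 0.0, atol=1e-8)][0]
print(f"  RHF ground state on the ESMF surface: E = {rhf_ground.energy:.8f} Eh,"
      f" Hessian index {rhf_ground.hessian_index} (saddle, not a minimum)")
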