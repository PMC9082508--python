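"""Build the minimal-basis H2 singlet Hamiltonian from scratch.

Constructs the STO-3G integrals at the equilibrium bond length and
assembles the 3x3 Hamiltonian over the singlet configuration state
functions {sigma_g^2, open-shell singlet, sigma_u^2}.  The eigenvalues are
the three exact singlet total energies (hartree, nuclear repulsion
included); the zero off-diagonal elements reflect the g/u spatial symmetry
of the open-shell CSF.
"""

import numpy as np

from statescape import build_csf_hamiltonian

R = 1.437707  # bohr
ham = build_csf_hamiltonian(R)

np.set_printoptions(precision=8, suppress=True)
print(f"H2/STO-3G singlet CSF Hamiltonian at R = {R} bohr")
print(f"basis order: {ham.basis_order}")
print(ham.matrix)
print("exact singlet energies (Eh):", ham.eigenvalues())
print("RHF-level sigma_g^2 diagonal energy (Eh):", ham.matrix[0, 0])
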