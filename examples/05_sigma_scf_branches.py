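"""Variance-optimization (sigma-SCF analogue) branches across bond lengths.

Tracks the constrained stationary points of the Hamiltonian variance on the
RHF circle as the bond stretches.  The sigma_u^2 configuration is present
at every geometry but flips from variance minimum to variance maximum at
large R, and a degenerate pair of unphysical variance maxima — stationary
points with no RHF energy counterpart — persists at all bond lengths.
"""

import numpy as np

from statescape import build_csf_hamiltonian, rhf_embedding, solution_curves

R_values = [1.437707, 2.0, 3.0, 4.0, 5.0]
df = solution_curves(rhf_embedding(), build_csf_hamiltonian, R_values,
                     objective="variance", grid_density=240)

print("variance stationary points on the RHF circle (index 0 = minimum):")
print(df.round({"phi": 4, "energy": 6, "objective_value": 6}).to_string(index=False))

su2 = df[np.isclose(df.phi, np.pi / 2, atol=1e-6)]
print("\nsigma_u^2 branch classification by geometry:")
for _, row in su2.iterrows():
    kind = "minimum" if row.hessian_index == 0 else "maximum"
    print(f"  R = {row.R:4.2f}  variance {kind}  (E = {row.energy:.6f} Eh)")
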