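"""Classify every stationary point of the exact energy on the hypersphere.

For the three-state H2 problem at R = 2 bohr, each eigenstate appears as a
sign pair of stationary points whose constrained Hessian index equals its
excitation level: the ground state gives the only two minima, the first
excited state index-1 saddles, the second excited state the maxima.  The
full spectrum is then reconstructed from the local curvature at a single
point, and each state is mapped to the stereographic plane.
"""

import numpy as np

from statescape import (
    build_csf_hamiltonian,
    enumerate_exact_stationary_points,
    spectrum_from_stationary_point,
    stereographic_project,
)

H = build_csf_hamiltonian(2.0).matrix
points = enumerate_exact_stationary_points(H)

print("stationary points of the exact singlet energy at R = 2 bohr:")
for sp in points:
    X, Y = stereographic_project(sp.point)
    print(f"  E = {sp.energy: .8f} Eh  index {sp.hessian_index}"
          f"  {sp.label:>14s}  (X, Y) = ({X: .4f}, {Y: .4f})")

ground = points[0]
print("\nspectrum reconstructed from the ground point's energy + Hessian:")
print(" ", spectrum_from_stationary_point(ground, H))
print("direct diagonalization:")
print(" ", np.linalg.eigvalsh(H))
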