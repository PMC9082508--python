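"""Minimal-basis H2 model: STO-3G integrals and the singlet CSF Hamiltonian.

Everything here is computed from scratch in atomic units (hartree, bohr).
Two hydrogen-like centers at bond length ``R`` carry one contracted s-type
Gaussian each (the standard STO-3G contraction for H).  From the resulting
one- and two-electron integrals we assemble the exact electronic Hamiltonian
of the two-electron singlet space, a 3x3 real symmetric matrix in the basis
of configuration state functions (CSFs)

    { sigma_g^2,  open-shell singlet (sigma_g sigma_u),  sigma_u^2 },

which is the full configuration interaction problem for singlet H2 in a
minimal basis.  Nuclear repulsion 1/R is included on the diagonal so that
matrix eigenvalues are total energies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .errors import DomainError

__all__ = [
    "STO3G_H_EXPONENTS",
    "STO3G_H_COEFFS",
    "GaussianShell",
    "AOIntegralSet",
    "MOBasis",
    "CSFHamiltonian",
    "sto3g_hydrogen",
    "boys_f0",
    "build_ao_integrals",
    "symmetry_mos",
    "mo_integrals",
    "build_csf_hamiltonian",
]

# STO-3G hydrogen 1s parameters: least-squares fit of three primitive
# Gaussians to a Slater 1s function, scaled by the standard H scale factor
# zeta = 1.24 (exponents carry zeta^2).  Values as tabulated in the EMSL /
# Basis Set Exchange STO-3G entry for H.
STO3G_H_EXPONENTS = (3.42525091, 0.62391373, 0.16885540)  # bohr^-2
STO3G_H_COEFFS = (0.15432897, 0.53532814, 0.44463454)


def boys_f0(x):
    """Boys function F0(x) = integral_0^1 exp(-x t^2) dt.

    Closed form ``sqrt(pi/x) * erf(sqrt(x)) / 2`` for x > 0, with the
    continuous limit F0(0) = 1.  Accepts scalars or arrays; x must be
    nonnegative.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise DomainError("boys_f0 requires x >= 0")
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    out = np.ones_like(x)
    pos = x > 0
    sx = np.sqrt(x[pos])
    out[pos] = 0.5 * np.sqrt(np.pi) * erf(sx) / sx
    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class GaussianShell:
    """A contracted s-type Gaussian: sum_i d_i (2 a_i / pi)^{3/4} exp(-a_i r^2).

    The contraction coefficients are rescaled at construction so the
    contracted function has unit self-overlap.
    """

    center: np.ndarray
    exponents: np.ndarray
    contraction_coeffs: np.ndarray

    def __post_init__(self):
        center = np.asarray(self.center, dtype=float).reshape(3)
        a = np.asarray(self.exponents, dtype=float)
        d = np.asarray(self.contraction_coeffs, dtype=float)
        if a.shape != d.shape:
            raise DomainError("exponents and contraction_coeffs must have equal length")
        if np.any(a <= 0):
            raise DomainError("Gaussian exponents must be strictly positive")
        # working coefficients: primitive norms (2a/pi)^{3/4} folded in, then the
        # contraction rescaled to unit self-overlap; the raw input coefficients
        # stay untouched so shells can be rebuilt from one another
        dn = d * (2.0 * a / np.pi) ** 0.75
        p = a[:, None] + a[None, :]
        s_self = np.sum(dn[:, None] * dn[None, :] * (np.pi / p) ** 1.5)
        dn = dn / np.sqrt(s_self)
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "exponents", a)
        object.__setattr__(self, "contraction_coeffs", d)
        object.__setattr__(self, "_norm_coeffs", dn)

    def self_overlap(self) -> float:
        a, d = self.exponents, self._norm_coeffs
        p = a[:, None] + a[None, :]
        return float(np.sum(d[:, None] * d[None, :] * (np.pi / p) ** 1.5))


def sto3g_hydrogen(center=(0.0, 0.0, 0.0)) -> GaussianShell:
    """The STO-3G hydrogen 1s shell at ``center`` (bohr)."""
    return GaussianShell(np.asarray(center, float),
                         np.array(STO3G_H_EXPONENTS),
                         np.array(STO3G_H_COEFFS))


@dataclass(frozen=True)
class AOIntegralSet:
    """One- and two-electron integrals over the two AO basis functions.

    ``nuclear_attraction`` is the total electron-nucleus attraction matrix
    (both centers, charge +1 each); ``eri`` is in chemists' notation
    (ij|kl) with the full 8-fold permutational symmetry.
    """

    bond_length: float
    overlap: np.ndarray
    kinetic: np.ndarray
    nuclear_attraction: np.ndarray
    eri: np.ndarray
    nuclear_repulsion: float

    @property
    def core_hamiltonian(self) -> np.ndarray:
        return self.kinetic + self.nuclear_attraction


def _primitive_pairs(sh_a: GaussianShell, sh_b: GaussianShell):
    """Gaussian-product data for all primitive pairs of two shells."""
    a = sh_a.exponents[:, None]
    b = sh_b.exponents[None, :]
    da = sh_a._norm_coeffs[:, None]
    db = sh_b._norm_coeffs[None, :]
    p = a + b
    mu = a * b / p
    ab2 = float(np.dot(sh_a.center - sh_b.center, sh_a.center - sh_b.center))
    pref = da * db * np.exp(-mu * ab2)
    # product-Gaussian centers, shape (na, nb, 3)
    centers = (a[..., None] * sh_a.center + b[..., None] * sh_b.center) / p[..., None]
    return p, mu, ab2, pref, centers


def _overlap(sh_a, sh_b):
    p, mu, ab2, pref, _ = _primitive_pairs(sh_a, sh_b)
    return float(np.sum(pref * (np.pi / p) ** 1.5))


def _kinetic(sh_a, sh_b):
    p, mu, ab2, pref, _ = _primitive_pairs(sh_a, sh_b)
    return float(np.sum(pref * mu * (3.0 - 2.0 * mu * ab2) * (np.pi / p) ** 1.5))


def _nuclear_attraction(sh_a, sh_b, nucleus: np.ndarray, charge: float = 1.0):
    p, mu, ab2, pref, centers = _primitive_pairs(sh_a, sh_b)
    pc2 = np.sum((centers - nucleus) ** 2, axis=-1)
    return float(-charge * np.sum(pref * (2.0 * np.pi / p) * boys_f0(p * pc2)))


def _eri(sh_a, sh_b, sh_c, sh_d):
    """(ab|cd) in chemists' notation over four contracted s shells."""
    p, _, _, pref_ab, P = _primitive_pairs(sh_a, sh_b)
    q, _, _, pref_cd, Q = _primitive_pairs(sh_c, sh_d)
    p4 = p[:, :, None, None]
    q4 = q[None, None, :, :]
    pq2 = np.sum((P[:, :, None, None, :] - Q[None, None, :, :, :]) ** 2, axis=-1)
    pref = pref_ab[:, :, None, None] * pref_cd[None, None, :, :]
    val = pref * 2.0 * np.pi ** 2.5 / (p4 * q4 * np.sqrt(p4 + q4)) \
        * boys_f0(p4 * q4 / (p4 + q4) * pq2)
    return float(np.sum(val))


def build_ao_integrals(R: float, shell: GaussianShell | None = None) -> AOIntegralSet:
    """All AO integrals for two identical s shells separated by ``R`` bohr.

    ``shell`` supplies the radial part (exponents/contraction); centers are
    placed at the origin and at (0, 0, R).  Defaults to STO-3G hydrogen.
    """
    if R <= 0:
        raise DomainError(f"bond length must be positive, got {R}")
    template = shell if shell is not None else sto3g_hydrogen()
    sh1 = GaussianShell(np.zeros(3), template.exponents, template.contraction_coeffs)
    sh2 = GaussianShell(np.array([0.0, 0.0, R]), template.exponents,
                        template.contraction_coeffs)
    shells = (sh1, sh2)
    n = 2
    S = np.empty((n, n))
    T = np.empty((n, n))
    V = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            S[i, j] = _overlap(shells[i], shells[j])
            T[i, j] = _kinetic(shells[i], shells[j])
            V[i, j] = sum(_nuclear_attraction(shells[i], shells[j], sh.center)
                          for sh in shells)
    eri = np.empty((n, n, n, n))
    for i in range(n):
        for j in range(n):
            for k in range(n):
                for l in range(n):
                    eri[i, j, k, l] = _eri(shells[i], shells[j], shells[k], shells[l])
    return AOIntegralSet(bond_length=float(R), overlap=S, kinetic=T,
                         nuclear_attraction=V, eri=eri,
                         nuclear_repulsion=1.0 / R)


@dataclass(frozen=True)
class MOBasis:
    """Symmetry-adapted molecular orbitals sigma_g, sigma_u of H2.

    ``mo_coeffs`` columns hold the AO coefficients of (sigma_g, sigma_u);
    the phase convention is equal-sign AO coefficients for sigma_g and
    (+, -) for sigma_u.
    """

    mo_coeffs: np.ndarray
    labels: tuple = ("gerade", "ungerade")


def symmetry_mos(ints: AOIntegralSet) -> MOBasis:
    """Build sigma_g/sigma_u from the AO overlap, normalized in the S metric."""
    s12 = ints.overlap[0, 1]
    if abs(s12) >= 1.0:
        raise DomainError("AO basis is (numerically) linearly dependent: |S12| >= 1")
    ng = 1.0 / np.sqrt(2.0 * (1.0 + s12))
    nu = 1.0 / np.sqrt(2.0 * (1.0 - s12))
    C = np.array([[ng, nu],
                  [ng, -nu]])
    return MOBasis(mo_coeffs=C)


def mo_integrals(ints: AOIntegralSet, mos: MOBasis | None = None):
    """Transform AO integrals to the (sigma_g, sigma_u) MO basis.

    Returns ``(h, g)`` where ``h`` is the 2x2 core Hamiltonian and ``g`` the
    2x2x2x2 repulsion tensor in chemists' notation, both over MOs.
    """
    mos = mos if mos is not None else symmetry_mos(ints)
    C = mos.mo_coeffs
    h = C.T @ ints.core_hamiltonian @ C
    g = np.einsum("pi,qj,rk,sl,pqrs->ijkl", C, C, C, C, ints.eri, optimize=True)
    return h, g


@dataclass(frozen=True)
class CSFHamiltonian:
    """The 3x3 singlet Hamiltonian in {sg^2, open-shell singlet, su^2} order.

    Includes nuclear repulsion on the diagonal; elements (1,2) and (2,3)
    vanish by g/u spatial symmetry (the open-shell singlet is ungerade).
    """

    matrix: np.ndarray
    bond_length: float
    basis_order: tuple = ("sigma_g^2", "open-shell singlet", "sigma_u^2")

    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvalsh(self.matrix)

    def eigenstates(self):
        return np.linalg.eigh(self.matrix)


def build_csf_hamiltonian(R: float, shell: GaussianShell | None = None) -> CSFHamiltonian:
    """Assemble the singlet CSF Hamiltonian at bond length ``R`` (bohr).

    Matrix elements follow from the Slater-Condon rules for the three
    two-electron singlet CSFs over orthonormal MOs g = sigma_g, u = sigma_u:

        <g^2|H|g^2>   = 2 h_gg + (gg|gg)
        <gu,S|H|gu,S> = h_gg + h_uu + (gg|uu) + (gu|gu)
        <u^2|H|u^2>   = 2 h_uu + (uu|uu)
        <g^2|H|u^2>   = (gu|gu)

    with nuclear repulsion 1/R added on the diagonal.
    """
    ints = build_ao_integrals(R, shell)
    h, g = mo_integrals(ints)
    J_gg = g[0, 0, 0, 0]
    J_uu = g[1, 1, 1, 1]
    J_gu = g[0, 0, 1, 1]
    K_gu = g[0, 1, 0, 1]
    e_nuc = ints.nuclear_repulsion
    H = np.array([
        [2 * h[0, 0] + J_gg + e_nuc, 0.0, K_gu],
        [0.0, h[0, 0] + h[1, 1] + J_gu + K_gu + e_nuc, 0.0],
        [K_gu, 0.0, 2 * h[1, 1] + J_uu + e_nuc],
    ])
    return CSFHamiltonian(matrix=H, bond_length=float(R))
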