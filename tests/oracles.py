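"""Independent oracles used by the test suite.

Two construction paths that share no code with the package:

* primitive Gaussian integrals by adaptive numerical quadrature, written
  directly against the defining integrals (1D separable products for overlap
  and kinetic energy, 2D spherical-coordinate quadrature for the Coulomb
  integrals, exploiting the collinear geometry of H2);
* a determinant-basis configuration-interaction builder using generic
  bitstring Slater-Condon rules over spin orbitals, whose spectrum must
  contain the singlet CSF eigenvalues.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import integrate


def _norm(a: float) -> float:
    return (2.0 * a / math.pi) ** 0.75


def quad_overlap_prim(a: float, za: float, b: float, zb: float) -> float:
    """<ga|gb> for normalized s primitives on the z axis, by 1D quadrature."""
    perp = integrate.quad(lambda x: math.exp(-(a + b) * x * x),
                          -np.inf, np.inf, epsabs=1e-14)[0]
    axial = integrate.quad(
        lambda z: math.exp(-a * (z - za) ** 2 - b * (z - zb) ** 2),
        -np.inf, np.inf, epsabs=1e-14)[0]
    return _norm(a) * _norm(b) * perp * perp * axial


def quad_kinetic_prim(a: float, za: float, b: float, zb: float) -> float:
    """-(1/2)<ga|lap|gb> via the symmetric form (1/2) int grad ga . grad gb."""
    s_perp = integrate.quad(lambda x: math.exp(-(a + b) * x * x),
                            -np.inf, np.inf, epsabs=1e-14)[0]
    s_ax = integrate.quad(
        lambda z: math.exp(-a * (z - za) ** 2 - b * (z - zb) ** 2),
        -np.inf, np.inf, epsabs=1e-14)[0]
    d_perp = integrate.quad(
        lambda x: 4 * a * b * x * x * math.exp(-(a + b) * x * x),
        -np.inf, np.inf, epsabs=1e-14)[0]
    d_ax = integrate.quad(
        lambda z: 4 * a * b * (z - za) * (z - zb)
        * math.exp(-a * (z - za) ** 2 - b * (z - zb) ** 2),
        -np.inf, np.inf, epsabs=1e-14)[0]
    total = d_perp * s_perp * s_ax + s_perp * d_perp * s_ax + s_perp * s_perp * d_ax
    return 0.5 * _norm(a) * _norm(b) * total


def quad_attraction_prim(a: float, za: float, b: float, zb: float,
                         zc: float) -> float:
    """<ga| -1/|r - C| |gb> by 2D spherical quadrature centered on the nucleus.

    All centers lie on the z axis, so in spherical coordinates (r, u = cos
    polar angle) about C the integrand is azimuthally symmetric and the 1/r
    singularity is cancelled by the r^2 Jacobian.
    """
    da, db = za - zc, zb - zc

    def integrand(u, r):
        ra2 = r * r + da * da - 2 * r * u * da
        rb2 = r * r + db * db - 2 * r * u * db
        return r * math.exp(-a * ra2 - b * rb2)

    val, _ = integrate.dblquad(integrand, 0.0, 40.0, -1.0, 1.0,
                               epsabs=1e-12, epsrel=1e-12)
    return -2.0 * math.pi * _norm(a) * _norm(b) * val


def gaussian_potential(q: float, d: float) -> float:
    """Electrostatic potential of the unit-charge density (q/pi)^{3/2} e^{-q r^2}
    at distance d from its center: erf(sqrt(q) d) / d (limit 2 sqrt(q/pi) at 0)."""
    if d < 1e-12:
        return 2.0 * math.sqrt(q / math.pi)
    return math.erf(math.sqrt(q) * d) / d


def quad_gaussian_potential(q: float, d: float) -> float:
    """Same potential by direct 2D quadrature (validates gaussian_potential)."""
    def integrand(u, r):
        r12sq = r * r + d * d - 2 * r * u * d
        return r * r * math.exp(-q * r * r) / math.sqrt(r12sq)

    val, _ = integrate.dblquad(integrand, 0.0, 30.0, -1.0, 1.0,
                               epsabs=1e-12, epsrel=1e-12)
    return (q / math.pi) ** 1.5 * 2.0 * math.pi * val


def quad_eri_prim(a, za, b, zb, c, zc, d, zd) -> float:
    """(ab|cd) for normalized s primitives on the z axis.

    Electron 2's charge distribution g_c g_d is collapsed to its product
    Gaussian and replaced by its electrostatic potential (validated
    separately by quad_gaussian_potential); electron 1 is integrated by 2D
    spherical quadrature about that product center.
    """
    q = c + d
    zq = (c * zc + d * zd) / q
    kcd = math.exp(-c * d / q * (zc - zd) ** 2)
    # total charge of the normalized primitive product
    charge = _norm(c) * _norm(d) * kcd * (math.pi / q) ** 1.5
    da, db = za - zq, zb - zq

    def integrand(u, r):
        ra2 = r * r + da * da - 2 * r * u * da
        rb2 = r * r + db * db - 2 * r * u * db
        return r * r * math.exp(-a * ra2 - b * rb2) * gaussian_potential(q, r)

    val, _ = integrate.dblquad(integrand, 0.0, 40.0, -1.0, 1.0,
                               epsabs=1e-12, epsrel=1e-12)
    return _norm(a) * _norm(b) * charge * 2.0 * math.pi * val


def shell_pair_contract(prim_fn, shell_a, shell_b, *extra) -> float:
    """Sum a two-index primitive oracle over the contractions of two shells."""
    za, zb = shell_a.center[2], shell_b.center[2]
    total = 0.0
    for ai, dai in zip(shell_a.exponents, shell_a._norm_coeffs):
        for bj, dbj in zip(shell_b.exponents, shell_b._norm_coeffs):
            # oracle primitives carry their own normalization; divide it out
            total += dai * dbj / (_norm(ai) * _norm(bj)) \
                * prim_fn(ai, za, bj, zb, *extra)
    return total


# ---------------------------------------------------------------------------
# determinant-basis CI for two electrons in two spatial orbitals

def spin_orbital_integrals(h: np.ndarray, g: np.ndarray):
    """Expand spatial (h, g) to spin orbitals; g in chemists' notation.

    Spin orbital 2p + s has spatial index p and spin s (0 = alpha, 1 = beta).
    Returns one-electron h_so and the physicists' antisymmetrized <ij||kl>.
    """
    n = h.shape[0]
    ns = 2 * n
    h_so = np.zeros((ns, ns))
    for i in range(ns):
        for j in range(ns):
            if i % 2 == j % 2:
                h_so[i, j] = h[i // 2, j // 2]
    g_phys = np.zeros((ns,) * 4)  # <ij|kl> = (p_i p_k | p_j p_l) with spin deltas
    for i, j, k, l in itertools.product(range(ns), repeat=4):
        if i % 2 == k % 2 and j % 2 == l % 2:
            g_phys[i, j, k, l] = g[i // 2, k // 2, j // 2, l // 2]
    return h_so, g_phys - g_phys.transpose(0, 1, 3, 2)


def slater_condon(det1, det2, h_so, g_asym):
    """<det1|H|det2> for two-electron determinants given as sorted index pairs."""
    d1, d2 = tuple(det1), tuple(det2)
    common = sorted(set(d1) & set(d2))
    diff1 = [x for x in d1 if x not in common]
    diff2 = [x for x in d2 if x not in common]
    if len(diff1) == 0:
        i, j = d1
        return h_so[i, i] + h_so[j, j] + g_asym[i, j, i, j]
    if len(diff1) == 1:
        m = common[0]
        n1, n2 = diff1[0], diff2[0]
        sign = (-1) ** (d1.index(n1) + d2.index(n2))
        return sign * (h_so[n1, n2] + g_asym[n1, m, n2, m])
    i, j = d1
    k, l = d2
    return g_asym[i, j, k, l]


def determinant_ci_spectrum(h: np.ndarray, g: np.ndarray,
                            e_nuc: float = 0.0) -> np.ndarray:
    """All eigenvalues of the two-electron Hamiltonian over determinants."""
    ns = 2 * h.shape[0]
    h_so, g_asym = spin_orbital_integrals(h, g)
    dets = list(itertools.combinations(range(ns), 2))
    H = np.array([[slater_condon(a, b, h_so, g_asym) for b in dets] for a in dets])
    return np.sort(np.linalg.eigvalsh(H)) + e_nuc
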