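"""Gradient extremals, geodesics between eigenstates, and the variance landscape.

On the exact energy landscape the gradient-extremal paths — curves along
which the local gradient is an eigenvector of the constrained Hessian — are
precisely the great-circle geodesics between pairs of eigenstates,

    c(theta) = cos(theta) c_i + sin(theta) c_j,     theta in [0, pi/2],

with energy E(theta) = E_i cos^2(theta) + E_j sin^2(theta) and squared
gradient norm |grad E|^2 = (E_j - E_i)^2 sin^2(2 theta).  The identity
|grad E|^2 = 4 (<H^2> - <H>^2) ties the gradient norm to the Hamiltonian
variance, so the variance landscape inherits this structure: eigenstates are
its zeros, and every pair of eigenstates is separated by a variance barrier
of height (Delta E)^2 / 4 peaked at the midpoint theta = pi/4, where the
energy has an inflection but the square-gradient is stationary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError, DomainError
from .landscape import (
    STATIONARITY_TOL,
    StatePoint,
    _as_symmetric,
    _as_unit_vector,
    local_gradient,
    local_hessian,
    tangent_frame,
)

__all__ = [
    "GeodesicPath",
    "BarrierRecord",
    "geodesic",
    "energy_along",
    "square_gradient_along",
    "sample_geodesic",
    "extremal_residual",
    "variance",
    "folded_spectrum",
    "barrier_catalog",
]


def geodesic(c_i, c_j, theta) -> StatePoint | list[StatePoint]:
    """Point(s) on the great circle cos(theta) c_i + sin(theta) c_j.

    The endpoints must be orthonormal (e.g. two eigenstates of the same
    Hamiltonian); theta may be a scalar or an array of angles in radians.
    """
    vi = _as_unit_vector(c_i)
    vj = _as_unit_vector(c_j)
    if abs(float(vi @ vj)) > 1e-10:
        raise DomainError("geodesic endpoints must be orthogonal")
    th = np.asarray(theta, dtype=float)
    if th.ndim == 0:
        return StatePoint(np.cos(th) * vi + np.sin(th) * vj)
    return [StatePoint(np.cos(t) * vi + np.sin(t) * vj) for t in th]


def energy_along(theta, E_i: float, E_j: float):
    """Energy profile E_i cos^2(theta) + E_j sin^2(theta) along a geodesic."""
    th = np.asarray(theta, dtype=float)
    out = E_i * np.cos(th) ** 2 + E_j * np.sin(th) ** 2
    return float(out) if th.ndim == 0 else out


def square_gradient_along(theta, delta_E: float):
    """|grad E|^2 = (Delta E)^2 sin^2(2 theta); peak (Delta E)^2 at pi/4."""
    th = np.asarray(theta, dtype=float)
    out = delta_E ** 2 * np.sin(2.0 * th) ** 2
    return float(out) if th.ndim == 0 else out


@dataclass(frozen=True)
class GeodesicPath:
    """A sampled gradient extremal between eigenstates i and j."""

    endpoint_indices: tuple
    theta_grid: np.ndarray
    points: list
    energies: np.ndarray
    square_gradients: np.ndarray


def sample_geodesic(H, i: int, j: int, n_samples: int = 101) -> GeodesicPath:
    """Sample the geodesic between eigenstates ``i`` and ``j`` of ``H``.

    Energies and square-gradients are evaluated analytically from the
    eigenvalues; they agree with the direct quadratic form / projected
    gradient along the path to machine precision.
    """
    H = _as_symmetric(H)
    evals, evecs = np.linalg.eigh(H)
    if not (0 <= i < evals.size and 0 <= j < evals.size) or i == j:
        raise DomainError("endpoint indices must be distinct eigenstate indices")
    theta = np.linspace(0.0, np.pi / 2.0, n_samples)
    pts = geodesic(evecs[:, i], evecs[:, j], theta)
    return GeodesicPath(
        endpoint_indices=(i, j),
        theta_grid=theta,
        points=pts,
        energies=energy_along(theta, evals[i], evals[j]),
        square_gradients=square_gradient_along(theta, evals[j] - evals[i]),
    )


def extremal_residual(c, H, stationarity_tol: float = STATIONARITY_TOL) -> float:
    """Deviation from the gradient-extremal condition at ``c``.

    A point lies on a gradient extremal when the local gradient is an
    eigenvector of the constrained Hessian.  Returned is the norm of the
    component of (Hessian @ gradient) orthogonal to the gradient, which is
    zero exactly on extremals; stationary points (vanishing gradient) return
    zero by convention.
    """
    v = _as_unit_vector(c)
    frame = tangent_frame(v)
    g = local_gradient(v, H, frame)
    gnorm = np.linalg.norm(g)
    if gnorm < stationarity_tol:
        return 0.0
    Q = local_hessian(v, H, frame)
    Qg = Q @ g
    ghat = g / gnorm
    return float(np.linalg.norm(Qg - (Qg @ ghat) * ghat))


def variance(c, H) -> float:
    """Hamiltonian variance <H^2> - <H>^2; equals |grad E|^2 / 4."""
    v = _as_unit_vector(c)
    H = _as_symmetric(H)
    Hv = H @ v
    return float(Hv @ Hv - (v @ Hv) ** 2)


def folded_spectrum(c, H, omega: float) -> float:
    """Folded-spectrum objective <(H - omega)^2> = variance + (E - omega)^2.

    Over exact eigenstates it is minimized by the one with energy closest to
    the target ``omega``, which is what makes it useful for steering an
    optimization toward an interior state.
    """
    v = _as_unit_vector(c)
    H = _as_symmetric(H)
    Hv = H @ v
    e = float(v @ Hv)
    return float(Hv @ Hv - e * e + (e - omega) ** 2)


@dataclass(frozen=True)
class BarrierRecord:
    """Square-gradient barrier between one pair of eigenstates."""

    pair: tuple
    height: float          # (E_j - E_i)^2, hartree^2
    inflection_theta: float  # always pi/4 on the exact landscape
    adjacency_rank: int    # |i - j| in the energy ordering


def barrier_catalog(H) -> list[BarrierRecord]:
    """One barrier record per unordered eigenstate pair, sorted by height.

    Barrier heights are the squared spectral gaps, so for a non-degenerate
    spectrum the lowest barrier always connects states adjacent in energy.
    """
    H = _as_symmetric(H)
    evals = np.linalg.eigvalsh(H)
    records = []
    n = evals.size
    for i in range(n):
        for j in range(i + 1, n):
            records.append(BarrierRecord(
                pair=(i, j),
                height=float((evals[j] - evals[i]) ** 2),
                inflection_theta=np.pi / 4.0,
                adjacency_rank=j - i,
            ))
    records.sort(key=lambda r: r.height)
    return records
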