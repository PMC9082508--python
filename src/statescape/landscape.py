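"""Differential geometry of the exact electronic energy on the unit hypersphere.

A normalized configuration-interaction state is a coefficient vector ``c`` on
the unit sphere S^{N-1} of its N-dimensional Hilbert space, and the energy is
the quadratic form E(c) = c^T H c.  This module provides the ambient gradient
2Hc, deterministic orthonormal tangent frames, the projected (local) gradient
and constrained Hessian, enumeration and classification of all stationary
points (the +/- sign pairs of the eigenvectors of H), reconstruction of the
full spectrum from the local structure at a single stationary point, and the
stereographic projection used to visualize three-state problems.

Classification theorems realized here:

* a state is stationary iff it is an eigenvector of H;
* at the k-th eigenstate the constrained Hessian eigenvalues are
  2(E_i - E_k), i != k, so the Hessian index equals the excitation level k:
  the ground state gives the only minima, the k-th excited state an index-k
  saddle pair, the highest state the maxima;
* degenerate eigenvalues produce zero Hessian eigenvalues — such states sit
  on flat continua of stationary points and are flagged as degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ContractError, DomainError

__all__ = [
    "StatePoint",
    "TangentFrame",
    "LocalCurvature",
    "StationaryPoint",
    "energy",
    "global_gradient",
    "tangent_frame",
    "local_gradient",
    "local_hessian",
    "local_curvature",
    "enumerate_exact_stationary_points",
    "spectrum_from_stationary_point",
    "stereographic_project",
    "stereographic_inverse",
]

#: default tolerance on the local-gradient norm below which a point counts
#: as stationary (hartree)
STATIONARITY_TOL = 1e-9
#: default tolerance on eigenvalue gaps below which states count as degenerate
DEGENERACY_TOL = 1e-8


def _as_unit_vector(c, tol: float = 1e-8) -> np.ndarray:
    v = np.asarray(getattr(c, "coeffs", c), dtype=float).ravel()
    nrm = np.linalg.norm(v)
    if abs(nrm - 1.0) > tol:
        raise ContractError(f"state vector must be unit-norm, |c| = {nrm!r}")
    return v


def _as_symmetric(H) -> np.ndarray:
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[0] != H.shape[1]:
        raise DomainError("Hamiltonian must be a square matrix")
    if not np.allclose(H, H.T, atol=1e-10):
        raise DomainError("Hamiltonian must be symmetric")
    return H


@dataclass(frozen=True)
class StatePoint:
    """A unit-norm CI coefficient vector on the hypersphere."""

    coeffs: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.coeffs, dtype=float).ravel()
        nrm = np.linalg.norm(v)
        if not np.isfinite(nrm) or abs(nrm - 1.0) > 1e-8:
            raise ContractError(f"StatePoint requires a unit vector, |c| = {nrm!r}")
        object.__setattr__(self, "coeffs", v)

    @property
    def dimension(self) -> int:
        return self.coeffs.size

    def __neg__(self) -> "StatePoint":
        return StatePoint(-self.coeffs)


@dataclass(frozen=True)
class TangentFrame:
    """An orthonormal basis of the tangent space at a StatePoint.

    ``basis`` is N x (N-1); together with the point it satisfies the
    completeness relation c c^T + B B^T = I.  The frame itself is a gauge
    choice: gradient norms, Hessian spectra and indices are frame-invariant,
    raw frame coordinates are not.
    """

    point: StatePoint
    basis: np.ndarray


def tangent_frame(c) -> TangentFrame:
    """Deterministic orthonormal tangent frame at ``c``.

    Uses the Householder reflector that maps ``c`` onto a signed first
    coordinate axis; the image of the remaining axes forms the frame.
    """
    v = np.asarray(getattr(c, "coeffs", c), dtype=float).ravel()
    nrm = np.linalg.norm(v)
    if nrm == 0:
        raise DomainError("cannot build a tangent frame at the zero vector")
    point = c if isinstance(c, StatePoint) else StatePoint(v / nrm)
    u = point.coeffs.copy()
    n = u.size
    sign = 1.0 if u[0] >= 0 else -1.0
    w = u.copy()
    w[0] += sign  # reflector v = c + sign(c_1) e_1, maps c -> -sign e_1
    w /= np.linalg.norm(w)
    # columns 2..N of the reflector I - 2 w w^T are orthonormal and orthogonal to c
    B = -2.0 * np.outer(w, w[1:])
    B[1:, :] += np.eye(n - 1)
    return TangentFrame(point=point, basis=B)


def _check_frame(c_vec: np.ndarray, frame: TangentFrame) -> np.ndarray:
    B = frame.basis
    if not np.allclose(frame.point.coeffs, c_vec, atol=1e-10):
        raise ContractError("tangent frame was built at a different point")
    return B


def energy(c, H) -> float:
    """E(c) = c^T H c, the expectation value on the unit sphere."""
    v = _as_unit_vector(c)
    H = _as_symmetric(H)
    if H.shape[0] != v.size:
        raise ContractError("dimension mismatch between state and Hamiltonian")
    return float(v @ H @ v)


def global_gradient(c, H) -> np.ndarray:
    """Ambient-space gradient of the quadratic form: 2 H c."""
    v = _as_unit_vector(c)
    H = _as_symmetric(H)
    if H.shape[0] != v.size:
        raise ContractError("dimension mismatch between state and Hamiltonian")
    return 2.0 * H @ v


def local_gradient(c, H, frame: TangentFrame | None = None) -> np.ndarray:
    """Tangent-space gradient B^T (2 H c); zero exactly at eigenvectors."""
    v = _as_unit_vector(c)
    frame = frame if frame is not None else tangent_frame(v)
    B = _check_frame(v, frame)
    return B.T @ global_gradient(v, H)


def local_hessian(c, H, frame: TangentFrame | None = None) -> np.ndarray:
    """Constrained Hessian 2 B^T (H - E(c) I) B in the tangent frame."""
    v = _as_unit_vector(c)
    frame = frame if frame is not None else tangent_frame(v)
    B = _check_frame(v, frame)
    H = _as_symmetric(H)
    e = float(v @ H @ v)
    shifted = H - e * np.eye(H.shape[0])
    return 2.0 * B.T @ shifted @ B


@dataclass(frozen=True)
class LocalCurvature:
    """Energy, local gradient and constrained Hessian at one point."""

    energy: float
    local_gradient: np.ndarray
    local_hessian: np.ndarray
    frame: TangentFrame


def local_curvature(c, H) -> LocalCurvature:
    v = _as_unit_vector(c)
    frame = tangent_frame(v)
    return LocalCurvature(
        energy=energy(v, H),
        local_gradient=local_gradient(v, H, frame),
        local_hessian=local_hessian(v, H, frame),
        frame=frame,
    )


@dataclass
class StationaryPoint:
    """A classified stationary point of the energy on the hypersphere."""

    point: StatePoint
    energy: float
    hessian_index: int
    hessian_eigenvalues: np.ndarray
    label: str
    degenerate: bool = False
    sign_partner: Optional["StationaryPoint"] = field(default=None, repr=False)


def _classify_label(index: int, n_tangent: int) -> str:
    if index == 0:
        return "minimum"
    if index == n_tangent:
        return "maximum"
    return f"index-{index} saddle"


def enumerate_exact_stationary_points(
    H,
    stationarity_tol: float = STATIONARITY_TOL,
    degeneracy_tol: float = DEGENERACY_TOL,
) -> list[StationaryPoint]:
    """All 2N stationary points (+/- each eigenvector), sorted by energy.

    The k-th eigenstate yields a sign pair with constrained Hessian spectrum
    {2(E_i - E_k) : i != k} and Hessian index k.  Points whose Hessian has a
    (near-)zero eigenvalue — i.e. members of a degenerate eigenvalue — are
    flagged ``degenerate``: they belong to a flat continuum of stationary
    points rather than being isolated.
    """
    H = _as_symmetric(H)
    evals, evecs = np.linalg.eigh(H)
    n = evals.size
    points: list[StationaryPoint] = []
    for k in range(n):
        others = np.delete(evals, k)
        hess_eigs = np.sort(2.0 * (others - evals[k]))
        index = int(np.sum(hess_eigs < -stationarity_tol))
        degenerate = bool(np.any(np.abs(others - evals[k]) < degeneracy_tol))
        label = _classify_label(index, n - 1)
        pair = []
        for sign in (+1.0, -1.0):
            pair.append(StationaryPoint(
                point=StatePoint(sign * evecs[:, k]),
                energy=float(evals[k]),
                hessian_index=index,
                hessian_eigenvalues=hess_eigs,
                label=label,
                degenerate=degenerate,
            ))
        pair[0].sign_partner = pair[1]
        pair[1].sign_partner = pair[0]
        points.extend(pair)
    points.sort(key=lambda sp: sp.energy)
    return points


def spectrum_from_stationary_point(sp: StationaryPoint, H=None,
                                   stationarity_tol: float = STATIONARITY_TOL) -> np.ndarray:
    """Reconstruct the full eigenvalue list from one stationary point.

    The spectrum is {E_k} together with {E_k + lambda_i / 2} over the
    constrained Hessian eigenvalues lambda_i.  If ``H`` is supplied the
    stationarity of ``sp`` is verified against it first.
    """
    if H is not None:
        g = local_gradient(sp.point, H)
        if np.linalg.norm(g) > max(stationarity_tol, 1e-9):
            raise ContractError("point is not stationary: |local gradient| = "
                                f"{np.linalg.norm(g):.3e}")
    recovered = np.concatenate(([sp.energy],
                                sp.energy + np.asarray(sp.hessian_eigenvalues) / 2.0))
    return np.sort(recovered)


def stereographic_project(c) -> tuple[float, float]:
    """Project a 3-state vector to the plane, centered on (0, 1, 0).

    X = c1 / (1 + c2), Y = c3 / (1 + c2).  The antipode (0, -1, 0) of the
    projection center maps to infinity; it is signalled with (inf, inf)
    rather than an exception.
    """
    v = _as_unit_vector(c)
    if v.size != 3:
        raise DomainError("stereographic projection is defined for 3-state problems")
    denom = 1.0 + v[1]
    if denom <= 1e-300:
        return (np.inf, np.inf)
    return (float(v[0] / denom), float(v[2] / denom))


def stereographic_inverse(X: float, Y: float) -> StatePoint:
    """Inverse stereographic map back to the unit sphere (pole excluded)."""
    s = X * X + Y * Y
    c2 = (1.0 - s) / (1.0 + s)
    return StatePoint(np.array([X * (1.0 + c2), c2, Y * (1.0 + c2)]))
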