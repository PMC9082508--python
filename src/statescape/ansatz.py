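"""Ansatz submanifolds of the H2 singlet hypersphere and their stationary points.

Two approximate wave-function families are embedded into the three-state CSF
sphere {sigma_g^2, open-shell singlet, sigma_u^2}:

* RHF — one closed-shell determinant with doubly occupied orbital
  psi_1 = cos(phi) sigma_g + sin(phi) sigma_u.  Expanded in CSFs,

      c(phi) = (cos^2 phi, sqrt(2) cos phi sin phi, sin^2 phi),

  a one-parameter circle on the sphere (period pi: flipping the orbital sign
  leaves the determinant unchanged).

* ESMF — excited-state mean-field: the reference determinant of psi_1 mixed
  with the open-shell singlet built from (psi_1, psi_2), where
  psi_2 = -sin(phi) sigma_g + cos(phi) sigma_u, via a CI angle theta:

      c(theta, phi) = cos(theta) [psi_1 psi_1-bar] + sin(theta) |psi_1 psi_2, S=0>.

  Expanded in the fixed CSF basis the open-shell component reads
  (-sqrt2 cs, cos^2 - sin^2, sqrt2 cs) with c = cos phi, s = sin phi.

Stationary points of three objectives — the energy, the Hamiltonian variance
(the objective of sigma-SCF-style variance optimization), and the squared
norm of the ansatz-constrained energy gradient (the SGM objective) — are
located by dense periodic grid scan followed by Newton polish, de-duplicated
up to parameter aliasing and overall wave-function sign, and classified by
their parameter-space Hessian index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, DomainError
from .landscape import StatePoint, _as_symmetric

__all__ = [
    "Embedding",
    "ConstrainedStationaryPoint",
    "rhf_embedding",
    "esmf_embedding",
    "rhf_embed",
    "esmf_embed",
    "constrained_gradient",
    "constrained_hessian",
    "variance_objective",
    "sgm_objective",
    "find_stationary_points",
    "solution_curves",
    "principal_parameters",
]

logger = logging.getLogger(__name__)

#: gradient-norm threshold accepted as stationary after polish
POLISH_TOL = 1e-11
#: two solutions are the same state if embedded vectors agree up to sign
DEDUP_TOL = 1e-6
#: Hessian eigenvalue threshold for index counting
INDEX_TOL = 1e-9

_SQRT2 = np.sqrt(2.0)


@dataclass(frozen=True)
class Embedding:
    """A smooth parametric map t -> c(t) from angles into the unit sphere.

    The trigonometric construction keeps ||c(t)|| = 1 identically, so the
    plain parameter-space derivatives of any objective composed with the map
    are the constrained derivatives on the sphere.
    """

    ansatz: str
    parameter_names: tuple
    periods: tuple
    _map: Callable
    _jacobian: Callable
    _second: Callable

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_names)

    def _t(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if t.shape[-1:] != (self.n_parameters,):
            t = t.reshape(t.shape + (1,)) if self.n_parameters == 1 and t.ndim == 0 \
                else t
        if t.shape[-1] != self.n_parameters:
            raise ContractError(
                f"{self.ansatz} embedding expects {self.n_parameters} parameter(s)")
        return t

    def map(self, t) -> np.ndarray:
        """Coefficient vector(s) c(t), shape (..., 3)."""
        return self._map(self._t(t))

    def jacobian(self, t) -> np.ndarray:
        """Partial derivatives dc/dt, shape (..., 3, p)."""
        return self._jacobian(self._t(t))

    def second_derivatives(self, t) -> np.ndarray:
        """Second partials d^2 c / dt_a dt_b, shape (..., 3, p, p)."""
        return self._second(self._t(t))

    def state(self, t) -> StatePoint:
        return StatePoint(self.map(t))

    def wrap(self, t) -> np.ndarray:
        return np.mod(self._t(t), np.asarray(self.periods))


# ---------------------------------------------------------------------------
# RHF: c(phi) = ((1 + cos 2phi)/2, sin 2phi / sqrt2, (1 - cos 2phi)/2)

def _rhf_map(t):
    c2, s2 = np.cos(2 * t[..., 0]), np.sin(2 * t[..., 0])
    return np.stack([(1 + c2) / 2, s2 / _SQRT2, (1 - c2) / 2], axis=-1)


def _rhf_jacobian(t):
    c2, s2 = np.cos(2 * t[..., 0]), np.sin(2 * t[..., 0])
    return np.stack([-s2, _SQRT2 * c2, s2], axis=-1)[..., None]


def _rhf_second(t):
    c2, s2 = np.cos(2 * t[..., 0]), np.sin(2 * t[..., 0])
    return np.stack([-2 * c2, -2 * _SQRT2 * s2, 2 * c2], axis=-1)[..., None, None]


def rhf_embedding() -> Embedding:
    """The closed-shell RHF circle, parameter phi with period pi."""
    return Embedding("RHF", ("phi",), (np.pi,),
                     _rhf_map, _rhf_jacobian, _rhf_second)


def rhf_embed(phi: float) -> StatePoint:
    """CSF coefficients of the closed-shell determinant with orbital angle phi."""
    return rhf_embedding().state([phi])


# ---------------------------------------------------------------------------
# ESMF: c(theta, phi) = cos(theta) a(phi) + sin(theta) b(phi)
# a = closed-shell determinant of psi_1, b = open-shell singlet of (psi_1, psi_2)

def _esmf_ab(phi):
    c2, s2 = np.cos(2 * phi), np.sin(2 * phi)
    a = np.stack([(1 + c2) / 2, s2 / _SQRT2, (1 - c2) / 2], axis=-1)
    b = np.stack([-s2 / _SQRT2, c2, s2 / _SQRT2], axis=-1)
    da = np.stack([-s2, _SQRT2 * c2, s2], axis=-1)
    db = np.stack([-_SQRT2 * c2, -2 * s2, _SQRT2 * c2], axis=-1)
    dda = np.stack([-2 * c2, -2 * _SQRT2 * s2, 2 * c2], axis=-1)
    ddb = np.stack([2 * _SQRT2 * s2, -4 * c2, -2 * _SQRT2 * s2], axis=-1)
    return a, b, da, db, dda, ddb


def _esmf_map(t):
    th, ph = t[..., 0], t[..., 1]
    a, b, *_ = _esmf_ab(ph)
    return np.cos(th)[..., None] * a + np.sin(th)[..., None] * b


def _esmf_jacobian(t):
    th, ph = t[..., 0], t[..., 1]
    a, b, da, db, *_ = _esmf_ab(ph)
    ct, st = np.cos(th)[..., None], np.sin(th)[..., None]
    d_theta = -st * a + ct * b
    d_phi = ct * da + st * db
    return np.stack([d_theta, d_phi], axis=-1)


def _esmf_second(t):
    th, ph = t[..., 0], t[..., 1]
    a, b, da, db, dda, ddb = _esmf_ab(ph)
    ct, st = np.cos(th)[..., None], np.sin(th)[..., None]
    d_tt = -(ct * a + st * b)
    d_tp = -st * da + ct * db
    d_pp = ct * dda + st * ddb
    row_t = np.stack([d_tt, d_tp], axis=-1)
    row_p = np.stack([d_tp, d_pp], axis=-1)
    return np.stack([row_t, row_p], axis=-1)


def esmf_embedding() -> Embedding:
    """The two-angle ESMF surface, (theta, phi) with periods (2 pi, pi)."""
    return Embedding("ESMF", ("theta", "phi"), (2 * np.pi, np.pi),
                     _esmf_map, _esmf_jacobian, _esmf_second)


def esmf_embed(theta: float, phi: float) -> StatePoint:
    """CSF coefficients of the ESMF state at CI angle theta, orbital angle phi."""
    return esmf_embedding().state([theta, phi])


def get_embedding(name: str) -> Embedding:
    key = name.strip().lower()
    if key == "rhf":
        return rhf_embedding()
    if key == "esmf":
        return esmf_embedding()
    raise DomainError(f"unknown ansatz {name!r}; expected 'rhf' or 'esmf'")


# ---------------------------------------------------------------------------
# objectives in parameter space

def _ham(H) -> np.ndarray:
    return _as_symmetric(getattr(H, "matrix", H))


def _quad(c, M, d):
    # batched c^T M d with c, d of shape (..., 3)
    return np.einsum("...i,ij,...j->...", c, M, d)


def constrained_gradient(e: Embedding, t, H) -> np.ndarray:
    """Energy gradient in parameter space, J^T (2 H c)."""
    H = _ham(H)
    c = e.map(t)
    J = e.jacobian(t)
    return 2.0 * np.einsum("...ia,ij,...j->...a", J, H, c)


def constrained_hessian(e: Embedding, t, H) -> np.ndarray:
    """Exact parameter-space Hessian of the energy along the embedding."""
    H = _ham(H)
    c = e.map(t)
    J = e.jacobian(t)
    S = e.second_derivatives(t)
    term1 = 2.0 * np.einsum("...ia,ij,...jb->...ab", J, H, J)
    term2 = 2.0 * np.einsum("...iab,ij,...j->...ab", S, H, c)
    return term1 + term2


def _energy_value(e, t, H):
    H = _ham(H)
    c = e.map(t)
    return _quad(c, H, c)


def variance_objective(e: Embedding, t, H) -> np.ndarray:
    """Hamiltonian variance <H^2> - <H>^2 restricted to the ansatz."""
    H = _ham(H)
    c = e.map(t)
    Hc = np.einsum("ij,...j->...i", H, c)
    return np.einsum("...i,...i->...", Hc, Hc) - _quad(c, H, c) ** 2


def _variance_gradient(e, t, H):
    H = _ham(H)
    M = H @ H
    c = e.map(t)
    J = e.jacobian(t)
    E = _quad(c, H, c)
    JMc = np.einsum("...ia,ij,...j->...a", J, M, c)
    JHc = np.einsum("...ia,ij,...j->...a", J, H, c)
    return 2.0 * JMc - 4.0 * E[..., None] * JHc


def _variance_hessian(e, t, H):
    # V = c^T H^2 c - E^2  =>  V_ab = (c^T H^2 c)_ab - 2 E_a E_b - 2 E E_ab
    H = _ham(H)
    M = H @ H
    c = e.map(t)
    J = e.jacobian(t)
    S = e.second_derivatives(t)
    E = _quad(c, H, c)
    E_a = 2.0 * np.einsum("...ia,ij,...j->...a", J, H, c)
    E_ab = 2.0 * np.einsum("...ia,ij,...jb->...ab", J, H, J) \
        + 2.0 * np.einsum("...iab,ij,...j->...ab", S, H, c)
    F_ab = 2.0 * np.einsum("...ia,ij,...jb->...ab", J, M, J) \
        + 2.0 * np.einsum("...iab,ij,...j->...ab", S, M, c)
    return F_ab - 2.0 * np.einsum("...a,...b->...ab", E_a, E_a) \
        - 2.0 * E[..., None, None] * E_ab


def sgm_objective(e: Embedding, t, H) -> np.ndarray:
    """Square-gradient-minimization objective |J^T 2Hc|^2.

    Zero exactly where the ansatz energy is stationary; strictly positive at
    variance-only artifacts, which is what lets SGM discriminate physical
    solutions from unphysical variance stationary points.
    """
    g = constrained_gradient(e, t, H)
    return np.einsum("...a,...a->...", g, g)


def _sgm_gradient(e, t, H):
    g = constrained_gradient(e, t, H)
    Eh = constrained_hessian(e, t, H)
    return 2.0 * np.einsum("...ab,...b->...a", Eh, g)


def _fd_hessian(grad_fn, t, h=1e-5):
    t = np.asarray(t, dtype=float)
    p = t.size
    Hm = np.empty((p, p))
    for a in range(p):
        tp = t.copy(); tp[a] += h
        tm = t.copy(); tm[a] -= h
        Hm[:, a] = (grad_fn(tp) - grad_fn(tm)) / (2 * h)
    return 0.5 * (Hm + Hm.T)


class _Objective:
    def __init__(self, name, value, gradient, hessian):
        self.name = name
        self.value = value
        self.gradient = gradient
        self.hessian = hessian


def _get_objective(name: str) -> _Objective:
    key = name.strip().lower()
    if key == "energy":
        return _Objective("energy", _energy_value, constrained_gradient,
                          lambda e, t, H: constrained_hessian(e, t, H))
    if key == "variance":
        return _Objective("variance", variance_objective, _variance_gradient,
                          lambda e, t, H: _variance_hessian(e, t, H))
    if key in ("sqgrad", "local_square_gradient", "sgm"):
        return _Objective("local_square_gradient", sgm_objective, _sgm_gradient,
                          lambda e, t, H: _fd_hessian(
                              lambda x: _sgm_gradient(e, x, H), t))
    raise DomainError(f"unknown objective {name!r}")


# ---------------------------------------------------------------------------
# stationary-point search

@dataclass
class ConstrainedStationaryPoint:
    """A classified stationary point of an objective on an ansatz manifold."""

    parameters: tuple
    point: StatePoint
    objective: str
    value: float
    energy: float
    hessian_index: int
    hessian_eigenvalues: np.ndarray
    degenerate_partner_count: int = 0


def principal_parameters(e: Embedding, t) -> tuple:
    """Map parameters to principal ranges (-period/2, period/2].

    Shifting theta by pi flips the overall sign of the ESMF state and
    shifting phi by pi leaves it unchanged, so each distinct state (up to
    sign) has a representative with every angle in (-period/2, period/2].
    """
    t = np.asarray(t, dtype=float).ravel()
    out = []
    for val, period in zip(t, (np.pi,) * len(t)):
        w = np.mod(val, period)
        if w > period / 2 + 1e-12:
            w -= period
        out.append(w)
    return tuple(out)


def _states_equivalent(v, w, tol=DEDUP_TOL):
    return min(np.linalg.norm(v - w), np.linalg.norm(v + w)) < tol


def _newton_polish(e, obj, H, t0, tol=POLISH_TOL, max_iter=60):
    t = np.asarray(t0, dtype=float).copy()
    for _ in range(max_iter):
        g = obj.gradient(e, t, H)
        if np.linalg.norm(g) < tol:
            return t
        Hm = np.atleast_2d(obj.hessian(e, t, H))
        try:
            step = np.linalg.solve(Hm, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(Hm, g, rcond=None)[0]
        if not np.all(np.isfinite(step)):
            return None
        nstep = np.linalg.norm(step)
        if nstep > 0.5:  # keep Newton inside the basin of the seeding cell
            step *= 0.5 / nstep
        t = t - step
    g = obj.gradient(e, t, H)
    return t if np.linalg.norm(g) < tol else None


def _grid_seeds(e, obj, H, grid_density):
    """Grid points whose squared gradient norm is a periodic local minimum."""
    p = e.n_parameters
    axes = [np.linspace(0.0, period, grid_density, endpoint=False)
            for period in e.periods]
    mesh = np.meshgrid(*axes, indexing="ij")
    T = np.stack([m.ravel() for m in mesh], axis=-1)
    g = obj.gradient(e, T, H)
    gn2 = np.sum(g * g, axis=-1).reshape([grid_density] * p)
    mask = np.ones_like(gn2, dtype=bool)
    for axis in range(p):
        for shift in (-1, 1):
            mask &= gn2 <= np.roll(gn2, shift, axis=axis)
    if p == 2:  # include diagonal neighbours
        for s0 in (-1, 1):
            for s1 in (-1, 1):
                mask &= gn2 <= np.roll(np.roll(gn2, s0, axis=0), s1, axis=1)
    return T[mask.ravel()]


def find_stationary_points(e: Embedding, H, objective: str = "energy",
                           grid_density: int = 720,
                           index_tol: float = INDEX_TOL,
                           dedup_tol: float = DEDUP_TOL) -> list[ConstrainedStationaryPoint]:
    """Locate and classify all stationary points of an objective on an ansatz.

    A dense periodic grid scan of the objective's parameter-space gradient
    seeds Newton polish; converged roots are de-duplicated modulo parameter
    aliasing and overall wave-function sign, then classified by the
    eigenvalues of the parameter-space Hessian.  Non-convergent seeds are
    dropped with a logged warning, never silently merged.
    """
    if grid_density < 64:
        raise DomainError("grid_density must be at least 64 per parameter")
    Hmat = _ham(H)
    obj = _get_objective(objective)
    seeds = _grid_seeds(e, obj, Hmat, grid_density)
    survivors: list[ConstrainedStationaryPoint] = []
    for seed in seeds:
        t = _newton_polish(e, obj, Hmat, seed)
        if t is None:
            logger.warning("%s/%s polish did not converge from seed %s; dropped",
                           e.ansatz, obj.name, np.round(seed, 6))
            continue
        t = e.wrap(t)
        vec = e.map(t)
        if any(_states_equivalent(vec, s.point.coeffs, dedup_tol) for s in survivors):
            continue
        Hess = np.atleast_2d(obj.hessian(e, t, Hmat))
        eigs = np.sort(np.linalg.eigvalsh(Hess))
        index = int(np.sum(eigs < -index_tol))
        survivors.append(ConstrainedStationaryPoint(
            parameters=tuple(float(x) for x in t),
            point=StatePoint(vec),
            objective=obj.name,
            value=float(obj.value(e, t, Hmat)),
            energy=float(_energy_value(e, t, Hmat)),
            hessian_index=index,
            hessian_eigenvalues=eigs,
        ))
    # degeneracy grouping by objective value
    values = np.array([s.value for s in survivors])
    for s in survivors:
        s.degenerate_partner_count = int(np.sum(np.abs(values - s.value) < 1e-7) - 1)
    survivors.sort(key=lambda s: s.value)
    return survivors


def solution_curves(e: Embedding, H_builder: Callable[[float], object],
                    R_values: Sequence[float], objective: str = "energy",
                    grid_density: int = 240) -> pd.DataFrame:
    """Track stationary-point branches across bond lengths.

    For each R the stationary points are found and continuity-linked to the
    previous geometry by nearest embedded-state distance (up to sign).
    Branch births and deaths (Coulson-Fischer-type events) are logged.
    Returns a table with one row per (R, branch).
    """
    rows = []
    branches: list[np.ndarray] = []  # last known state of each branch
    alive: dict[int, bool] = {}
    for R in R_values:
        H = H_builder(R)
        pts = find_stationary_points(e, H, objective, grid_density)
        assigned = {}
        for s in pts:
            best, best_d = None, np.inf
            for b, vec in enumerate(branches):
                if b in assigned.values():
                    continue
                d = min(np.linalg.norm(s.point.coeffs - vec),
                        np.linalg.norm(s.point.coeffs + vec))
                if d < best_d:
                    best, best_d = b, d
            if best is not None and best_d < 0.5:
                assigned[id(s)] = best
                branches[best] = s.point.coeffs
            else:
                branches.append(s.point.coeffs)
                b_new = len(branches) - 1
                assigned[id(s)] = b_new
                if rows:
                    logger.info("branch %d born at R = %.4f (%s/%s)",
                                b_new, R, e.ansatz, objective)
        seen = set(assigned.values())
        for b, was_alive in list(alive.items()):
            if was_alive and b not in seen:
                logger.info("branch %d lost at R = %.4f (%s/%s)",
                            b, R, e.ansatz, objective)
        alive = {b: (b in seen) for b in range(len(branches))}
        for s in pts:
            row = {"R": float(R), "branch": assigned[id(s)]}
            for name, val in zip(e.parameter_names, s.parameters):
                row[name] = val
            row.update(energy=s.energy, objective_value=s.value,
                       hessian_index=s.hessian_index)
            rows.append(row)
    return pd.DataFrame(rows)
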