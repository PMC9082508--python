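"""Synthetic Hamiltonian fixtures for property tests and demonstrations.

The landscape theorems (sign-pair stationary points, index = excitation
level, the gradient/variance identity, barrier structure) hold for any real
symmetric Hamiltonian, so random matrices with a prescribed spectrum are the
natural test harness: H = U diag(spectrum) U^T with U a seeded random
orthogonal matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .landscape import StatePoint

__all__ = ["DEFAULT_SEED", "SpectrumSpec", "random_hamiltonian", "random_state"]

#: package-wide default seed; property tests draw sub-seeds from it
DEFAULT_SEED = 20220218


@dataclass(frozen=True)
class SpectrumSpec:
    """Dimension, eigenvalue list (hartree) and seed for a random Hamiltonian."""

    dimension: int
    eigenvalues: tuple
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        ev = tuple(float(x) for x in self.eigenvalues)
        if self.dimension < 2:
            raise ConfigError("SpectrumSpec requires dimension >= 2")
        if len(ev) != self.dimension:
            raise ConfigError("eigenvalue list length must equal dimension")
        if not all(np.isfinite(ev)):
            raise ConfigError("eigenvalues must be finite")
        object.__setattr__(self, "eigenvalues", ev)


def _random_orthogonal(n: int, rng: np.random.Generator) -> np.ndarray:
    A = rng.standard_normal((n, n))
    Q, R = np.linalg.qr(A)
    # fix the gauge so the factorization (hence the matrix) is deterministic
    return Q * np.sign(np.diag(R))


def random_hamiltonian(spec: SpectrumSpec) -> np.ndarray:
    """Symmetric matrix with exactly the spectrum of ``spec``, seeded."""
    rng = np.random.default_rng(spec.seed)
    U = _random_orthogonal(spec.dimension, rng)
    return U @ np.diag(spec.eigenvalues) @ U.T


def random_state(n: int, rng: np.random.Generator | int | None = None) -> StatePoint:
    """A uniformly random unit vector on S^{n-1}."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    v = rng.standard_normal(n)
    return StatePoint(v / np.linalg.norm(v))
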